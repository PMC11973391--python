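"""Clan-structured Y-STR dataset simulator with known truth.

Emulates the sampling design of a patrilineal tribe study: a handful of
clans, each descending from one or a few founder haplotypes, sampled
T years after the founders lived.  Alleles evolve under a strict stepwise
mutation model (SMM): per locus, mutation counts are Poisson with rate
mu per generation, each mutation moving the repeat count by +-1 with
equal probability (reflected at the locus allele range).  Genealogies are
either star-shaped (every sample an independent lineage from the founder
— the regime under which rho dating is calibrated) or Kingman
coalescent trees rescaled so the root sits at the founder.

Defaults mirror the published study design: seven clans with sample
sizes 40/32/39/85/36/53/65 (n = 350), one founder per clan, T = 1000
years, mu = 2.1e-3 per locus per generation, 30-year generations.
Founder haplotypes drawn uniformly within locus allele ranges make
founder effects visible: clan-level diversity drops well below
tribe-level diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AlleleCall, HaplotypeTable
from .loci import PANEL_Y23, LocusDef

STUDY_CLAN_SIZES: dict[str, int] = {
    "Kerderi": 40, "Kereit": 32, "Ramadan": 39, "Tabyn": 85,
    "Tama": 36, "Teleu": 53, "Zhagalbaily": 65,
}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_clans: int = 7
    samples_per_clan: tuple[int, ...] | None = None  # default: study sizes
    founders_per_clan: int = 1
    t_years: float = 1000.0
    mutation_rate: float = 2.1e-3
    generation_years: float = 30.0
    genealogy: str = "star"
    admixture_rate: float = 0.0
    null_rate: float = 0.0
    duplication_rate: float = 0.0
    loci: tuple[LocusDef, ...] = field(default=PANEL_Y23)

    def __post_init__(self) -> None:
        for r in (self.admixture_rate, self.null_rate, self.duplication_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.genealogy not in ("star", "coalescent"):
            raise ValueError(f"unknown genealogy {self.genealogy!r}")
        if self.founders_per_clan < 1 or self.n_clans < 1:
            raise ValueError("need >= 1 clan and founder")
        if self.mutation_rate <= 0 or self.generation_years <= 0:
            raise ValueError("mutation rate and generation time must be positive")

    def clan_names(self) -> list[str]:
        if self.n_clans == len(STUDY_CLAN_SIZES):
            return list(STUDY_CLAN_SIZES)
        return [f"Clan{i + 1:02d}" for i in range(self.n_clans)]

    def clan_sizes(self) -> list[int]:
        if self.samples_per_clan is not None:
            if len(self.samples_per_clan) != self.n_clans:
                raise ValueError("samples_per_clan length != n_clans")
            return list(self.samples_per_clan)
        if self.n_clans == len(STUDY_CLAN_SIZES):
            return list(STUDY_CLAN_SIZES.values())
        return [50] * self.n_clans

    @property
    def t_generations(self) -> float:
        return self.t_years / self.generation_years


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated table."""

    founders: dict[str, np.ndarray]  # founder id -> integer haplotype
    founder_of_sample: dict[str, str]
    t_years: dict[str, float]  # founder id -> depth
    genealogy_edges: list[tuple[str, str]]
    locus_names: list[str]


# -- primitives ------------------------------------------------------------


def draw_founder(
    rng: np.random.Generator, loci: Sequence[LocusDef] = PANEL_Y23
) -> np.ndarray:
    """Uniform integer allele per (single- or multi-copy) locus slot."""
    out = []
    for d in loci:
        k = 2 if d.multi_copy else 1
        out.extend(
            rng.integers(int(np.ceil(d.min_repeats)),
                         int(np.floor(d.max_repeats)) + 1, size=k)
        )
    return np.array(out, dtype=int)


def _mutate(
    allele: int, n_steps: int, lo: int, hi: int, rng: np.random.Generator
) -> int:
    """Apply n single steps of +-1 with reflection at [lo, hi]."""
    a = allele
    for _ in range(n_steps):
        a += rng.choice((-1, 1))
        if a < lo:
            a = lo + (lo - a)
        elif a > hi:
            a = hi - (a - hi)
    return a


def _slot_bounds(loci: Sequence[LocusDef]) -> list[tuple[int, int]]:
    bounds = []
    for d in loci:
        k = 2 if d.multi_copy else 1
        bounds.extend(
            [(int(np.ceil(d.min_repeats)), int(np.floor(d.max_repeats)))] * k
        )
    return bounds


def evolve(
    founder: np.ndarray,
    t_generations: float,
    mutation_rate: float,
    rng: np.random.Generator,
    loci: Sequence[LocusDef] = PANEL_Y23,
) -> np.ndarray:
    """One star-genealogy lineage: per locus, Poisson(mu * g) mutations of
    +-1 each, reflected at the locus allele range."""
    if t_generations < 0:
        raise ValueError("time must be >= 0")
    bounds = _slot_bounds(loci)
    hap = np.array(founder, dtype=int)
    counts = rng.poisson(mutation_rate * t_generations, size=len(hap))
    for i, (m, (lo, hi)) in enumerate(zip(counts, bounds)):
        if m:
            hap[i] = _mutate(hap[i], int(m), lo, hi, rng)
    return hap


def _coalescent_sample(
    founder: np.ndarray,
    n: int,
    t_generations: float,
    mutation_rate: float,
    rng: np.random.Generator,
    loci: Sequence[LocusDef],
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Evolve n lineages down a Kingman topology whose root is rescaled to
    sit t_generations before the present; mutations fall on branches.
    Returns (haplotypes, parent-child edges over internal node ids)."""
    if n == 1:
        return evolve(founder, t_generations, mutation_rate, rng, loci)[None, :], []
    # coalescent intervals (units arbitrary — rescaled to total height T)
    times = {}
    active = list(range(n))
    next_id = n
    t = 0.0
    for i in range(n):
        times[i] = 0.0
    merges = []
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        a, b = rng.choice(len(active), size=2, replace=False)
        i, j = active[a], active[b]
        merges.append((next_id, i, j))
        times[next_id] = t
        active = [x for x in active if x not in (i, j)] + [next_id]
        next_id += 1
    root = active[0]
    scale = t_generations / times[root]
    bounds = _slot_bounds(loci)
    haps: dict[int, np.ndarray] = {root: np.array(founder, dtype=int)}
    edges: list[tuple[int, int]] = []
    for parent, i, j in reversed(merges):
        for child in (i, j):
            blen = (times[parent] - times[child]) * scale
            hap = haps[parent].copy()
            counts = rng.poisson(mutation_rate * blen, size=len(hap))
            for s, (m, (lo, hi)) in enumerate(zip(counts, bounds)):
                if m:
                    hap[s] = _mutate(hap[s], int(m), lo, hi, rng)
            haps[child] = hap
            edges.append((parent, child))
    return np.vstack([haps[i] for i in range(n)]), edges


# -- table assembly --------------------------------------------------------


def _slot_names(loci: Sequence[LocusDef]) -> list[str]:
    names = []
    for d in loci:
        if d.multi_copy:
            names.extend([d.name + "a", d.name + "b"])
        else:
            names.append(d.name)
    return names


def _calls_from_ints(
    hap: np.ndarray, loci: Sequence[LocusDef]
) -> list[AlleleCall]:
    calls = []
    pos = 0
    for d in loci:
        if d.multi_copy:
            a, b = int(hap[pos]), int(hap[pos + 1])
            calls.append(AlleleCall.duplicated(a, b))
            pos += 2
        else:
            calls.append(AlleleCall.value(int(hap[pos])))
            pos += 1
    return calls


def simulate_tribe(cfg: SimulationConfig) -> tuple[HaplotypeTable, SimulationTruth]:
    """Simulate a clan-structured tribe; fully reproducible by seed."""
    rng = np.random.default_rng(cfg.seed)
    loci = cfg.loci
    names = cfg.clan_names()
    sizes = cfg.clan_sizes()

    founders: dict[str, np.ndarray] = {}
    t_years: dict[str, float] = {}
    for clan in names:
        for f in range(cfg.founders_per_clan):
            fid = f"{clan}/F{f + 1}"
            founders[fid] = draw_founder(rng, loci)
            t_years[fid] = cfg.t_years

    meta_rows = []
    call_rows = []
    founder_of: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    sample_no = 0
    for clan, size in zip(names, sizes):
        # founder choice per sample; admixture swaps in another clan's founder
        own = [f"{clan}/F{f + 1}" for f in range(cfg.founders_per_clan)]
        foreign = [fid for fid in founders if not fid.startswith(clan + "/")]
        chosen = []
        for _ in range(size):
            if foreign and rng.random() < cfg.admixture_rate:
                chosen.append(foreign[rng.integers(len(foreign))])
            else:
                chosen.append(own[rng.integers(len(own))])
        if cfg.genealogy == "star":
            for fid in chosen:
                sample_no += 1
                sid = f"S{sample_no:04d}"
                hap = evolve(
                    founders[fid], cfg.t_generations, cfg.mutation_rate, rng, loci
                )
                meta_rows.append(_meta(sid, clan, fid))
                call_rows.append(hap)
                founder_of[sid] = fid
                edges.append((fid, sid))
        else:
            by_founder: dict[str, list[int]] = {}
            for s, fid in enumerate(chosen):
                by_founder.setdefault(fid, []).append(s)
            clan_haps: dict[int, np.ndarray] = {}
            for fid, slots in sorted(by_founder.items()):
                haps, _ = _coalescent_sample(
                    founders[fid], len(slots), cfg.t_generations,
                    cfg.mutation_rate, rng, loci,
                )
                for local, s in enumerate(slots):
                    clan_haps[s] = haps[local]
            for s in range(size):
                fid = chosen[s]
                sample_no += 1
                sid = f"S{sample_no:04d}"
                meta_rows.append(_meta(sid, clan, fid))
                call_rows.append(clan_haps[s])
                founder_of[sid] = fid
                edges.append((fid, sid))

    calls = _noise(
        np.array([_calls_from_ints(h, loci) for h in call_rows], dtype=object),
        loci, cfg, rng,
    )
    table = HaplotypeTable(pd.DataFrame(meta_rows), calls, tuple(loci))
    truth = SimulationTruth(
        founders=founders,
        founder_of_sample=founder_of,
        t_years=t_years,
        genealogy_edges=edges,
        locus_names=_slot_names(loci),
    )
    return table, truth


def _meta(sid: str, clan: str, fid: str) -> dict:
    return {
        "id": sid, "tribe": "Simulated", "clan": clan,
        "haplogroup": "HG-" + fid.replace("/", "-"),
    }


def _noise(
    calls: np.ndarray,
    loci: Sequence[LocusDef],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inject null alleles and duplications at single-copy loci."""
    if cfg.null_rate == 0 and cfg.duplication_rate == 0:
        return calls
    n, m = calls.shape
    for i in range(n):
        for j, d in enumerate(loci):
            if d.multi_copy:
                continue
            u = rng.random()
            if u < cfg.null_rate:
                calls[i, j] = AlleleCall.null()
            elif u < cfg.null_rate + cfg.duplication_rate:
                base = calls[i, j].repeats
                calls[i, j] = AlleleCall.duplicated(base, base + 1)
    return calls
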