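"""Analysis of molecular variance (AMOVA) on squared distances.

One-level design partitions variance among and within populations;
the two-level design adds groups of populations (e.g., a geographic
north/south split) on top.  Sums of squares follow the classic
distance-matrix formulation: for any set S of samples,

    SSD(S) = (1 / 2|S|) * sum_{i in S} sum_{j in S} d^2_ij,

and components are obtained by equating mean squares to their
expectations with the standard unequal-sample-size coefficients:

    MS_WP          = sigma_c^2
    MS_AP(one lvl) = sigma_c^2 + n' sigma_b^2,
        n'  = (N - sum_p n_p^2 / N) / (P - 1)
    MS_AP/WG       = sigma_c^2 + n' sigma_b^2,
        n'  = (N - sum_g sum_{p in g} n_p^2 / n_g) / (P - G)
    MS_AG          = sigma_c^2 + n'' sigma_b^2 + n''' sigma_a^2,
        n''  = (sum_g sum_{p in g} n_p^2 / n_g - sum_p n_p^2 / N) / (G - 1)
        n''' = (N - sum_g n_g^2 / N) / (G - 1)

Phi-statistics: F_ST = (sigma_a^2 + sigma_b^2)/sigma_tot^2 (one level:
sigma_b^2/sigma_tot^2), F_SC = sigma_b^2/(sigma_b^2 + sigma_c^2),
F_CT = sigma_a^2/sigma_tot^2.  Negative components are reported as
computed, never truncated.

Significance is assessed by permutation: samples among populations for
F_ST and F_SC (F_SC within groups), whole populations among groups for
F_CT, with exhaustive enumeration when fewer distinct rearrangements
exist than permutations requested.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .distance import DistanceMatrix

SQUARED_METRICS = {"squared_steps", "hamming"}


@dataclass(frozen=True)
class Partition:
    """Sample -> population assignment, optionally population -> group."""

    populations: tuple[str, ...]
    groups: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.groups is not None:
            missing = set(self.populations) - set(self.groups)
            if missing:
                raise ValueError(f"populations without a group: {sorted(missing)}")

    @property
    def has_groups(self) -> bool:
        return self.groups is not None

    def group_labels(self) -> tuple[str, ...] | None:
        if self.groups is None:
            return None
        return tuple(self.groups[p] for p in self.populations)


@dataclass
class AMOVAResult:
    sigma_a: float | None  # among groups; None for one-level designs
    sigma_b: float  # among populations (within groups)
    sigma_c: float  # within populations
    percent: dict[str, float]
    fst: float
    fsc: float | None
    fct: float | None
    df: dict[str, int]
    ss: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    seed: int | None = None

    @property
    def sigma_total(self) -> float:
        return (self.sigma_a or 0.0) + self.sigma_b + self.sigma_c


# -- sums of squares -------------------------------------------------------


def _ssd(d2: np.ndarray, idx: np.ndarray) -> float:
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2.0 * len(idx)))


def _codes(labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    uniq = list(dict.fromkeys(labels))
    lut = {u: i for i, u in enumerate(uniq)}
    return np.array([lut[x] for x in labels]), uniq


def one_level_components(
    d2: np.ndarray, pops: np.ndarray
) -> tuple[float, float, dict[str, float]]:
    """(sigma_among, sigma_within, extras) for a one-level design."""
    N = len(pops)
    codes = np.unique(pops)
    sizes = np.array([(pops == c).sum() for c in codes], dtype=float)
    P = len(codes)
    if P < 2:
        raise ValueError("need >= 2 populations")
    if (sizes < 2).any():
        raise ValueError("every population needs n >= 2")
    ssd_t = _ssd(d2, np.arange(N))
    ssd_wp = sum(_ssd(d2, np.flatnonzero(pops == c)) for c in codes)
    ssd_ap = ssd_t - ssd_wp
    df_ap, df_wp = P - 1, N - P
    ms_wp = ssd_wp / df_wp
    ms_ap = ssd_ap / df_ap
    n_prime = (N - float(np.sum(sizes**2)) / N) / df_ap
    sigma_c = ms_wp
    sigma_b = (ms_ap - ms_wp) / n_prime
    extras = {
        "ss_among": ssd_ap, "ss_within": ssd_wp,
        "df_among": df_ap, "df_within": df_wp,
    }
    return sigma_b, sigma_c, extras


def two_level_components(
    d2: np.ndarray, pops: np.ndarray, groups: np.ndarray
) -> tuple[float, float, float, dict[str, float]]:
    """(sigma_a, sigma_b, sigma_c, extras) for a group/population design."""
    N = len(pops)
    pop_codes = np.unique(pops)
    grp_codes = np.unique(groups)
    P, G = len(pop_codes), len(grp_codes)
    if G < 2:
        raise ValueError("need >= 2 groups")
    sizes = {c: float((pops == c).sum()) for c in pop_codes}
    if any(s < 2 for s in sizes.values()):
        raise ValueError("every population needs n >= 2")
    grp_of_pop = {}
    for c in pop_codes:
        gs = np.unique(groups[pops == c])
        if len(gs) != 1:
            raise ValueError("population split across groups")
        grp_of_pop[c] = gs[0]

    ssd_t = _ssd(d2, np.arange(N))
    ssd_wp = sum(_ssd(d2, np.flatnonzero(pops == c)) for c in pop_codes)
    ssd_wg = sum(_ssd(d2, np.flatnonzero(groups == g)) for g in grp_codes)
    ssd_ap_wg = ssd_wg - ssd_wp
    ssd_ag = ssd_t - ssd_wg

    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    if df_ap < 1:
        raise ValueError("need more populations than groups")
    ms_wp = ssd_wp / df_wp
    ms_ap = ssd_ap_wg / df_ap
    ms_ag = ssd_ag / df_ag

    n_g = {g: float((groups == g).sum()) for g in grp_codes}
    sum_np2_over_ng = sum(
        sum(sizes[c] ** 2 for c in pop_codes if grp_of_pop[c] == g) / n_g[g]
        for g in grp_codes
    )
    sum_np2_over_N = sum(s**2 for s in sizes.values()) / N
    n1 = (N - sum_np2_over_ng) / df_ap
    n2 = (sum_np2_over_ng - sum_np2_over_N) / df_ag
    n3 = (N - sum(v**2 for v in n_g.values()) / N) / df_ag

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    extras = {
        "ss_among_groups": ssd_ag, "ss_among_pops": ssd_ap_wg,
        "ss_within": ssd_wp, "df_among_groups": df_ag,
        "df_among_pops": df_ap, "df_within": df_wp,
    }
    return sigma_a, sigma_b, sigma_c, extras


def _phi(num: float, den: float) -> float:
    return 0.0 if den == 0 else num / den


# -- public API ------------------------------------------------------------


def amova(
    dist: DistanceMatrix,
    part: Partition,
    n_permutations: int = 0,
    seed: int | None = None,
) -> AMOVAResult:
    """AMOVA variance components and Phi-statistics, with optional
    permutation p-values (requires ``seed`` when permuting)."""
    if dist.metric not in SQUARED_METRICS:
        raise ValueError(
            f"AMOVA requires squared distances, got metric {dist.metric!r}"
        )
    if len(part.populations) != len(dist.labels):
        raise ValueError("partition does not match distance matrix")
    d2 = dist.values
    pops, _ = _codes(part.populations)

    if part.has_groups:
        groups, _ = _codes(part.group_labels())
        sa, sb, sc, ex = two_level_components(d2, pops, groups)
        tot = sa + sb + sc
        result = AMOVAResult(
            sigma_a=sa, sigma_b=sb, sigma_c=sc,
            percent={
                "among_groups": _phi(sa, tot) * 100,
                "among_populations": _phi(sb, tot) * 100,
                "within_populations": _phi(sc, tot) * 100,
            },
            fst=_phi(sa + sb, tot),
            fsc=_phi(sb, sb + sc),
            fct=_phi(sa, tot),
            df={k: int(v) for k, v in ex.items() if k.startswith("df")},
            ss={k: v for k, v in ex.items() if k.startswith("ss")},
        )
    else:
        sb, sc, ex = one_level_components(d2, pops)
        tot = sb + sc
        result = AMOVAResult(
            sigma_a=None, sigma_b=sb, sigma_c=sc,
            percent={
                "among_populations": _phi(sb, tot) * 100,
                "within_populations": _phi(sc, tot) * 100,
            },
            fst=_phi(sb, tot),
            fsc=None, fct=None,
            df={k: int(v) for k, v in ex.items() if k.startswith("df")},
            ss={k: v for k, v in ex.items() if k.startswith("ss")},
        )

    if n_permutations > 0:
        if seed is None:
            raise ValueError("permutation testing requires a seed")
        stats = ["FST"] if not part.has_groups else ["FST", "FSC", "FCT"]
        for s in stats:
            result.p_values[s] = permutation_test(
                dist, part, s, n_permutations, seed
            )
        result.n_permutations = n_permutations
        result.seed = seed
    return result


# -- permutation inference -------------------------------------------------


def _statistic(d2: np.ndarray, pops: np.ndarray,
               groups: np.ndarray | None, which: str) -> float:
    if groups is None:
        sb, sc, _ = one_level_components(d2, pops)
        return _phi(sb, sb + sc)
    sa, sb, sc, _ = two_level_components(d2, pops, groups)
    tot = sa + sb + sc
    if which == "FST":
        return _phi(sa + sb, tot)
    if which == "FSC":
        return _phi(sb, sb + sc)
    if which == "FCT":
        return _phi(sa, tot)
    raise ValueError(f"unknown statistic {which!r}")


def _multinomial(sizes: Sequence[int]) -> int:
    n = sum(sizes)
    out = 1
    for s in sizes:
        out *= math.comb(n, s)
        n -= s
    return out


def _assignments(indices: list[int], sizes: list[int]):
    """Yield all distinct splits of ``indices`` into blocks of given sizes."""
    if len(sizes) == 1:
        yield (tuple(indices),)
        return
    for block in itertools.combinations(indices, sizes[0]):
        rest = [i for i in indices if i not in block]
        for tail in _assignments(rest, sizes[1:]):
            yield (block,) + tail


def permutation_test(
    dist: DistanceMatrix,
    part: Partition,
    statistic: str = "FST",
    n_permutations: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for one Phi-statistic.

    F_ST / F_SC permute samples among populations (F_SC only within each
    group); F_CT permutes whole populations among groups.  Monte-Carlo
    p = (#{perm >= obs} + 1)/(n_perm + 1); exhaustive enumeration (exact
    fraction) replaces sampling when fewer distinct rearrangements exist.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    d2 = dist.values
    pops, _ = _codes(part.populations)
    groups = None
    if part.has_groups:
        groups, _ = _codes(part.group_labels())
    if statistic in ("FSC", "FCT") and groups is None:
        raise ValueError(f"{statistic} requires a two-level partition")

    obs = _statistic(d2, pops, groups, statistic)
    rng = np.random.default_rng(seed)
    eps = 1e-12

    if statistic == "FCT":
        return _permute_fct(d2, pops, groups, obs, n_permutations, rng, eps)
    if statistic == "FSC":
        return _permute_within_groups(
            d2, pops, groups, obs, n_permutations, rng, eps
        )
    return _permute_global(d2, pops, groups, obs, n_permutations, rng, eps)


def _permute_global(d2, pops, groups, obs, n_perm, rng, eps) -> float:
    codes, counts = np.unique(pops, return_counts=True)
    total = _multinomial(counts.tolist())
    if total <= n_perm:
        hits = denom = 0
        for split in _assignments(list(range(len(pops))), counts.tolist()):
            perm = np.empty(len(pops), dtype=int)
            for c, block in zip(codes, split):
                perm[list(block)] = c
            g = groups  # group membership follows sample position
            if _statistic(d2, perm, g, "FST") >= obs - eps:
                hits += 1
            denom += 1
        return hits / denom
    hits = 0
    for _ in range(n_perm):
        perm = pops[rng.permutation(len(pops))]
        if _statistic(d2, perm, groups, "FST") >= obs - eps:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _permute_within_groups(d2, pops, groups, obs, n_perm, rng, eps) -> float:
    total = 1
    for g in np.unique(groups):
        _, counts = np.unique(pops[groups == g], return_counts=True)
        total *= _multinomial(counts.tolist())
        if total > n_perm:
            break
    if total <= n_perm:
        # exhaustive: product of per-group splits
        per_group = []
        grp_codes = np.unique(groups)
        for g in grp_codes:
            idx = np.flatnonzero(groups == g)
            codes, counts = np.unique(pops[idx], return_counts=True)
            opts = []
            for split in _assignments(idx.tolist(), counts.tolist()):
                assign = {}
                for c, block in zip(codes, split):
                    for i in block:
                        assign[i] = c
                opts.append(assign)
            per_group.append(opts)
        hits = denom = 0
        for combo in itertools.product(*per_group):
            perm = pops.copy()
            for assign in combo:
                for i, c in assign.items():
                    perm[i] = c
            if _statistic(d2, perm, groups, "FSC") >= obs - eps:
                hits += 1
            denom += 1
        return hits / denom
    hits = 0
    for _ in range(n_perm):
        perm = pops.copy()
        for g in np.unique(groups):
            idx = np.flatnonzero(groups == g)
            perm[idx] = perm[idx][rng.permutation(len(idx))]
        if _statistic(d2, perm, groups, "FSC") >= obs - eps:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _permute_fct(d2, pops, groups, obs, n_perm, rng, eps) -> float:
    pop_codes = np.unique(pops)
    grp_of_pop = np.array([np.unique(groups[pops == c])[0] for c in pop_codes])
    grp_codes, grp_counts = np.unique(grp_of_pop, return_counts=True)
    total = _multinomial(grp_counts.tolist())

    def stat_for(pop_to_grp: np.ndarray) -> float:
        g = np.empty(len(pops), dtype=int)
        for c, gg in zip(pop_codes, pop_to_grp):
            g[pops == c] = gg
        return _statistic(d2, pops, g, "FCT")

    if total <= n_perm:
        hits = denom = 0
        for split in _assignments(list(range(len(pop_codes))), grp_counts.tolist()):
            assign = np.empty(len(pop_codes), dtype=int)
            for gg, block in zip(grp_codes, split):
                assign[list(block)] = gg
            if stat_for(assign) >= obs - eps:
                hits += 1
            denom += 1
        return hits / denom
    hits = 0
    for _ in range(n_perm):
        assign = grp_of_pop[rng.permutation(len(pop_codes))]
        if stat_for(assign) >= obs - eps:
            hits += 1
    return (hits + 1) / (n_perm + 1)
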