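"""Mutational-step, R_ST and Nei standard genetic distances.

Step distances operate on single-copy loci only (DYS385 copies cannot be
paired across haplotypes) with microvariants rounded to the nearest
integer.  R_ST is the microsatellite fixation index obtained from the
variance components of a two-population analysis of molecular variance on
squared-step distances.  Nei's standard distance D = -ln(I) compares
per-locus allele frequency spectra between populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import _locus_spectrum
from .io import AlleleCall, HaplotypeTable
from .loci import RST_DEFAULT

VALID_METRICS = ("steps", "squared_steps", "rst", "nei_d", "hamming")


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix tagged with its metric."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.metric not in VALID_METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("label/value shape mismatch")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix not symmetric")

    def row_means(self) -> pd.Series:
        """Mean off-diagonal distance per row (the 'mean d' summary)."""
        v = self.values.copy()
        np.fill_diagonal(v, np.nan)
        with np.errstate(invalid="ignore"):
            means = np.nanmean(v, axis=1)
        return pd.Series(means, index=list(self.labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))


# -- haplotype-level step distances ---------------------------------------


def _to_number(x: object) -> float:
    """Integer repeat count or NaN for null/duplicated calls."""
    if isinstance(x, AlleleCall):
        if x.is_value:
            return float(math.floor(x.repeats + 0.5))  # round half up
        return float("nan")
    if x is None:
        return float("nan")
    return float(math.floor(float(x) + 0.5))


def step_distance(
    a: Sequence[object], b: Sequence[object], mode: str = "absolute"
) -> float:
    """Sum of per-locus |differences| (or squared differences) between two
    haplotypes, skipping loci where either call is missing (pairwise
    deletion of nulls and duplications)."""
    if len(a) != len(b):
        raise ValueError("haplotypes differ in locus count")
    xs = np.array([_to_number(v) for v in a])
    ys = np.array([_to_number(v) for v in b])
    ok = ~(np.isnan(xs) | np.isnan(ys))
    if not ok.any():
        raise ValueError("no shared non-null loci")
    d = xs[ok] - ys[ok]
    if mode == "absolute":
        return float(np.abs(d).sum())
    if mode == "squared":
        return float((d * d).sum())
    raise ValueError(f"unknown mode {mode!r}")


def sample_profiles(
    table: HaplotypeTable,
    loci: Sequence[str] | None = None,
    deletion: str = "pairwise",
) -> tuple[np.ndarray, list[str]]:
    """Integer allele matrix (samples x loci) with NaN for null/duplicated
    calls.  ``deletion='listwise'`` drops samples with any missing call.
    Default loci: the typical-marker panel minus DYS385 (15 loci)."""
    if loci is None:
        loci = [n for n in RST_DEFAULT if n in table.locus_names]
    names = list(loci)
    for n in names:
        if table.loci[table.locus_index(n)].multi_copy:
            raise ValueError(f"step distances undefined at multi-copy locus {n}")
    mat = np.full((table.n_samples, len(names)), np.nan)
    for j, n in enumerate(names):
        col = table.column(n)
        mat[:, j] = [_to_number(c) for c in col]
    if deletion == "listwise":
        keep = ~np.isnan(mat).any(axis=1)
        mat = mat[keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion policy {deletion!r}")
    return mat, names


def squared_step_matrix(profiles: np.ndarray) -> np.ndarray:
    """Pairwise squared-step distances with per-pair (pairwise) deletion
    of missing loci."""
    n = profiles.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        diff = profiles - profiles[i]
        with np.errstate(invalid="ignore"):
            sq = np.nansum(diff * diff, axis=1)
        out[i] = sq
    np.fill_diagonal(out, 0.0)
    return (out + out.T) / 2.0


# -- population-level distances -------------------------------------------


def rst_pairwise(
    pop_a: HaplotypeTable,
    pop_b: HaplotypeTable,
    loci: Sequence[str] | None = None,
    deletion: str = "pairwise",
) -> float:
    """R_ST between two populations: among-population variance fraction of
    a one-level AMOVA on squared-step distances.  May be slightly
    negative; reported unclamped."""
    from .amova import one_level_components

    if pop_a.n_samples < 2 or pop_b.n_samples < 2:
        raise ValueError("R_ST requires >= 2 samples per population")
    prof_a, names = sample_profiles(pop_a, loci, deletion)
    prof_b, _ = sample_profiles(pop_b, names, deletion)
    profiles = np.vstack([prof_a, prof_b])
    d2 = squared_step_matrix(profiles)
    pops = np.array([0] * prof_a.shape[0] + [1] * prof_b.shape[0])
    sigma_b, sigma_c, _ = one_level_components(d2, pops)
    total = sigma_b + sigma_c
    return 0.0 if total == 0 else float(sigma_b / total)


def nei_standard_distance(
    pop_a: HaplotypeTable,
    pop_b: HaplotypeTable,
    loci: Sequence[str] | None = None,
) -> float:
    """Nei's (1972) standard genetic distance D = -ln(J_ab/sqrt(J_a J_b)),
    with homozygosities J averaged arithmetically over loci.

    Returns +inf when the two populations share no alleles at any locus
    (J_ab = 0); exactly 0 for identical frequency sets.
    """
    names = list(loci) if loci is not None else pop_a.locus_names
    ja = jb = jab = 0.0
    for name in names:
        sa = _locus_spectrum(pop_a, name)
        sb = _locus_spectrum(pop_b, name)
        fa = dict(zip(sa.labels, sa.frequencies))
        fb = dict(zip(sb.labels, sb.frequencies))
        ja += sum(x * x for x in fa.values())
        jb += sum(x * x for x in fb.values())
        jab += sum(fa[k] * fb[k] for k in fa.keys() & fb.keys())
    L = len(names)
    ja, jb, jab = ja / L, jb / L, jab / L
    if jab == 0:
        return float("inf")
    identity = jab / math.sqrt(ja * jb)
    return max(0.0, -math.log(min(identity, 1.0)))


def distance_matrix(
    populations: Mapping[str, HaplotypeTable],
    metric: str = "rst",
    loci: Sequence[str] | None = None,
) -> DistanceMatrix:
    """All pairwise population distances under ``metric`` ('rst' or
    'nei_d')."""
    labels = tuple(populations.keys())
    if len(labels) < 2:
        raise ValueError("need >= 2 populations")
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = populations[labels[i]], populations[labels[j]]
            if metric == "rst":
                d = rst_pairwise(a, b, loci)
            elif metric == "nei_d":
                d = nei_standard_distance(a, b, loci)
            else:
                raise ValueError(f"unsupported population metric {metric!r}")
            out[i, j] = out[j, i] = d
    return DistanceMatrix(labels, out, metric)
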