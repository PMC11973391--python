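"""Haplotype- and locus-level diversity and forensic statistics.

Core quantity: Nei's unbiased gene diversity applied to haplotype,
haplogroup, or per-locus allele frequency spectra,

    HD = n (1 - sum p_i^2) / (n - 1),

with p_i the frequency of the i-th distinct class in a sample of size n.
Companion statistics: haplotype match probability (HMP = sum p_i^2),
discrimination capacity (distinct/total), unique-haplotype fraction, and
the per-locus forensic panel (GD, RMP, PD, PIC, PE, TPI).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import HaplotypeTable


@dataclass(frozen=True)
class FrequencySpectrum:
    """Distinct classes with their counts; counts sorted descending,
    ties broken lexicographically by label."""

    labels: tuple[str, ...]
    counts: tuple[int, ...]
    n: int

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.counts):
            raise ValueError("labels and counts differ in length")
        if any(c < 1 for c in self.counts):
            raise ValueError("all counts must be >= 1")
        if sum(self.counts) != self.n:
            raise ValueError("counts must sum to n")

    @classmethod
    def from_counts(
        cls, counts: Sequence[int], labels: Sequence[str] | None = None
    ) -> "FrequencySpectrum":
        if labels is None:
            labels = [f"h{i}" for i in range(len(counts))]
        order = sorted(range(len(counts)), key=lambda i: (-counts[i], str(labels[i])))
        return cls(
            labels=tuple(str(labels[i]) for i in order),
            counts=tuple(int(counts[i]) for i in order),
            n=int(sum(counts)),
        )

    @property
    def frequencies(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n

    @property
    def k_distinct(self) -> int:
        return len(self.counts)


def spectrum(
    table: HaplotypeTable,
    key: str = "haplotype",
    *,
    clan: str | None = None,
    loci: Sequence[str] | None = None,
    null_as_allele: bool = False,
) -> FrequencySpectrum:
    """Frequency spectrum of a sample set under a grouping key.

    key='haplotype': two samples share a class iff every locus call is
    identical (nulls equal nulls; DYS385 compared as an unordered pair).
    key='haplogroup': the haplogroup label column.
    key=<locus name>: the allele spectrum at one locus — null calls are
    excluded (unless ``null_as_allele``), duplications contribute both
    alleles, DYS385 contributes unordered combination labels.
    """
    t = table if clan is None else table.subset(clan=clan)
    if t.n_samples == 0:
        raise ValueError("empty sample subset")
    if key == "haplotype":
        keys = ["|".join(t.haplotype_key(i, loci)) for i in range(t.n_samples)]
    elif key == "haplogroup":
        keys = [str(x) for x in t.meta["haplogroup"]]
    else:
        return _locus_spectrum(t, key, null_as_allele=null_as_allele)
    labels, counts = np.unique(keys, return_counts=True)
    return FrequencySpectrum.from_counts(counts.tolist(), labels.tolist())


def _locus_spectrum(
    table: HaplotypeTable, locus: str, *, null_as_allele: bool = False
) -> FrequencySpectrum:
    j = table.locus_index(locus)
    d = table.loci[j]
    alleles: list[str] = []
    for c in table.calls[:, j]:
        if c.is_null:
            if null_as_allele:
                alleles.append("null")
            continue
        if d.multi_copy:
            alleles.append(c.token())  # unordered combination label
        elif c.is_pair:
            alleles.extend(c.token().split(","))  # duplication: both copies
        else:
            alleles.append(c.token())
    if not alleles:
        raise ValueError(f"locus {locus} has no non-null calls")
    labels, counts = np.unique(alleles, return_counts=True)
    return FrequencySpectrum.from_counts(counts.tolist(), labels.tolist())


# -- scalar statistics -----------------------------------------------------


def nei_diversity(s: FrequencySpectrum) -> float:
    """Unbiased gene/haplotype diversity n(1 - sum p_i^2)/(n - 1)."""
    if s.n < 2:
        raise ValueError("diversity requires n >= 2")
    p = s.frequencies
    return float(s.n * (1.0 - np.sum(p * p)) / (s.n - 1))


def match_probability(s: FrequencySpectrum) -> float:
    """Probability two random individuals match: sum p_i^2."""
    p = s.frequencies
    return float(np.sum(p * p))


def discrimination_capacity(s: FrequencySpectrum) -> float:
    """Distinct classes over sample size."""
    return s.k_distinct / s.n


def unique_fraction(s: FrequencySpectrum) -> float:
    """Fraction of individuals carrying a singleton class."""
    return sum(1 for c in s.counts if c == 1) / s.n


@dataclass(frozen=True)
class DiversityPanel:
    """One row of the tribe/clan comparison table."""

    population: str
    n: int
    k_distinct: int
    unique_fraction: float
    discrimination_capacity: float
    match_probability: float
    nei_diversity: float


def diversity_panel(
    table: HaplotypeTable,
    population: str = "all",
    *,
    key: str = "haplotype",
    clan: str | None = None,
) -> DiversityPanel:
    s = spectrum(table, key=key, clan=clan)
    return DiversityPanel(
        population=population,
        n=s.n,
        k_distinct=s.k_distinct,
        unique_fraction=unique_fraction(s),
        discrimination_capacity=discrimination_capacity(s),
        match_probability=match_probability(s),
        nei_diversity=nei_diversity(s),
    )


def summarize(table: HaplotypeTable, by: str = "clan", key: str = "haplotype") -> pd.DataFrame:
    """Tribe-level plus per-group diversity panels as a DataFrame."""
    rows = [diversity_panel(table, "all", key=key)]
    if by == "clan":
        for name in pd.unique(table.meta["clan"].astype(str)):
            if name:
                rows.append(diversity_panel(table, name, key=key, clan=name))
    return pd.DataFrame([r.__dict__ for r in rows])


# -- forensic per-locus panel ----------------------------------------------


@dataclass(frozen=True)
class ForensicLocusPanel:
    locus: str
    allele_count: int
    gene_diversity: float
    random_match_probability: float
    power_of_discrimination: float
    pic: float
    power_of_exclusion: float
    typical_paternity_index: float


def forensic_panel(
    table: HaplotypeTable, locus: str, *, null_as_allele: bool = False
) -> ForensicLocusPanel:
    """Per-locus forensic statistics on the allele spectrum.

    GD is the unbiased Nei diversity of allele frequencies; RMP = sum p^2;
    PD = 1 - RMP; PIC = 1 - sum p^2 - (sum p^2)^2 + sum p^4.  PE and TPI
    follow the conventional diploid formulas adapted to haploid data with
    h = GD and H = 1 - h: PE = h^2 (1 - 2 h H^2), TPI = 1/(2H).
    """
    s = _locus_spectrum(table, locus, null_as_allele=null_as_allele)
    p = s.frequencies
    sp2 = float(np.sum(p**2))
    sp4 = float(np.sum(p**4))
    gd = nei_diversity(s)
    h = gd
    H = 1.0 - h
    pe = h * h * (1.0 - 2.0 * h * H * H)
    tpi = float("inf") if H == 0 else 1.0 / (2.0 * H)
    return ForensicLocusPanel(
        locus=locus,
        allele_count=s.k_distinct,
        gene_diversity=gd,
        random_match_probability=sp2,
        power_of_discrimination=1.0 - sp2,
        pic=1.0 - sp2 - sp2 * sp2 + sp4,
        power_of_exclusion=pe,
        typical_paternity_index=tpi,
    )


def forensic_table(table: HaplotypeTable) -> pd.DataFrame:
    rows = [forensic_panel(table, d.name) for d in table.loci]
    return pd.DataFrame([r.__dict__ for r in rows])
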