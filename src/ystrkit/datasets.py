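"""Published summary tables bundled for worked examples and cross-checks.

The package ships the printed Y-chromosome haplogroup frequency table of
the Zhetiru tribe study (350 Kazakh men in seven clans) so that the
haplogroup-diversity computation can be replayed from published numbers
without access to the per-sample YHRD deposition.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .diversity import FrequencySpectrum

#: Sample sizes of the tribe and its seven clans as published.
ZHETIRU_SAMPLE_SIZES: dict[str, int] = {
    "Zhetiru": 350,
    "Kerderi": 40,
    "Kereit": 32,
    "Ramadan": 39,
    "Tabyn": 85,
    "Tama": 36,
    "Teleu": 53,
    "Zhagalbaily": 65,
}

#: Published tribe-level haplotype summary: 350 samples, 260 distinct
#: haplotypes, 215 of them unique.
ZHETIRU_HAPLOTYPE_COUNTS: dict[str, int] = {
    "n": 350,
    "distinct": 260,
    "unique": 215,
}


def load_haplogroup_frequencies() -> pd.DataFrame:
    """Published haplogroup frequencies, indexed by haplogroup, one
    column per population (tribe + 7 clans)."""
    ref = resources.files("ystrkit.data") / "zhetiru_haplogroup_frequencies.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col="haplogroup")
    return df


def counts_from_frequencies(freqs: pd.Series, n: int) -> np.ndarray:
    """Convert printed (rounded) frequencies back to integer counts.

    Multiplies by ``n`` and rounds to the nearest integer; raises if the
    reconstructed counts do not sum exactly to ``n`` (which would mean the
    printed column is not consistent with its sample size).
    """
    counts = np.rint(np.asarray(freqs, dtype=float) * n).astype(int)
    if counts.sum() != n:
        raise ValueError(
            f"reconstructed counts sum to {counts.sum()}, expected {n}"
        )
    return counts


def haplogroup_spectrum(population: str) -> FrequencySpectrum:
    """Haplogroup frequency spectrum of one published population column."""
    df = load_haplogroup_frequencies()
    if population not in df.columns:
        raise KeyError(f"unknown population {population!r}")
    n = ZHETIRU_SAMPLE_SIZES[population]
    col = df[population]
    counts = counts_from_frequencies(col, n)
    keep = counts > 0
    return FrequencySpectrum.from_counts(
        counts[keep].tolist(), col.index[keep].tolist()
    )
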