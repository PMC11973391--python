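"""Canonical Y-STR locus panel definitions.

The default panel mirrors the 23-locus PowerPlex Y23 set: 17 "typical"
Y-STR markers plus 6 rapidly mutating loci.  DYS385 is the single
multi-copy entry (two unordered copies, a/b), so the panel is described
by 22 locus definitions covering 23 amplified loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True)
class LocusDef:
    """One Y-STR locus: name, copy number, and permitted allele range.

    ``allele_range`` bounds are validation limits (generous envelopes around
    the commercial allelic-ladder ranges), not population truths.
    """

    name: str
    min_repeats: float
    max_repeats: float
    multi_copy: bool = False

    def in_range(self, repeats: float) -> bool:
        return self.min_repeats <= repeats <= self.max_repeats


def _l(name: str, lo: float, hi: float, multi: bool = False) -> LocusDef:
    return LocusDef(name=name, min_repeats=lo, max_repeats=hi, multi_copy=multi)


#: The 23-locus panel in reporting order; DYS385 holds two unordered copies.
PANEL_Y23: tuple[LocusDef, ...] = (
    _l("DYS19", 10, 19),
    _l("DYS385", 6, 28, multi=True),
    _l("DYS389I", 9, 17),
    _l("DYS389II", 24, 36),
    _l("DYS390", 17, 28),
    _l("DYS391", 5, 16),
    _l("DYS392", 4, 20),
    _l("DYS393", 7, 18),
    _l("DYS437", 12, 18),
    _l("DYS438", 6, 14),
    _l("DYS439", 7, 17),
    _l("DYS448", 14, 24),
    _l("DYS456", 11, 23),
    _l("DYS458", 12, 24),
    _l("DYS635", 17, 27),
    _l("YGATAH4", 8, 14),
    _l("DYS481", 16, 32),
    _l("DYS533", 7, 17),
    _l("DYS549", 9, 15),
    _l("DYS570", 12, 26),
    _l("DYS576", 11, 25),
    _l("DYS643", 6, 17),
)

#: Names of the 17 "typical" markers (DYS385a/b counted as two loci).
TYPICAL_17: tuple[str, ...] = (
    "DYS19", "DYS385", "DYS389I", "DYS389II", "DYS390", "DYS391", "DYS392",
    "DYS393", "DYS437", "DYS438", "DYS439", "DYS448", "DYS456", "DYS458",
    "DYS635", "YGATAH4",
)

#: Single-copy loci of the full panel (the 21-locus network set).
NETWORK_21: tuple[str, ...] = tuple(
    d.name for d in PANEL_Y23 if not d.multi_copy
)

#: Default single-copy set for step/R_ST distances: the typical markers
#: minus the unpairable DYS385 copies (15 loci).
RST_DEFAULT: tuple[str, ...] = tuple(
    n for n in TYPICAL_17 if n != "DYS385"
)


def locus_count(defs: Sequence[LocusDef]) -> int:
    """Number of amplified loci (multi-copy entries count twice)."""
    return sum(2 if d.multi_copy else 1 for d in defs)


def get_locus(defs: Sequence[LocusDef], name: str) -> LocusDef:
    for d in defs:
        if d.name == name:
            return d
    raise KeyError(f"unknown locus {name!r}")


def single_copy_names(defs: Iterable[LocusDef]) -> list[str]:
    return [d.name for d in defs if not d.multi_copy]
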