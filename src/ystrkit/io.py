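"""Reading, validating and writing Y-STR haplotype tables.

Tables are delimited text (CSV or TSV), one row per individual, with
metadata columns (``id``, ``tribe``, ``clan``, ``haplogroup``) followed by
one column per locus.  DYS385 may appear as two columns (``DYS385a`` /
``DYS385b``) or as one ``DYS385`` column holding a paired token such as
``"13,17"``.

Allele pathologies observed in real casework data are first-class states:
null alleles (deletions; token ``0``, ``-`` or ``null``), microvariant
alleles (fractional repeats such as ``13.2``), and duplications (two
alleles at a nominally single-copy locus, token ``"15,16"``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .loci import PANEL_Y23, LocusDef, get_locus

META_COLUMNS = ("id", "tribe", "clan", "haplogroup")

#: tokens accepted (case-insensitively) as a null allele on input
NULL_TOKENS = frozenset({"0", "-", "null"})


class ParseError(ValueError):
    """Raised when a token or a table fails Y-STR validation."""


class AlleleState(enum.Enum):
    VALUE = "value"
    NULL = "null"
    DUPLICATED = "duplicated"


_VALID_FRACTIONS = (0, 1, 2, 3)


def _check_repeats(x: float) -> float:
    if x <= 0:
        raise ParseError(f"repeat count must be positive, got {x}")
    frac = round(x * 10) % 10
    if frac not in _VALID_FRACTIONS:
        raise ParseError(f"invalid microvariant fraction in allele {x}")
    return round(x, 1)


@dataclass(frozen=True)
class AlleleCall:
    """One locus observation: a value (possibly microvariant), a null, or a
    duplication (an ordered pair at a nominally single-copy locus).

    DYS385, the panel's one genuinely multi-copy locus, reuses the pair
    representation: its two copies are stored sorted ascending, like a
    duplication, because copies cannot be assigned to chromosomes.
    """

    state: AlleleState
    repeats: float | None = None
    pair: tuple[float, float] | None = None

    @classmethod
    def value(cls, repeats: float) -> "AlleleCall":
        return cls(AlleleState.VALUE, repeats=_check_repeats(float(repeats)))

    @classmethod
    def null(cls) -> "AlleleCall":
        return cls(AlleleState.NULL)

    @classmethod
    def duplicated(cls, a: float, b: float) -> "AlleleCall":
        a, b = sorted((_check_repeats(float(a)), _check_repeats(float(b))))
        return cls(AlleleState.DUPLICATED, pair=(a, b))

    @property
    def is_null(self) -> bool:
        return self.state is AlleleState.NULL

    @property
    def is_value(self) -> bool:
        return self.state is AlleleState.VALUE

    @property
    def is_pair(self) -> bool:
        return self.state is AlleleState.DUPLICATED

    @property
    def is_microvariant(self) -> bool:
        def frac(x: float) -> bool:
            return round(x * 10) % 10 != 0

        if self.is_value:
            return frac(self.repeats)  # type: ignore[arg-type]
        if self.is_pair:
            return any(frac(x) for x in self.pair)  # type: ignore[union-attr]
        return False

    def token(self) -> str:
        """Canonical text encoding (the inverse of :func:`parse_allele`)."""
        if self.is_null:
            return "0"
        if self.is_value:
            return _fmt(self.repeats)  # type: ignore[arg-type]
        a, b = self.pair  # type: ignore[misc]
        return f"{_fmt(a)},{_fmt(b)}"


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:.1f}"


def _parse_number(tok: str, where: str) -> float:
    try:
        x = float(tok)
    except ValueError:
        raise ParseError(f"non-numeric allele token {tok!r} {where}") from None
    return x


def parse_allele(token: str, locus: LocusDef, *, where: str = "") -> AlleleCall:
    """Parse one allele token for ``locus``.

    ``"15"`` and ``"13.2"`` become values; ``"0"``, ``"-"`` and ``"null"``
    (any case) become nulls; ``"15,16"`` or ``"15/16"`` becomes a sorted
    pair — a duplication at a single-copy locus, the two copies at DYS385.
    """
    tok = token.strip()
    if not tok:
        raise ParseError(f"empty allele token {where}")
    if tok.lower() in NULL_TOKENS:
        return AlleleCall.null()
    parts = tok.replace("/", ",").split(",")
    if len(parts) > 2:
        raise ParseError(f">2 alleles in token {token!r} {where}")
    values = [_parse_number(p.strip(), where) for p in parts]
    for v in values:
        if v <= 0:
            raise ParseError(f"non-positive allele {v} {where}")
        if not locus.in_range(v):
            raise ParseError(
                f"allele {v} outside permitted range "
                f"[{locus.min_repeats}, {locus.max_repeats}] {where}"
            )
    if len(values) == 2:
        return AlleleCall.duplicated(*values)
    if locus.multi_copy:
        # a lone token at DYS385 means both copies share the same length
        return AlleleCall.duplicated(values[0], values[0])
    return AlleleCall.value(values[0])


@dataclass
class HaplotypeTable:
    """Individuals x loci grid of :class:`AlleleCall` plus sample metadata.

    ``meta`` holds one row per sample (``id`` unique; ``tribe``, ``clan``,
    ``haplogroup`` and any extra columns preserved from input).  ``calls``
    is an object array aligned ``(sample, locus definition)``.
    """

    meta: pd.DataFrame
    calls: np.ndarray  # shape (n_samples, n_locus_defs), dtype=object
    loci: tuple[LocusDef, ...] = field(default=PANEL_Y23)

    def __post_init__(self) -> None:
        self.meta = self.meta.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=object)
        n, m = self.calls.shape
        if n != len(self.meta):
            raise ParseError("metadata and call grid disagree on sample count")
        if m != len(self.loci):
            raise ParseError("call grid and locus panel disagree on locus count")
        ids = self.meta["id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ParseError(f"duplicate sample id {dup!r}")
        for i in range(n):
            for j in range(m):
                if not isinstance(self.calls[i, j], AlleleCall):
                    raise ParseError(
                        f"missing call for sample {ids.iloc[i]!r} "
                        f"at locus {self.loci[j].name}"
                    )

    # -- accessors ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.meta)

    @property
    def locus_names(self) -> list[str]:
        return [d.name for d in self.loci]

    def locus_index(self, name: str) -> int:
        try:
            return self.locus_names.index(name)
        except ValueError:
            raise KeyError(f"unknown locus {name!r}") from None

    def call(self, sample: int, locus: str) -> AlleleCall:
        return self.calls[sample, self.locus_index(locus)]

    def column(self, locus: str) -> list[AlleleCall]:
        return list(self.calls[:, self.locus_index(locus)])

    def haplotype_key(self, sample: int, loci: Sequence[str] | None = None) -> tuple[str, ...]:
        """Exact-match haplotype key: canonical token per locus.

        Nulls compare equal to nulls and DYS385 compares as an unordered
        pair because tokens are canonical.
        """
        names = list(loci) if loci is not None else self.locus_names
        return tuple(self.call(sample, n).token() for n in names)

    def subset(
        self,
        index: Sequence[int] | np.ndarray | None = None,
        *,
        clan: str | None = None,
        tribe: str | None = None,
    ) -> "HaplotypeTable":
        mask = np.ones(self.n_samples, dtype=bool)
        if clan is not None:
            mask &= (self.meta["clan"].astype(str) == clan).to_numpy()
        if tribe is not None:
            mask &= (self.meta["tribe"].astype(str) == tribe).to_numpy()
        idx = np.flatnonzero(mask)
        if index is not None:
            sel = np.asarray(index)
            if sel.dtype == bool:
                sel = np.flatnonzero(sel)
            idx = np.intersect1d(idx, sel.astype(int))
        if len(idx) == 0:
            raise ValueError("subset selects no samples")
        return HaplotypeTable(self.meta.iloc[idx], self.calls[idx], self.loci)

    def groupby_clan(self) -> dict[str, "HaplotypeTable"]:
        return {
            str(c): self.subset(clan=str(c))
            for c in pd.unique(self.meta["clan"].astype(str))
        }


# -- reading ---------------------------------------------------------------


def _dialect_sep(dialect: str | None, path: Path) -> str:
    if dialect == "comma":
        return ","
    if dialect == "tab":
        return "\t"
    if dialect is None:
        return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raise ValueError(f"unknown dialect {dialect!r}")


def read_table(
    path: str | Path,
    dialect: str | None = None,
    locus_panel: Sequence[LocusDef] = PANEL_Y23,
) -> HaplotypeTable:
    """Read and validate a haplotype table from delimited text.

    Raises :class:`ParseError` naming the sample and locus on any bad
    token, missing locus column, duplicate id, or ragged row.
    """
    path = Path(path)
    sep = _dialect_sep(dialect, path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    if "id" not in df.columns:
        raise ParseError("missing required column 'id'")

    cols = set(df.columns)
    locus_cols: dict[str, tuple[str, ...]] = {}
    for d in locus_panel:
        if d.multi_copy:
            if {d.name + "a", d.name + "b"} <= cols:
                locus_cols[d.name] = (d.name + "a", d.name + "b")
            elif d.name in cols:
                locus_cols[d.name] = (d.name,)
            else:
                raise ParseError(f"missing locus column {d.name}")
        else:
            if d.name not in cols:
                raise ParseError(f"missing locus column {d.name}")
            locus_cols[d.name] = (d.name,)

    used = {c for cs in locus_cols.values() for c in cs}
    meta_cols = [c for c in df.columns if c not in used]
    meta = df[meta_cols].copy()
    for c in META_COLUMNS:
        if c not in meta.columns:
            meta[c] = ""

    n = len(df)
    calls = np.empty((n, len(locus_panel)), dtype=object)
    for j, d in enumerate(locus_panel):
        src = locus_cols[d.name]
        for i in range(n):
            where = f"(sample {df['id'].iloc[i]!r}, locus {d.name})"
            if len(src) == 2:
                a = df[src[0]].iloc[i].strip()
                b = df[src[1]].iloc[i].strip()
                if a.lower() in NULL_TOKENS and b.lower() in NULL_TOKENS:
                    calls[i, j] = AlleleCall.null()
                else:
                    calls[i, j] = parse_allele(f"{a},{b}", d, where=where)
            else:
                tok = df[src[0]].iloc[i]
                if not tok.strip():
                    raise ParseError(f"ragged row: empty cell {where}")
                calls[i, j] = parse_allele(tok, d, where=where)
    return HaplotypeTable(meta, calls, tuple(locus_panel))


# -- writing ---------------------------------------------------------------


def write_table(
    table: HaplotypeTable,
    path: str | Path,
    dialect: str | None = None,
) -> None:
    """Write ``table`` as delimited text; round-trips through
    :func:`read_table` field-for-field.

    Column order: id, tribe, clan, haplogroup, extra metadata, then panel
    loci in panel order (DYS385 as two columns a/b).
    """
    path = Path(path)
    sep = _dialect_sep(dialect, path)
    out = pd.DataFrame()
    extra = [c for c in table.meta.columns if c not in META_COLUMNS]
    for c in list(META_COLUMNS) + extra:
        out[c] = table.meta[c] if c in table.meta.columns else ""
    for j, d in enumerate(table.loci):
        col = table.calls[:, j]
        if d.multi_copy:
            out[d.name + "a"] = [
                "0" if c.is_null else _fmt(c.pair[0]) for c in col
            ]
            out[d.name + "b"] = [
                "0" if c.is_null else _fmt(c.pair[1]) for c in col
            ]
        else:
            out[d.name] = [c.token() for c in col]
    out.to_csv(path, sep=sep, index=False)


# -- validation report -----------------------------------------------------


def validation_report(table: HaplotypeTable) -> pd.DataFrame:
    """Per-locus counts of nulls, duplications and microvariants."""
    rows = []
    for j, d in enumerate(table.loci):
        col = table.calls[:, j]
        rows.append(
            {
                "locus": d.name,
                "n": len(col),
                "nulls": sum(c.is_null for c in col),
                "duplicated": 0 if d.multi_copy
                else sum(c.is_pair for c in col),
                "microvariants": sum(c.is_microvariant for c in col),
            }
        )
    return pd.DataFrame(rows)


def build_table(
    records: Iterable[Mapping[str, object]],
    loci: Sequence[LocusDef] = PANEL_Y23,
) -> HaplotypeTable:
    """Assemble a table from dict records mapping metadata keys and locus
    names to :class:`AlleleCall` (or raw tokens, which are parsed)."""
    records = list(records)
    meta = pd.DataFrame(
        [{k: r.get(k, "") for k in META_COLUMNS} for r in records]
    )
    calls = np.empty((len(records), len(loci)), dtype=object)
    for i, r in enumerate(records):
        for j, d in enumerate(loci):
            v = r[d.name]
            if isinstance(v, AlleleCall):
                calls[i, j] = v
            else:
                calls[i, j] = parse_allele(
                    str(v), d, where=f"(sample {r.get('id')!r}, locus {d.name})"
                )
    return HaplotypeTable(meta, calls, tuple(loci))
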