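"""Shared domain types, table readers/writers and gene-symbol normalization.

Every downstream stage of the pipeline works on the small set of record
types defined here: phytochemical compounds with their molecular
descriptors and oral-bioavailability score, gene-symbol-level target
records tagged with a source database, and plain labelled symbol sets.

Tables are plain-text TSV/CSV with a header row.  The delimiter is
sniffed from the header (tab wins if present, otherwise comma); writers
always emit tab-separated UTF-8 with LF line endings and a stable
column order, so a write-then-read round-trip is exact.

Gene symbols are normalized deterministically: uppercase, strip
surrounding whitespace, then an optional alias -> approved-symbol lookup
(HGNC-style two-column table).  Unmappable inputs are reported, never
silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DescriptorBlock",
    "CompoundRecord",
    "TargetRecord",
    "TargetSet",
    "SymbolMap",
    "FormatError",
    "RowError",
    "KNOWN_SOURCE_DBS",
    "read_compound_table",
    "write_compound_table",
    "read_target_table",
    "write_target_table",
    "read_symbol_list",
    "write_symbol_list",
    "read_symbol_map",
    "normalize_symbols",
    "sniff_delimiter",
]

#: databases recognized as target sources (six chemical->target databases
#: and the three/four disease-target sources).
KNOWN_SOURCE_DBS = frozenset(
    {
        "bindingdb",
        "swisstarget",
        "stitch",
        "ttd",
        "ctd",
        "batman",
        "omim",
        "disgenet",
        "drugbank",
    }
)


class FormatError(ValueError):
    """A table does not conform to the expected format (e.g. missing column)."""


class RowError(ValueError):
    """A single row holds an unparseable value; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

#: ordered descriptor fields as they appear in tables
_DESCRIPTOR_FIELDS = (
    "mw",
    "mlogp",
    "wlogp",
    "xlogp",
    "hba",
    "hbd",
    "rotb",
    "tpsa",
    "molar_refractivity",
    "heavy_atoms",
    "carbons",
    "heteroatoms",
    "rings",
)


@dataclass(frozen=True)
class DescriptorBlock:
    """Molecular descriptors feeding the five drug-likeness rule sets.

    Any field may be ``None`` (absent); a rule set that needs an absent
    descriptor fails conservatively rather than guessing zero.

    Units: ``mw`` g/mol, ``tpsa`` A^2; log-P variants, molar
    refractivity unitless; the rest are counts.
    """

    mw: float | None = None
    mlogp: float | None = None
    wlogp: float | None = None
    xlogp: float | None = None
    hba: float | None = None  # N+O acceptor count
    hbd: float | None = None  # NH+OH donor count
    rotb: float | None = None
    tpsa: float | None = None
    molar_refractivity: float | None = None
    heavy_atoms: float | None = None
    carbons: float | None = None
    heteroatoms: float | None = None
    rings: float | None = None

    def __post_init__(self) -> None:
        if self.mw is not None and self.mw <= 0:
            raise ValueError(f"mw must be > 0, got {self.mw}")
        for name in ("hba", "hbd", "rotb", "heavy_atoms", "carbons", "heteroatoms", "rings"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class CompoundRecord:
    """One identified phytochemical with descriptors and OB score."""

    compound_id: str
    name: str
    ob_score: float
    descriptors: DescriptorBlock = field(default_factory=DescriptorBlock)
    rt_min: float | None = None
    adduct: str | None = None
    precursor_mz: float | None = None
    formula: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.ob_score <= 1.0):
            raise ValueError(f"ob_score must be in [0, 1], got {self.ob_score}")
        if self.rt_min is not None and self.rt_min < 0:
            raise ValueError(f"rt_min must be >= 0, got {self.rt_min}")


@dataclass(frozen=True)
class TargetRecord:
    """A gene-symbol-level target with its source database and native score."""

    symbol: str
    source_db: str
    score: float | None = None
    compound_id: str | None = None

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("symbol must be non-empty")
        if self.source_db not in KNOWN_SOURCE_DBS:
            raise ValueError(
                f"unknown source database {self.source_db!r}; "
                f"expected one of {sorted(KNOWN_SOURCE_DBS)}"
            )


@dataclass(frozen=True)
class TargetSet:
    """A labelled, deduplicated set of gene symbols."""

    label: str
    symbols: frozenset[str]

    def __init__(self, label: str, symbols: Iterable[str]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "symbols", frozenset(symbols))

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __iter__(self):
        return iter(sorted(self.symbols))


class SymbolMap:
    """Alias -> approved-symbol mapping (a function: one approved per alias).

    Lookup is case-insensitive on the alias side.  Approved symbols map
    to themselves, which makes :func:`normalize_symbols` idempotent.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        approved: set[str] = set()
        for alias, sym in (mapping or {}).items():
            a = alias.strip().upper()
            s = sym.strip().upper()
            if a in self._map and self._map[a] != s:
                raise ValueError(f"alias {a!r} maps to both {self._map[a]!r} and {s!r}")
            self._map[a] = s
            approved.add(s)
        self._approved = approved

    def __len__(self) -> int:
        return len(self._map)

    def lookup(self, symbol: str) -> str | None:
        """Approved symbol for ``symbol`` (already upper/stripped), else None."""
        if symbol in self._map:
            return self._map[symbol]
        if symbol in self._approved:
            return symbol
        return None


# ---------------------------------------------------------------------------
# delimiter sniffing and low-level parsing helpers
# ---------------------------------------------------------------------------


def sniff_delimiter(header_line: str) -> str:
    """Tab if the header contains one, else comma (source exports differ)."""
    return "\t" if "\t" in header_line else ","


def _parse_float(raw: str, column: str, line: int) -> float:
    try:
        v = float(raw)
    except ValueError:
        raise RowError(f"non-numeric {column} {raw!r}", line) from None
    if not math.isfinite(v):
        raise RowError(f"non-finite {column} {raw!r}", line)
    return v


def _opt(raw: str | None) -> str | None:
    if raw is None:
        return None
    raw = raw.strip()
    return raw if raw not in ("", "NA", "na", "NaN", "nan", ".") else None


def _read_rows(path: str | Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Header columns + (1-based line number, cells) for non-empty rows."""
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file, header expected")
    delim = sniff_delimiter(lines[0])
    header = [c.strip() for c in lines[0].split(delim)]
    rows = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        rows.append((i, line.split(delim)))
    return header, rows


def _cell(cells: list[str], idx: dict[str, int], col: str) -> str | None:
    j = idx.get(col)
    if j is None or j >= len(cells):
        return None
    return cells[j]


# ---------------------------------------------------------------------------
# compound tables
# ---------------------------------------------------------------------------

_COMPOUND_OPTIONAL = ("rt_min", "adduct", "precursor_mz", "formula")
_COMPOUND_COLUMNS = ("compound_id", "name", "ob_score") + _COMPOUND_OPTIONAL + _DESCRIPTOR_FIELDS


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound table (TSV or CSV, sniffed) into records, in file order.

    Required columns: ``compound_id``, ``name``, ``ob_score``.  Descriptor
    columns are optional; absent descriptors stay absent (``None``), never
    zero.  A missing required column raises :class:`FormatError` naming the
    column; a non-numeric numeric cell raises :class:`RowError` with the
    1-based line number.
    """
    header, rows = _read_rows(path)
    idx = {c: j for j, c in enumerate(header)}
    for col in ("compound_id", "name", "ob_score"):
        if col not in idx:
            raise FormatError(f"{path}: missing required column {col!r}")

    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for line, cells in rows:
        cid = (_cell(cells, idx, "compound_id") or "").strip()
        if not cid:
            raise RowError("empty compound_id", line)
        if cid in seen:
            raise RowError(f"duplicate compound_id {cid!r}", line)
        seen.add(cid)
        ob_raw = _opt(_cell(cells, idx, "ob_score"))
        if ob_raw is None:
            raise RowError("missing ob_score", line)
        ob = _parse_float(ob_raw, "ob_score", line)
        desc_vals = {}
        for dcol in _DESCRIPTOR_FIELDS:
            raw = _opt(_cell(cells, idx, dcol))
            desc_vals[dcol] = None if raw is None else _parse_float(raw, dcol, line)
        rt = _opt(_cell(cells, idx, "rt_min"))
        mz = _opt(_cell(cells, idx, "precursor_mz"))
        try:
            rec = CompoundRecord(
                compound_id=cid,
                name=(_cell(cells, idx, "name") or "").strip(),
                ob_score=ob,
                descriptors=DescriptorBlock(**desc_vals),
                rt_min=None if rt is None else _parse_float(rt, "rt_min", line),
                adduct=_opt(_cell(cells, idx, "adduct")),
                precursor_mz=None if mz is None else _parse_float(mz, "precursor_mz", line),
                formula=_opt(_cell(cells, idx, "formula")),
            )
        except ValueError as exc:
            raise RowError(str(exc), line) from None
        records.append(rec)
    return records


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return str(v)


def write_compound_table(records: Sequence[CompoundRecord], path: str | Path) -> None:
    """Write records as TSV (UTF-8, LF, stable column order)."""
    lines = ["\t".join(_COMPOUND_COLUMNS)]
    for r in records:
        row = [r.compound_id, r.name, _fmt(r.ob_score)]
        row += [_fmt(getattr(r, c)) for c in _COMPOUND_OPTIONAL]
        row += [_fmt(getattr(r.descriptors, c)) for c in _DESCRIPTOR_FIELDS]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# target tables and symbol lists
# ---------------------------------------------------------------------------

_TARGET_COLUMNS = ("symbol", "source_db", "score", "compound_id")


def read_target_table(path: str | Path) -> list[TargetRecord]:
    """Read a per-database target table; columns symbol, source_db[, score, compound_id]."""
    header, rows = _read_rows(path)
    idx = {c: j for j, c in enumerate(header)}
    for col in ("symbol", "source_db"):
        if col not in idx:
            raise FormatError(f"{path}: missing required column {col!r}")
    out: list[TargetRecord] = []
    for line, cells in rows:
        score_raw = _opt(_cell(cells, idx, "score"))
        try:
            out.append(
                TargetRecord(
                    symbol=(_cell(cells, idx, "symbol") or "").strip().upper(),
                    source_db=(_cell(cells, idx, "source_db") or "").strip().lower(),
                    score=None if score_raw is None else _parse_float(score_raw, "score", line),
                    compound_id=_opt(_cell(cells, idx, "compound_id")),
                )
            )
        except ValueError as exc:
            raise RowError(str(exc), line) from None
    return out


def write_target_table(records: Sequence[TargetRecord], path: str | Path) -> None:
    lines = ["\t".join(_TARGET_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join([r.symbol, r.source_db, _fmt(r.score), _fmt(r.compound_id)])
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_symbol_list(path: str | Path) -> list[str]:
    """One symbol per line; blanks and '#' comments skipped; order kept."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s)
    return out


def write_symbol_list(symbols: Iterable[str], path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(symbols) + "\n", encoding="utf-8", newline="\n"
    )


def read_symbol_map(path: str | Path) -> SymbolMap:
    """Two-column TSV (alias, approved) -> :class:`SymbolMap`."""
    mapping: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise RowError("expected two tab-separated columns (alias, approved)", i)
        mapping[parts[0].strip()] = parts[1].strip()
    return SymbolMap(mapping)


# ---------------------------------------------------------------------------
# symbol normalization
# ---------------------------------------------------------------------------


def normalize_symbols(
    symbols: Iterable[str],
    symbol_map: SymbolMap | None = None,
    label: str = "normalized",
) -> tuple[TargetSet, list[str]]:
    """Normalize raw gene symbols into an approved-symbol set.

    Pipeline: strip whitespace, uppercase, then alias lookup when a map
    is given.  Without a map every cleaned symbol passes through
    unchanged.  Returns the deduplicated :class:`TargetSet` and the list
    of unmappable inputs (original spelling, order kept, deduplicated) —
    a report, not a failure.

    Idempotent: approved symbols look up to themselves.
    """
    mapped: set[str] = set()
    unmapped: list[str] = []
    seen_unmapped: set[str] = set()
    for raw in symbols:
        s = raw.strip().upper()
        if not s:
            continue
        if symbol_map is None:
            mapped.add(s)
            continue
        hit = symbol_map.lookup(s)
        if hit is None:
            if raw not in seen_unmapped:
                unmapped.append(raw)
                seen_unmapped.add(raw)
        else:
            mapped.add(hit)
    return TargetSet(label, mapped), unmapped
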