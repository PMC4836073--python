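"""Reading and indexing RxNorm-format pipe-delimited release files.

RxNorm releases ship as RRF files: pipe-delimited text, one record per
line, a trailing pipe, and no header row.  Three tables matter here:

* ``RXNCONSO`` — atoms: one source's string for a concept, keyed by an
  atom identifier (RXAUI) and grouped under a concept identifier (RXCUI),
  with a source abbreviation (SAB, e.g. ``RXNORM`` or ``MTHSPL``) and a
  term type (TTY, e.g. ``IN``, ``SCD``, ``SBD``, ``SCDC``, ``DF``).
* ``RXNREL`` — named relationships between concepts and/or atoms
  (``has_inactive_ingredient``, ``consists_of``, ``has_ingredient``, …).
* ``RXNSAT`` — attributes such as ``RXN_STRENGTH``.

Column positions follow the RxNorm Technical Documentation layouts
(RXNCONSO 18 fields, RXNREL 16, RXNSAT 13) but are configurable via
:class:`ColumnMap` since other dialects exist in the wild.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Union

logger = logging.getLogger(__name__)

#: Suppression flag values dropped in default mode (suppressed by editors
#: or obsolete in the source vocabulary).
SUPPRESSED_FLAGS = frozenset({"Y", "O"})

TABLE_KINDS = ("CONSO", "REL", "SAT")


class RRFParseError(ValueError):
    """Raised in strict mode on the first malformed line."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True)
class AtomRecord:
    """One row of RXNCONSO: a single source's string for a concept."""

    rxcui: str
    rxaui: str
    sab: str
    tty: str
    name: str
    suppress: str = "N"


@dataclass(frozen=True)
class RelationshipRecord:
    """One row of RXNREL.

    By RxNorm convention ``rela`` names the relationship of the
    second-column entity to the first-column entity (entity2 RELA
    entity1); see :class:`ColumnMap.invert_rel_direction` to flip this.
    ``rela`` may be empty: REL-only rows are retained but never matched
    by rela filters.
    """

    rxcui1: str
    rxaui1: str
    rxcui2: str
    rxaui2: str
    rela: str
    sab: str
    suppress: str = "N"


@dataclass(frozen=True)
class AttributeRecord:
    """One row of RXNSAT: a named attribute of a concept or atom."""

    rxcui: str
    rxaui: str
    atn: str
    atv: str
    sab: str
    suppress: str = "N"


RRFRecord = Union[AtomRecord, RelationshipRecord, AttributeRecord]


@dataclass(frozen=True)
class ColumnMap:
    """Field positions for each table, defaulting to the RxNorm layouts.

    The defaults index the standard columns:
    RXNCONSO ``RXCUI|LAT|TS|LUI|STT|SUI|ISPREF|RXAUI|SAUI|SCUI|SDUI|SAB|
    TTY|CODE|STR|SRL|SUPPRESS|CVF``; RXNREL ``RXCUI1|RXAUI1|STYPE1|REL|
    RXCUI2|RXAUI2|STYPE2|RELA|RUI|SRUI|SAB|SL|DIR|RG|SUPPRESS|CVF``;
    RXNSAT ``RXCUI|LUI|SUI|RXAUI|STYPE|CODE|ATUI|SATUI|ATN|SAB|ATV|
    SUPPRESS|CVF``.
    """

    conso_fields: int = 18
    conso: dict = field(
        default_factory=lambda: {
            "rxcui": 0, "rxaui": 7, "sab": 11, "tty": 12, "name": 14,
            "suppress": 16,
        }
    )
    rel_fields: int = 16
    rel: dict = field(
        default_factory=lambda: {
            "rxcui1": 0, "rxaui1": 1, "rxcui2": 4, "rxaui2": 5,
            "rela": 7, "sab": 10, "suppress": 14,
        }
    )
    sat_fields: int = 13
    sat: dict = field(
        default_factory=lambda: {
            "rxcui": 0, "rxaui": 3, "atn": 8, "sab": 9, "atv": 10,
            "suppress": 11,
        }
    )
    #: If True, rela is read as naming the relationship of the FIRST
    #: entity to the second (the opposite of the RxNorm convention).
    invert_rel_direction: bool = False


@dataclass
class ParseReport:
    """Per-table parse accounting (lenient mode collects, strict aborts)."""

    n_lines: int = 0
    n_records: int = 0
    n_suppressed: int = 0
    errors: list = field(default_factory=list)  # (lineno, message)


def _decode_lines(stream: Union[IO, Iterable]) -> Iterator[str]:
    for raw in stream:
        if isinstance(raw, bytes):
            raw = raw.decode("utf-8")
        yield raw.rstrip("\r\n")


def _split_line(line: str, n_fields: int, lineno: int) -> list:
    # RRF dialect: trailing pipe => split yields n_fields + 1 parts with
    # an empty final part.
    parts = line.split("|")
    if len(parts) == n_fields + 1 and parts[-1] == "":
        return parts[:-1]
    if len(parts) == n_fields:
        # tolerate a missing trailing pipe
        return parts
    raise RRFParseError(
        lineno, f"expected {n_fields} pipe-delimited fields, found "
        f"{len(parts) - (1 if parts and parts[-1] == '' else 0)}"
    )


def parse_rrf(
    table_kind: str,
    stream: Union[IO, Iterable],
    *,
    column_map: ColumnMap | None = None,
    strict: bool = False,
    keep_suppressed: bool = False,
    report: ParseReport | None = None,
) -> list:
    """Parse an RRF byte/text stream into typed records.

    Parameters
    ----------
    table_kind
        One of ``CONSO``, ``REL``, ``SAT``.
    stream
        An iterable of lines (text or bytes, UTF-8).
    strict
        If True, the first malformed line raises :class:`RRFParseError`;
        otherwise malformed lines are skipped with a logged warning and
        collected on the report.
    keep_suppressed
        Retain rows whose suppression flag is ``Y`` or ``O``.
    report
        Optional :class:`ParseReport` to fill with accounting.
    """
    if table_kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    cmap = column_map or ColumnMap()
    rep = report if report is not None else ParseReport()
    records: list = []
    seen_rxaui: set = set()

    for lineno, line in enumerate(_decode_lines(stream), start=1):
        if line == "":
            continue
        rep.n_lines += 1
        try:
            if table_kind == "CONSO":
                parts = _split_line(line, cmap.conso_fields, lineno)
                c = cmap.conso
                rec: RRFRecord = AtomRecord(
                    rxcui=parts[c["rxcui"]], rxaui=parts[c["rxaui"]],
                    sab=parts[c["sab"]], tty=parts[c["tty"]],
                    name=parts[c["name"]], suppress=parts[c["suppress"]],
                )
                if not rec.rxcui or not rec.rxaui or not rec.sab:
                    raise RRFParseError(
                        lineno, "empty rxcui/rxaui/sab in CONSO row")
                if rec.rxaui in seen_rxaui:
                    raise RRFParseError(
                        lineno, f"duplicate rxaui {rec.rxaui}")
            elif table_kind == "REL":
                parts = _split_line(line, cmap.rel_fields, lineno)
                c = cmap.rel
                rec = RelationshipRecord(
                    rxcui1=parts[c["rxcui1"]], rxaui1=parts[c["rxaui1"]],
                    rxcui2=parts[c["rxcui2"]], rxaui2=parts[c["rxaui2"]],
                    rela=parts[c["rela"]], sab=parts[c["sab"]],
                    suppress=parts[c["suppress"]],
                )
                if not (rec.rxcui1 or rec.rxaui1) or not (rec.rxcui2 or rec.rxaui2):
                    raise RRFParseError(
                        lineno, "REL row missing identifiers on one side")
            else:
                parts = _split_line(line, cmap.sat_fields, lineno)
                c = cmap.sat
                rec = AttributeRecord(
                    rxcui=parts[c["rxcui"]], rxaui=parts[c["rxaui"]],
                    atn=parts[c["atn"]], atv=parts[c["atv"]],
                    sab=parts[c["sab"]], suppress=parts[c["suppress"]],
                )
                if not rec.atn:
                    raise RRFParseError(lineno, "empty attribute name")
        except RRFParseError as exc:
            if strict:
                raise
            logger.warning("skipping malformed %s row: %s", table_kind, exc)
            rep.errors.append((exc.lineno, str(exc)))
            continue

        if not keep_suppressed and rec.suppress in SUPPRESSED_FLAGS:
            rep.n_suppressed += 1
            continue
        if table_kind == "CONSO":
            seen_rxaui.add(rec.rxaui)  # type: ignore[union-attr]
        records.append(rec)
        rep.n_records += 1
    return records


def serialize_rrf(
    table_kind: str, records: Iterable, *, column_map: ColumnMap | None = None
) -> str:
    """Re-serialize typed records back to RRF lines (inverse of parsing).

    Fields without a typed slot are emitted empty; parsing then
    re-serializing a file whose untyped columns were empty reproduces the
    retained lines byte-for-byte.
    """
    cmap = column_map or ColumnMap()
    out = []
    for rec in records:
        if table_kind == "CONSO":
            n, cols = cmap.conso_fields, cmap.conso
            values = {"rxcui": rec.rxcui, "rxaui": rec.rxaui, "sab": rec.sab,
                      "tty": rec.tty, "name": rec.name,
                      "suppress": rec.suppress}
        elif table_kind == "REL":
            n, cols = cmap.rel_fields, cmap.rel
            values = {"rxcui1": rec.rxcui1, "rxaui1": rec.rxaui1,
                      "rxcui2": rec.rxcui2, "rxaui2": rec.rxaui2,
                      "rela": rec.rela, "sab": rec.sab,
                      "suppress": rec.suppress}
        elif table_kind == "SAT":
            n, cols = cmap.sat_fields, cmap.sat
            values = {"rxcui": rec.rxcui, "rxaui": rec.rxaui, "atn": rec.atn,
                      "atv": rec.atv, "sab": rec.sab,
                      "suppress": rec.suppress}
        else:
            raise ValueError(f"unknown table kind {table_kind!r}")
        fields = [""] * n
        for key, idx in cols.items():
            fields[idx] = values[key]
        out.append("|".join(fields) + "|")
    return "\n".join(out) + ("\n" if out else "")


def index_atoms(
    atoms: Iterable[AtomRecord],
    sab_filter: str | None = None,
    tty_filter: str | None = None,
) -> dict:
    """Group atoms by rxcui, keeping only those matching both filters.

    A ``None`` filter matches everything.  Concepts with no matching atom
    are absent from the returned map.
    """
    index: dict = {}
    for atom in atoms:
        if sab_filter is not None and atom.sab != sab_filter:
            continue
        if tty_filter is not None and atom.tty != tty_filter:
            continue
        index.setdefault(atom.rxcui, []).append(atom)
    return index


def index_atoms_by_rxaui(atoms: Iterable[AtomRecord]) -> dict:
    """Map rxaui -> atom (rxaui is unique within a parsed table)."""
    return {atom.rxaui: atom for atom in atoms}
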