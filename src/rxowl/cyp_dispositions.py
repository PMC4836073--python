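"""Curated cytochrome-P450 substrate/inhibitor assignments.

The ontology gets its CYP binding facts from a curated table of
(molecule, isoenzyme, mode) triples in the style of the Indiana
University School of Medicine P450 drug-interaction table — not from
RxNorm, which carries no such pharmacology.  Molecules are matched to
normalized ingredient concepts by exact case-insensitive name equality
against ``RXNORM``/``IN`` atoms; no fuzzy matching is attempted, since a
wrong match would assert a false pharmacological claim.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

from .role_taxonomy import ISOENZYMES, MODES
from .rrf_io import AtomRecord, index_atoms

CSV_HEADER = ("molecule", "isoenzyme", "mode")


@dataclass(frozen=True)
class CypRecord:
    """One molecule x isoenzyme x binding-mode assignment."""

    molecule_name: str
    isoenzyme: str
    mode: str
    resolved_rxcui: Optional[str] = None


@dataclass
class CypReport:
    n_rows: int = 0
    n_records: int = 0
    n_duplicates: int = 0
    n_rejected: int = 0
    rejected: List[str] = field(default_factory=list)
    unresolved: List[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "rows": self.n_rows,
            "records": self.n_records,
            "duplicates": self.n_duplicates,
            "rejected": self.n_rejected,
            "unresolved": list(self.unresolved),
        }


def load_cyp_table(csv_stream, report: CypReport | None = None
                   ) -> List[CypRecord]:
    """Load ``molecule,isoenzyme,mode`` rows into unique records.

    Rows with isoenzymes or modes outside the closed vocabularies are
    rejected per-row (reported); duplicate triples collapse to one
    record.  A missing or wrong header is an error.
    """
    if isinstance(csv_stream, (bytes, str)):
        csv_stream = io.StringIO(
            csv_stream.decode("utf-8")
            if isinstance(csv_stream, bytes) else csv_stream)
    rep = report if report is not None else CypReport()
    reader = csv.reader(csv_stream)
    try:
        header = next(reader)
    except StopIteration:
        raise ValueError("CYP table is empty: missing header") from None
    if tuple(h.strip().lower() for h in header) != CSV_HEADER:
        raise ValueError(
            f"CYP table header must be {','.join(CSV_HEADER)!r}, "
            f"got {','.join(header)!r}")

    seen: set = set()
    records: List[CypRecord] = []
    for row in reader:
        if not row or all(not c.strip() for c in row):
            continue
        rep.n_rows += 1
        if len(row) != 3:
            rep.n_rejected += 1
            rep.rejected.append(",".join(row))
            continue
        molecule, isoenzyme, mode = (c.strip() for c in row)
        if isoenzyme not in ISOENZYMES or mode not in MODES or not molecule:
            rep.n_rejected += 1
            rep.rejected.append(",".join(row))
            continue
        key = (molecule.lower(), isoenzyme, mode)
        if key in seen:
            rep.n_duplicates += 1
            continue
        seen.add(key)
        records.append(CypRecord(molecule, isoenzyme, mode))
    rep.n_records = len(records)
    return records


def resolve_molecules(
    records: Iterable[CypRecord],
    atoms: Iterable[AtomRecord],
    report: CypReport | None = None,
) -> List[CypRecord]:
    """Fill ``resolved_rxcui`` by exact case-insensitive name match
    against RXNORM/IN atoms; unresolved records are kept (and listed on
    the report) so curators can see what failed."""
    in_index = index_atoms(atoms, sab_filter="RXNORM", tty_filter="IN")
    by_name: Dict[str, str] = {}
    for rxcui, atom_list in in_index.items():
        for atom in atom_list:
            by_name.setdefault(atom.name.lower(), rxcui)

    out: List[CypRecord] = []
    unresolved: set = set()
    for rec in records:
        rxcui = by_name.get(rec.molecule_name.lower())
        if rxcui is None:
            unresolved.add(rec.molecule_name)
            out.append(rec)
        else:
            out.append(replace(rec, resolved_rxcui=rxcui))
    if report is not None:
        report.unresolved = sorted(unresolved)
    return out


def disposition_counts(records: Iterable[CypRecord]) -> dict:
    """Per-(isoenzyme, mode) assignment counts plus the number of
    distinct molecules (a molecule with several dispositions counts
    once in the total)."""
    counts = {(iso, mode): 0 for iso in ISOENZYMES for mode in MODES}
    molecules: set = set()
    seen: set = set()
    for rec in records:
        key = (rec.molecule_name.lower(), rec.isoenzyme, rec.mode)
        if key in seen:
            continue
        seen.add(key)
        counts[(rec.isoenzyme, rec.mode)] += 1
        molecules.add(rec.molecule_name.lower())
    return {
        "counts": {f"{iso}:{mode}": n for (iso, mode), n in
                   sorted(counts.items())},
        "distinct_molecules": len(molecules),
    }


# A small demonstration table in the schema real curated tables use.
# Esomeprazole is the classic both-modes case for CYP2C19.
DEMO_CYP_TABLE = """\
molecule,isoenzyme,mode
esomeprazole,CYP2C19,inhibitor
esomeprazole,CYP2C19,substrate
omeprazole,CYP2C19,substrate
omeprazole,CYP2C19,inhibitor
clopidogrel,CYP2C19,substrate
fluoxetine,CYP2D6,substrate
fluoxetine,CYP2D6,inhibitor
paroxetine,CYP2D6,substrate
paroxetine,CYP2D6,inhibitor
metoprolol,CYP2D6,substrate
codeine,CYP2D6,substrate
quinidine,CYP2D6,inhibitor
"""
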