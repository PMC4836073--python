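"""Active-ingredient strength extraction for discrete solid dose forms.

For tablets, capsules and caplets the strength printed on the label is
the total mass of active ingredient per discrete unit — directly
representable as a mass magnitude plus a unit.  Other dose forms carry
concentrations (mass per mL or per g of product), which need the total
package quantity to yield a mass; those are detected and skipped.

RxNorm attaches strengths not to the clinical drug (SCD) but to its
components: one SCDC (semantic clinical drug component) exists per
unique (active ingredient, strength) pair, linked by

    SCD --consists_of--> SCDC --has_ingredient--> IN

with the strength string on the SCDC as the ``RXN_STRENGTH`` attribute.
Extraction walks that chain for every SCD whose dose form passes the
discrete-solid filter and parses the strength strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .rrf_io import (AtomRecord, AttributeRecord, ColumnMap,
                     RelationshipRecord, index_atoms)

#: Unit symbols with packaged unit individuals; everything else is
#: rejected (reported), never guessed.
UNIT_TABLE = ("MG", "MCG", "G", "UNT", "MEQ")

DEFAULT_DOSE_FORM_TOKENS = ("tablet", "capsule", "caplet")


@dataclass(frozen=True)
class DoseFormFilter:
    """Case-insensitive whole-word dose-form matcher."""

    allowed_tokens: Tuple[str, ...] = DEFAULT_DOSE_FORM_TOKENS

    def __post_init__(self):
        if not self.allowed_tokens:
            raise ValueError("DoseFormFilter needs at least one token")

    def matches(self, dose_form: str) -> bool:
        words = re.findall(r"[A-Za-z]+", dose_form.lower())
        return any(tok.lower() in words for tok in self.allowed_tokens)


@dataclass(frozen=True)
class StrengthRecord:
    scd_rxcui: str
    ingredient_rxcui: str
    value: float
    unit: str

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("strength value must be positive")
        if self.unit not in UNIT_TABLE:
            raise ValueError(f"unit {self.unit!r} not in the packaged table")


@dataclass(frozen=True)
class StrengthRejection:
    """A strength string that could not be used, with the reason."""

    atv: str
    reason: str  # "concentration" | "unknown-unit" | "malformed"


@dataclass
class StrengthReport:
    n_scds_considered: int = 0
    n_scds_solid: int = 0
    n_records: int = 0
    n_missing_strength: int = 0
    n_rejected: int = 0
    rejections: List[StrengthRejection] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "scds_considered": self.n_scds_considered,
            "scds_solid_form": self.n_scds_solid,
            "strength_records": self.n_records,
            "missing_strength": self.n_missing_strength,
            "rejected_strength": self.n_rejected,
        }


_STRENGTH_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s+([A-Za-z]+)\s*$")


def parse_strength_string(atv: str):
    """Parse ``"<number> <unit>"`` into ``(value, unit)``.

    Returns a :class:`StrengthRejection` for strings that are valid
    attribute values but out of scope: anything containing ``/`` is a
    concentration (mass per unit of product, not a total mass), unknown
    unit symbols are not guessed, and thousands separators are not
    accepted.  An *empty* string is an error, not a rejection.
    """
    if atv == "":
        raise ValueError("empty strength string")
    if "/" in atv:
        return StrengthRejection(atv, "concentration")
    m = _STRENGTH_RE.match(atv)
    if not m:
        return StrengthRejection(atv, "malformed")
    value, unit = float(m.group(1)), m.group(2).upper()
    if unit not in UNIT_TABLE:
        return StrengthRejection(atv, "unknown-unit")
    if value <= 0:
        return StrengthRejection(atv, "malformed")
    return value, unit


def is_discrete_solid_form(
    scd_atom: AtomRecord,
    relationships: Iterable[RelationshipRecord],
    atoms: Iterable[AtomRecord],
    dose_filter: DoseFormFilter | None = None,
    *,
    column_map: ColumnMap | None = None,
) -> bool:
    """True iff the SCD's dose form contains an allowed token.

    The dose form is taken from a ``has_dose_form`` relationship to a
    ``DF`` atom when one exists, otherwise from the trailing dose-form
    phrase of the SCD name (everything after the last strength token).
    """
    if scd_atom.tty != "SCD":
        raise ValueError("is_discrete_solid_form expects an SCD atom")
    dose_filter = dose_filter or DoseFormFilter()
    cmap = column_map or ColumnMap()
    df_index = index_atoms(atoms, sab_filter="RXNORM", tty_filter="DF")

    for rel in relationships:
        if rel.rela != "has_dose_form":
            continue
        # entity2 has_dose_form entity1 => entity2 is the drug.
        if cmap.invert_rel_direction:
            drug, formside = rel.rxcui1, rel.rxcui2
        else:
            drug, formside = rel.rxcui2, rel.rxcui1
        if drug == scd_atom.rxcui and formside in df_index:
            return any(dose_filter.matches(a.name)
                       for a in df_index[formside])
    if not scd_atom.name:
        raise ValueError(
            f"SCD {scd_atom.rxcui} has no name and no dose-form "
            "relationship")
    # Fall back to the name: the dose-form phrase trails the strengths,
    # e.g. "acetaminophen 325 MG Oral Tablet" -> "Oral Tablet".
    tail = re.split(r"\d+(?:\.\d+)?\s*[A-Za-z/%]*", scd_atom.name)[-1]
    return dose_filter.matches(tail if tail.strip() else scd_atom.name)


def extract_strengths(
    atoms: Iterable[AtomRecord],
    relationships: Iterable[RelationshipRecord],
    attributes: Iterable[AttributeRecord],
    dose_filter: DoseFormFilter | None = None,
    *,
    column_map: ColumnMap | None = None,
) -> Tuple[List[StrengthRecord], StrengthReport]:
    """Walk SCD -> SCDC -> IN for every discrete-solid SCD and attach
    the parsed ``RXN_STRENGTH`` of each SCDC.

    One record is produced per (SCD, ingredient); SCDCs with missing or
    rejected strengths are counted on the report, never guessed.
    """
    dose_filter = dose_filter or DoseFormFilter()
    cmap = column_map or ColumnMap()
    atoms = list(atoms)
    relationships = list(relationships)
    scd_index = index_atoms(atoms, sab_filter="RXNORM", tty_filter="SCD")
    scdc_index = index_atoms(atoms, sab_filter="RXNORM", tty_filter="SCDC")
    in_index = index_atoms(atoms, sab_filter="RXNORM", tty_filter="IN")

    # entity2 RELA entity1 (or inverted): subject -> [objects]
    consists_of: Dict[str, List[str]] = {}
    has_ingredient: Dict[str, List[str]] = {}
    for rel in relationships:
        if rel.sab != "RXNORM":
            continue
        if cmap.invert_rel_direction:
            subj, obj = rel.rxcui1, rel.rxcui2
        else:
            subj, obj = rel.rxcui2, rel.rxcui1
        if rel.rela == "consists_of":
            consists_of.setdefault(subj, []).append(obj)
        elif rel.rela == "has_ingredient":
            has_ingredient.setdefault(subj, []).append(obj)

    strength_attr: Dict[str, str] = {}
    for attr in attributes:
        if attr.atn == "RXN_STRENGTH":
            strength_attr[attr.rxcui] = attr.atv

    report = StrengthReport()
    records: Dict[Tuple[str, str], StrengthRecord] = {}

    for scd_rxcui, scd_atoms in sorted(scd_index.items()):
        report.n_scds_considered += 1
        if not is_discrete_solid_form(scd_atoms[0], relationships, atoms,
                                      dose_filter, column_map=cmap):
            continue
        report.n_scds_solid += 1
        scdcs = [c for c in consists_of.get(scd_rxcui, [])
                 if c in scdc_index]
        if not scdcs:
            report.warnings.append(
                f"SCD {scd_rxcui} has no consists_of components")
            continue
        for scdc in scdcs:
            ingredients = [i for i in has_ingredient.get(scdc, [])
                           if i in in_index]
            atv = strength_attr.get(scdc)
            if atv is None:
                report.n_missing_strength += 1
                continue
            parsed = parse_strength_string(atv)
            if isinstance(parsed, StrengthRejection):
                report.n_rejected += 1
                report.rejections.append(parsed)
                continue
            value, unit = parsed
            for ing in ingredients:
                key = (scd_rxcui, ing)
                if key not in records:
                    records[key] = StrengthRecord(
                        scd_rxcui=scd_rxcui, ingredient_rxcui=ing,
                        value=value, unit=unit)

    out = sorted(records.values(),
                 key=lambda r: (r.scd_rxcui, r.ingredient_rxcui))
    report.n_records = len(out)
    return out, report


def strengths_tsv(records: Iterable[StrengthRecord]) -> str:
    lines = ["scd_rxcui\tingredient_rxcui\tvalue\tunit"]
    lines += [f"{r.scd_rxcui}\t{r.ingredient_rxcui}\t{r.value:g}\t{r.unit}"
              for r in records]
    return "\n".join(lines) + "\n"
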