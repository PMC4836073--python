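"""Branded-drug -> excipient link extraction.

RxNorm carries excipient facts only under the ``MTHSPL`` source (rows
harvested from FDA Structured Product Labels), as
``has_inactive_ingredient`` relationships between SPL atoms.  The
normalized ``RXNORM`` source, which the ontology is built from, knows
nothing of excipients — so the two must be joined through concept
identifiers:

1. take every MTHSPL ``has_inactive_ingredient`` relationship row;
2. resolve both sides to RxCUIs (directly, or through the atom table
   when only an atom identifier is present);
3. keep the product side only if its concept has a ``RXNORM``/``SBD``
   atom (a semantic branded drug), and the ingredient side only if its
   concept has a ``RXNORM``/``IN`` atom;
4. collapse duplicates into unique (product, excipient) links.

Products whose only normalized atom is an SCD are *excluded*: SPL data
links many distinct marketed products (often with no SBD of their own)
to a single clinical-drug concept, piling every product's excipients
onto that SCD; keeping such links would assert excipients of one brand
on all of them.  Concepts carrying both SBD and SCD atoms are kept, as
the exclusion rationale only bites for SCD-only concepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

from .rrf_io import (AtomRecord, ColumnMap, RelationshipRecord, index_atoms,
                     index_atoms_by_rxaui)


@dataclass(frozen=True)
class ExcipientLink:
    """A unique branded-drug -> inactive-ingredient assertion."""

    product_rxcui: str
    excipient_rxcui: str
    #: contributing MTHSPL atom identifiers (rxaui pairs), for provenance
    provenance: Tuple[Tuple[str, str], ...] = ()


@dataclass
class ExtractionReport:
    n_rows: int = 0
    n_resolved: int = 0
    n_excluded_scd_only: int = 0
    n_unresolved: int = 0
    unresolved: List[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "rows": self.n_rows,
            "resolved": self.n_resolved,
            "excluded_scd_only": self.n_excluded_scd_only,
            "unresolved": self.n_unresolved,
        }


def _resolve_rxcui(rxcui: str, rxaui: str, by_rxaui: Dict[str, AtomRecord]):
    """Resolve a REL-row side to a concept id, consulting the atom table
    when only the atom identifier is populated."""
    if rxcui:
        return rxcui
    atom = by_rxaui.get(rxaui)
    return atom.rxcui if atom is not None else None


def extract_excipient_links(
    atoms: Iterable[AtomRecord],
    relationships: Iterable[RelationshipRecord],
    *,
    column_map: ColumnMap | None = None,
) -> Tuple[List[ExcipientLink], ExtractionReport]:
    """Run the four-step SPL-to-normalized-concept mapping.

    Returns unique links sorted by (product, excipient) plus a report
    counting resolved, excluded-as-SCD-only, and unresolved rows.
    """
    cmap = column_map or ColumnMap()
    atoms = list(atoms)
    by_rxaui = index_atoms_by_rxaui(atoms)
    sbd_index = index_atoms(atoms, sab_filter="RXNORM", tty_filter="SBD")
    scd_index = index_atoms(atoms, sab_filter="RXNORM", tty_filter="SCD")
    in_index = index_atoms(atoms, sab_filter="RXNORM", tty_filter="IN")

    report = ExtractionReport()
    links: Dict[Tuple[str, str], List[Tuple[str, str]]] = {}

    for rel in relationships:
        if rel.sab != "MTHSPL" or rel.rela != "has_inactive_ingredient":
            continue
        report.n_rows += 1
        # rela names the relationship of entity2 to entity1: the product
        # (entity2) has_inactive_ingredient the ingredient (entity1).
        if cmap.invert_rel_direction:
            prod_cui, prod_aui = rel.rxcui1, rel.rxaui1
            ing_cui, ing_aui = rel.rxcui2, rel.rxaui2
        else:
            prod_cui, prod_aui = rel.rxcui2, rel.rxaui2
            ing_cui, ing_aui = rel.rxcui1, rel.rxaui1

        product = _resolve_rxcui(prod_cui, prod_aui, by_rxaui)
        ingredient = _resolve_rxcui(ing_cui, ing_aui, by_rxaui)
        if product is None or ingredient is None or ingredient not in in_index:
            report.n_unresolved += 1
            report.unresolved.append(f"{prod_aui or prod_cui}->"
                                     f"{ing_aui or ing_cui}")
            continue
        if product not in sbd_index:
            if product in scd_index:
                report.n_excluded_scd_only += 1
            else:
                report.n_unresolved += 1
                report.unresolved.append(f"{prod_aui or prod_cui}->"
                                         f"{ing_aui or ing_cui}")
            continue
        report.n_resolved += 1
        links.setdefault((product, ingredient), []).append(
            (prod_aui, ing_aui))

    out = [
        ExcipientLink(product_rxcui=p, excipient_rxcui=e,
                      provenance=tuple(sorted(set(prov))))
        for (p, e), prov in links.items()
    ]
    out.sort(key=lambda l: (l.product_rxcui, l.excipient_rxcui))
    return out, report


def coverage_report(n_linked: int, n_total: int) -> float:
    """Fraction of branded drugs with at least one excipient link,
    rounded to 3 decimals for display."""
    if n_total <= 0:
        raise ValueError("coverage undefined for n_total <= 0")
    if n_linked < 0 or n_linked > n_total:
        raise ValueError("n_linked must be in [0, n_total]")
    return round(n_linked / n_total, 3)


def links_tsv(links: Iterable[ExcipientLink]) -> str:
    lines = ["product_rxcui\texcipient_rxcui"]
    lines += [f"{l.product_rxcui}\t{l.excipient_rxcui}" for l in links]
    return "\n".join(lines) + "\n"
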