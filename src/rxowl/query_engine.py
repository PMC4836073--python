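"""Structural queries over an axiom set.

Queries here answer the drug-safety question the ontology exists for:
*which drug products contain an active-ingredient aggregate whose
molecular grains bear a given CYP binding disposition* (and hence which
product pairs are drug-drug-interaction candidates through a shared
isoenzyme), plus excipient containment lookups for allergy use cases.

Subsumption is the reflexive-transitive closure of *asserted* named
subclass axioms only — no DL reasoner runs.  That is sufficient for the
hierarchy this package builds (branded drugs sit directly below their
clinical drugs) and keeps results reproducible; it is a documented
limitation for ontologies with inferred-only hierarchies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set, Tuple

from . import role_taxonomy as tax
from .owl_model import (And, AxiomSet, BEARER_OF, ClassExpression,
                        DataHasValue, HAS_GRANULAR_PART, HAS_PROPER_PART,
                        HasValue, Named, Some, render_expression)


@dataclass(frozen=True)
class QueryMatch:
    iri: str
    #: rendered axioms traversed to establish the match
    evidence: Tuple[str, ...]


@dataclass(frozen=True)
class QueryResult:
    matches: Tuple[QueryMatch, ...]

    @property
    def iris(self) -> Tuple[str, ...]:
        return tuple(m.iri for m in self.matches)

    def as_json(self, axioms: Optional[AxiomSet] = None) -> list:
        from .owl_model import RDFS_LABEL
        labels = {}
        if axioms is not None:
            labels = {s: v for p, s, v in axioms.annotations
                      if p == RDFS_LABEL}
        return [{"iri": m.iri, "label": labels.get(m.iri, ""),
                 "evidence": list(m.evidence)} for m in self.matches]


def _result(found: Dict[str, List[str]]) -> QueryResult:
    return QueryResult(tuple(
        QueryMatch(iri, tuple(found[iri])) for iri in sorted(found)))


def _named_subclass_children(axioms: AxiomSet) -> Dict[str, Set[str]]:
    """parent iri -> asserted named subclasses."""
    children: Dict[str, Set[str]] = {}
    for subject, expr in axioms.subclass_axioms:
        if isinstance(expr, Named):
            children.setdefault(expr.iri, set()).add(subject)
    return children


def descendants(axioms: AxiomSet, iri: str) -> Set[str]:
    """Reflexive-transitive closure of named subclass edges below iri."""
    children = _named_subclass_children(axioms)
    out = {iri}
    stack = [iri]
    while stack:
        for child in children.get(stack.pop(), ()):
            if child not in out:
                out.add(child)
                stack.append(child)
    return out


def _aggregate_conjuncts(expr: ClassExpression):
    """Operands of a has_proper_part some (... and ...) pattern, else None."""
    if (isinstance(expr, Some) and expr.prop == HAS_PROPER_PART
            and isinstance(expr.filler, And)):
        return expr.filler.operands
    return None


def _granular_parts(conjuncts) -> Set[str]:
    return {c.filler.iri for c in conjuncts
            if isinstance(c, Some) and c.prop == HAS_GRANULAR_PART
            and isinstance(c.filler, Named)}


def _borne_roles(conjuncts) -> Set[str]:
    return {c.filler.iri for c in conjuncts
            if isinstance(c, Some) and c.prop == BEARER_OF
            and isinstance(c.filler, Named)}


def _render_axiom(subject: str, expr: ClassExpression) -> str:
    return f"SubClassOf(<{subject}> {render_expression(expr)})"


def molecules_with_disposition(axioms: AxiomSet, disposition_iri: str
                               ) -> Dict[str, str]:
    """molecule iri -> rendered disposition axiom."""
    out: Dict[str, str] = {}
    for subject, expr in axioms.subclass_axioms:
        if (isinstance(expr, Some) and expr.prop == BEARER_OF
                and isinstance(expr.filler, Named)
                and expr.filler.iri == disposition_iri):
            out[subject] = _render_axiom(subject, expr)
    return out


def products_with_disposition(axioms: AxiomSet, isoenzyme: str, mode: str
                              ) -> QueryResult:
    """Drug products whose active-ingredient grains bear the disposition
    for (isoenzyme, mode), directly or via the subclass closure."""
    disposition = tax.iri_for(tax.disposition_label(isoenzyme, mode))
    active_role = tax.iri_for("active ingredient role")
    molecules = molecules_with_disposition(axioms, disposition)

    found: Dict[str, List[str]] = {}
    for subject, expr in axioms.subclass_axioms:
        conjuncts = _aggregate_conjuncts(expr)
        if conjuncts is None or active_role not in _borne_roles(conjuncts):
            continue
        hits = _granular_parts(conjuncts) & molecules.keys()
        if not hits:
            continue
        evidence = [_render_axiom(subject, expr)]
        evidence += [molecules[m] for m in sorted(hits)]
        found.setdefault(subject, evidence)
        for desc in descendants(axioms, subject):
            if desc != subject:
                found.setdefault(
                    desc, evidence + [_render_axiom(desc, Named(subject))])
    return _result(found)


def products_with_excipient(axioms: AxiomSet, ingredient_iri: str
                            ) -> QueryResult:
    """Products whose *excipient* conjunct has the given grain: a
    matching aggregate must bear a role from the excipient branch, so an
    ingredient present only as active ingredient does not match."""
    excipient_roles = descendants(axioms, tax.iri_for("excipient role"))
    found: Dict[str, List[str]] = {}
    for subject, expr in axioms.subclass_axioms:
        conjuncts = _aggregate_conjuncts(expr)
        if conjuncts is None:
            continue
        if not (_borne_roles(conjuncts) & excipient_roles):
            continue
        if ingredient_iri not in _granular_parts(conjuncts):
            continue
        evidence = [_render_axiom(subject, expr)]
        found.setdefault(subject, evidence)
        for desc in descendants(axioms, subject):
            if desc != subject:
                found.setdefault(
                    desc, evidence + [_render_axiom(desc, Named(subject))])
    return _result(found)


def ddi_candidate_pairs(axioms: AxiomSet, isoenzyme: str
                        ) -> Set[Tuple[str, str]]:
    """Ordered (inhibitor product, substrate product) pairs for one
    isoenzyme: every product inhibiting it crossed with every product
    metabolized by it, self-pairs excluded.  A product bearing both
    modes pairs with others in both directions, never with itself."""
    inhibitors = products_with_disposition(axioms, isoenzyme,
                                           "inhibitor").iris
    substrates = products_with_disposition(axioms, isoenzyme,
                                           "substrate").iris
    return {(i, s) for i in inhibitors for s in substrates if i != s}
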