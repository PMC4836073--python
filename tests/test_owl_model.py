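"""Axiom patterns, assembly placement, and serializer round-trips."""

import random

import pytest
from hypothesis import given, strategies as st

from rxowl import role_taxonomy as tax
from rxowl.owl_model import (And, AxiomSet, BEARER_OF, DataHasValue,
                             HAS_GRANULAR_PART, HAS_MEASUREMENT_UNIT,
                             HAS_PROPER_PART, HAS_SPECIFIED_VALUE, HasValue,
                             MASS, Named, OWLParseError, SMA, Some,
                             assemble_ontology, concept_iri,
                             emit_active_ingredient_expression,
                             emit_cyp_axiom, emit_excipient_expression,
                             parse, serialize, serialize_rdfxml, unit_iri)
from rxowl.rrf_io import AtomRecord, RelationshipRecord
from rxowl.excipient_extraction import ExcipientLink
from rxowl.strength_extraction import StrengthRecord


def test_active_ingredient_with_strength_node_for_node():
    """The 325 MG tablet pattern: aggregate, grain, role, mass-value."""
    acetaminophen = concept_iri("161")
    expr = emit_active_ingredient_expression(
        acetaminophen, (325, unit_iri("MG")))
    assert expr == Some(HAS_PROPER_PART, And((
        Named(SMA),
        Some(HAS_GRANULAR_PART, Named(acetaminophen)),
        Some(BEARER_OF, Named(tax.iri_for("active ingredient role"))),
        Some(BEARER_OF, And((
            Named(MASS),
            DataHasValue(HAS_SPECIFIED_VALUE, "325"),
            HasValue(HAS_MEASUREMENT_UNIT, unit_iri("MG")),
        ))),
    )))


def test_strengthless_expression_is_subtree_of_strengthful():
    ramipril = concept_iri("35296")
    bare = emit_active_ingredient_expression(ramipril)
    full = emit_active_ingredient_expression(ramipril, (5, unit_iri("MG")))
    assert bare.filler.operands == full.filler.operands[:3]
    assert len(full.filler.operands) == 4


def test_non_positive_strength_rejected():
    with pytest.raises(ValueError):
        emit_active_ingredient_expression(concept_iri("1"),
                                          (0, unit_iri("MG")))


def test_excipient_expression_shape_and_role_guard(scaffold):
    povidone = concept_iri("8031")
    role = tax.iri_for("binding excipient role")
    expr = emit_excipient_expression(povidone, role, scaffold)
    assert expr == Some(HAS_PROPER_PART, And((
        Named(SMA),
        Some(HAS_GRANULAR_PART, Named(povidone)),
        Some(BEARER_OF, Named(role)),
    )))
    # same shape with the generic default role
    generic = emit_excipient_expression(
        povidone, tax.iri_for("excipient role"), scaffold)
    assert generic.filler.operands[2].filler.iri == \
        tax.iri_for("excipient role")
    with pytest.raises(ValueError):
        emit_excipient_expression(
            povidone, tax.iri_for("active ingredient role"), scaffold)


def test_cyp_axiom_shape_guard_and_set_semantics(scaffold):
    molecule = concept_iri("283742")
    disp = tax.iri_for("function-inhibiting CYP2C19 binding disposition")
    subject, expr = emit_cyp_axiom(molecule, disp, scaffold)
    assert (subject, expr) == (molecule, Some(BEARER_OF, Named(disp)))
    with pytest.raises(ValueError):
        emit_cyp_axiom(molecule, tax.iri_for("excipient role"), scaffold)
    axioms = AxiomSet()
    axioms.add_subclass(subject, expr)
    before = len(axioms)
    axioms.add_subclass(subject, expr)
    assert len(axioms) == before


def test_two_dispositions_give_two_independent_axioms(scaffold):
    molecule = concept_iri("283742")
    axioms = AxiomSet()
    for mode in ("substrate", "inhibitor"):
        disp = tax.iri_for(tax.disposition_label("CYP2C19", mode))
        axioms.add_subclass(*emit_cyp_axiom(molecule, disp, scaffold))
    assert sum(1 for s, _ in axioms.subclass_axioms if s == molecule) == 2


@pytest.fixture
def tiny_assembly(scaffold):
    """1 SCD, 2 SBDs under it, 1 strength, 2 excipient links."""
    atoms = [
        AtomRecord("100", "a1", "RXNORM", "SCD", "drug 10 MG Oral Tablet"),
        AtomRecord("200", "a2", "RXNORM", "SBD", "brand A"),
        AtomRecord("201", "a3", "RXNORM", "SBD", "brand B"),
        AtomRecord("300", "a4", "RXNORM", "IN", "drugamol"),
        AtomRecord("301", "a5", "RXNORM", "IN", "povidone"),
    ]
    rels = [
        RelationshipRecord("100", "", "200", "", "tradename_of", "RXNORM"),
        RelationshipRecord("100", "", "201", "", "tradename_of", "RXNORM"),
    ]
    strengths = [StrengthRecord("100", "300", 10.0, "MG")]
    links = [ExcipientLink("200", "301"), ExcipientLink("201", "301")]
    return assemble_ontology(scaffold, links, strengths, [], atoms, rels)


def test_assembly_placement_rule(tiny_assembly):
    strength_subjects = set()
    excipient_subjects = set()
    active_role = tax.iri_for("active ingredient role")
    for subject, expr in tiny_assembly.subclass_axioms:
        if not isinstance(expr, Some) or expr.prop != HAS_PROPER_PART:
            continue
        roles = {o.filler.iri for o in expr.filler.operands
                 if isinstance(o, Some) and o.prop == BEARER_OF
                 and isinstance(o.filler, Named)}
        if active_role in roles:
            strength_subjects.add(subject)
        else:
            excipient_subjects.add(subject)
    assert strength_subjects == {concept_iri("100")}
    assert excipient_subjects == {concept_iri("200"), concept_iri("201")}


def test_assembly_sbd_subclass_edges_and_annotations(tiny_assembly):
    assert (concept_iri("200"), Named(concept_iri("100"))) in \
        tiny_assembly.subclass_axioms
    from rxowl.owl_model import RXCUI_IRI
    annotated = {s for p, s, v in tiny_assembly.annotations
                 if p == RXCUI_IRI}
    assert {concept_iri(c) for c in ("100", "200", "201", "300", "301")} \
        <= annotated


def test_assembly_skips_unknown_concepts(scaffold):
    from rxowl.owl_model import AssembleReport
    report = AssembleReport()
    axioms = assemble_ontology(
        scaffold, [ExcipientLink("999", "998")], [], [],
        [AtomRecord("1", "a1", "RXNORM", "IN", "x")], [], report=report)
    assert report.skipped and report.n_excipient_axioms == 0
    # empty inputs -> scaffold-only ontology
    bare = assemble_ontology(scaffold, [], [], [],
                             [AtomRecord("1", "a1", "RXNORM", "IN", "x")],
                             [])
    assert not any(s.startswith(concept_iri(""))
                   for s, _ in bare.subclass_axioms)


def test_empty_axiom_set_round_trips():
    empty = AxiomSet()
    text = serialize(empty)
    assert text.startswith("Prefix(")
    assert parse(text) == empty


def test_parse_error_reports_line_number():
    with pytest.raises(OWLParseError) as err:
        parse("Prefix(owl:=<http://x>)\nOntology(<http://o>\n"
              "SubClassOf(<a> Bogus(<b>))\n)\n")
    assert err.value.lineno == 3
    with pytest.raises(OWLParseError):
        parse("no ontology here")


# --- property-based round-trip over random axiom sets ---------------------

_word = st.text(alphabet="abcdefghij0123456789", min_size=1, max_size=6)
_class_iri = _word.map(lambda w: f"https://t.example/C{w}")
_oprop_iri = _word.map(lambda w: f"https://t.example/P{w}")
_dprop_iri = _word.map(lambda w: f"https://t.example/D{w}")
_indiv_iri = _word.map(lambda w: f"https://t.example/I{w}")
_literal = st.text(min_size=0, max_size=12)

_expr = st.recursive(
    _class_iri.map(Named),
    lambda kids: st.one_of(
        st.tuples(_oprop_iri, kids).map(lambda t: Some(*t)),
        st.tuples(_oprop_iri, _indiv_iri).map(lambda t: HasValue(*t)),
        st.tuples(_dprop_iri, _literal).map(lambda t: DataHasValue(*t)),
        st.lists(kids, min_size=2, max_size=3).map(
            lambda l: And(tuple(l))),
    ),
    max_leaves=6,
)


@st.composite
def axiom_sets(draw):
    axioms = AxiomSet()
    for subject, expr in draw(st.lists(st.tuples(_class_iri, _expr),
                                       max_size=8)):
        axioms.add_subclass(subject, expr)
    for subject, value in draw(st.lists(st.tuples(_class_iri, _literal),
                                        max_size=4)):
        axioms.annotate(subject, "https://t.example/Alabel", value)
    return axioms


@given(axiom_sets())
def test_serialize_parse_identity(axioms):
    assert parse(serialize(axioms)) == axioms


@given(axiom_sets())
def test_serialization_is_permutation_invariant(axioms):
    text = serialize(axioms)
    rebuilt = AxiomSet()
    entries = list(axioms.subclass_axioms)
    random.Random(0).shuffle(entries)
    for subject, expr in entries:
        rebuilt.add_subclass(subject, expr)
    for prop, subject, value in sorted(axioms.annotations, reverse=True):
        rebuilt.annotate(subject, prop, value)
    for iri, kind in axioms.declarations.items():
        rebuilt.declare(iri, kind)
    assert serialize(rebuilt) == text


def test_awkward_literals_round_trip():
    axioms = AxiomSet()
    for value in ('back\\slash', 'quo"te', 'new\nline', 'both \\" mixed'):
        axioms.annotate("https://t.example/Cx",
                        "https://t.example/Alabel", value)
    assert parse(serialize(axioms)) == axioms


def test_rdfxml_export_is_valid_xml(tiny_assembly):
    text = serialize_rdfxml(tiny_assembly)
    import xml.etree.ElementTree as ET
    ET.fromstring(text)
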