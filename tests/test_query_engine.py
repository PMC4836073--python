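"""Disposition, excipient and DDI queries against hand-built and
generated ontologies."""

import pytest

from _oracles import brute_force_disposition_products
from rxowl import role_taxonomy as tax
from rxowl.owl_model import (AxiomSet, Named, add_scaffold, concept_iri,
                             emit_active_ingredient_expression,
                             emit_cyp_axiom, emit_excipient_expression,
                             unit_iri)
from rxowl.query_engine import (ddi_candidate_pairs,
                                products_with_disposition,
                                products_with_excipient)


def minimal_ontology(scaffold):
    """Product P (SCD) with molecule X inhibiting CYP2C19, a branded
    drug B below P, an excipient E in B, and molecule Y used only as an
    active ingredient elsewhere."""
    ax = AxiomSet()
    add_scaffold(ax, scaffold)
    P, B, X, E, Y, Q = (concept_iri(c)
                        for c in ("1", "2", "3", "4", "5", "6"))
    ax.add_subclass(P, emit_active_ingredient_expression(
        X, (10.0, unit_iri("MG"))))
    ax.add_subclass(*emit_cyp_axiom(
        X, tax.iri_for("function-inhibiting CYP2C19 binding disposition"),
        scaffold))
    ax.add_subclass(B, Named(P))  # branded drug below the clinical drug
    ax.add_subclass(B, emit_excipient_expression(
        E, tax.iri_for("excipient role"), scaffold))
    ax.add_subclass(Q, emit_active_ingredient_expression(Y))
    return ax, dict(P=P, B=B, X=X, E=E, Y=Y, Q=Q)


@pytest.fixture
def small(scaffold):
    return minimal_ontology(scaffold)


def test_disposition_query_finds_product_and_descendant(small):
    ax, c = small
    result = products_with_disposition(ax, "CYP2C19", "inhibitor")
    assert result.iris == tuple(sorted([c["P"], c["B"]]))
    for match in result.matches:
        assert match.evidence  # evidence path reconstructs the match


def test_disposition_query_empty_cases(scaffold, small):
    ax, _ = small
    empty = AxiomSet()
    assert products_with_disposition(empty, "CYP2C19",
                                     "inhibitor").iris == ()
    # no molecule bears the substrate disposition in the small ontology
    assert products_with_disposition(ax, "CYP2C19", "substrate").iris == ()
    with pytest.raises(ValueError):
        products_with_disposition(ax, "CYP9Z9", "inhibitor")


def test_excipient_query_distinguishes_roles(small):
    ax, c = small
    # povidone-style excipient: only the branded drug carries it
    assert products_with_excipient(ax, c["E"]).iris == (c["B"],)
    # Y occurs only as an active ingredient: roles distinguish
    assert products_with_excipient(ax, c["Y"]).iris == ()
    assert products_with_excipient(ax, "https://nowhere/unknown").iris == ()


def test_ddi_pairs_hand_enumeration(scaffold):
    ax = AxiomSet()
    add_scaffold(ax, scaffold)
    P1, P2, X1, X2 = (concept_iri(c) for c in ("11", "12", "13", "14"))
    ax.add_subclass(P1, emit_active_ingredient_expression(X1))
    ax.add_subclass(P2, emit_active_ingredient_expression(X2))
    ax.add_subclass(*emit_cyp_axiom(
        X1, tax.iri_for("function-inhibiting CYP2D6 binding disposition"),
        scaffold))
    ax.add_subclass(*emit_cyp_axiom(
        X2, tax.iri_for("CYP2D6 active site binding disposition"),
        scaffold))
    assert ddi_candidate_pairs(ax, "CYP2D6") == {(P1, P2)}
    assert ddi_candidate_pairs(ax, "CYP2C19") == set()


def test_ddi_both_modes_product_never_self_paired(scaffold):
    ax = AxiomSet()
    add_scaffold(ax, scaffold)
    P1, P2, X1, X2 = (concept_iri(c) for c in ("21", "22", "23", "24"))
    ax.add_subclass(P1, emit_active_ingredient_expression(X1))
    ax.add_subclass(P2, emit_active_ingredient_expression(X2))
    for mode in ("substrate", "inhibitor"):  # esomeprazole-style molecule
        ax.add_subclass(*emit_cyp_axiom(
            X1, tax.iri_for(tax.disposition_label("CYP2C19", mode)),
            scaffold))
    ax.add_subclass(*emit_cyp_axiom(
        X2, tax.iri_for("CYP2C19 active site binding disposition"),
        scaffold))
    pairs = ddi_candidate_pairs(ax, "CYP2C19")
    # brute-force enumeration: inhibitors {P1}, substrates {P1, P2}
    assert pairs == {(P1, P2)}
    assert (P1, P1) not in pairs


def test_query_monotone_under_axiom_addition(small, scaffold):
    ax, c = small
    before = set(products_with_disposition(ax, "CYP2C19",
                                           "inhibitor").iris)
    ax.add_subclass(*emit_cyp_axiom(
        c["Y"], tax.iri_for("function-inhibiting CYP2C19 binding "
                            "disposition"), scaffold))
    after = set(products_with_disposition(ax, "CYP2C19",
                                          "inhibitor").iris)
    assert before <= after
    assert c["Q"] in after


def test_results_sorted_and_duplicate_free(built_ontology):
    for mode in ("substrate", "inhibitor"):
        iris = products_with_disposition(built_ontology, "CYP2D6",
                                         mode).iris
        assert list(iris) == sorted(set(iris))


def test_brute_force_scan_equivalence_on_built_ontology(built_ontology):
    active = tax.iri_for("active ingredient role")
    for iso in ("CYP2C19", "CYP2D6"):
        for mode in ("substrate", "inhibitor"):
            disp = tax.iri_for(tax.disposition_label(iso, mode))
            expected = brute_force_disposition_products(
                built_ontology, disp, active)
            got = set(products_with_disposition(built_ontology, iso,
                                                mode).iris)
            assert got == expected


def test_planted_disposition_products_recovered(built_ontology,
                                                fixture_bundle):
    manifest = fixture_bundle["manifest"]
    for key, expected in manifest.expected_disposition_products.items():
        iso, mode = key.split(":")
        got = sorted(
            iri.rsplit("RXCUI_", 1)[1]
            for iri in products_with_disposition(built_ontology, iso,
                                                 mode).iris)
        assert got == expected, key
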