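"""Dose-form filtering, strength-string grammar, SCD->SCDC->IN walk."""

import pytest

from _oracles import brute_force_strengths
from rxowl.rrf_io import AtomRecord, AttributeRecord, RelationshipRecord
from rxowl.strength_extraction import (DoseFormFilter, StrengthRejection,
                                       extract_strengths,
                                       is_discrete_solid_form,
                                       parse_strength_string)


def atom(rxcui, rxaui, sab, tty, name):
    return AtomRecord(rxcui, rxaui, sab, tty, name)


@pytest.mark.parametrize("atv, expected", [
    ("325 MG", (325.0, "MG")),
    ("0.25 MG", (0.25, "MG")),
    ("50 mcg", (50.0, "MCG")),
    ("10 UNT", (10.0, "UNT")),
])
def test_parse_strength_accepts_number_unit(atv, expected):
    assert parse_strength_string(atv) == expected


@pytest.mark.parametrize("atv, reason", [
    ("10 MG/ML", "concentration"),
    ("2 MG/ML / 20 MG/ML", "concentration"),
    ("325 STONE", "unknown-unit"),
    ("1,000 MG", "malformed"),
    ("MG 325", "malformed"),
])
def test_parse_strength_rejections(atv, reason):
    rejection = parse_strength_string(atv)
    assert isinstance(rejection, StrengthRejection)
    assert rejection.reason == reason


def test_empty_strength_string_is_an_error_not_a_rejection():
    with pytest.raises(ValueError):
        parse_strength_string("")


@pytest.mark.parametrize("name, expected", [
    ("furosemide 20 MG Oral Tablet", True),
    ("dimethicone 10 MG/ML Topical Cream", False),
    ("omeprazole 20 MG Delayed Release Oral Capsule", True),
    ("zomig 5 MG Caplet", True),
    ("guaifenesin 20 MG/ML Oral Solution", False),
])
def test_dose_form_from_trailing_name_phrase(name, expected):
    scd = atom("1", "a1", "RXNORM", "SCD", name)
    assert is_discrete_solid_form(scd, [], []) is expected


def test_dose_form_relationship_takes_precedence_over_name():
    scd = atom("1", "a1", "RXNORM", "SCD", "opaque concept name")
    df = atom("2", "a2", "RXNORM", "DF", "Oral Tablet")
    rel = [RelationshipRecord("2", "", "1", "", "has_dose_form", "RXNORM")]
    assert is_discrete_solid_form(scd, rel, [scd, df]) is True


def test_dose_form_filter_matches_whole_words_only():
    f = DoseFormFilter(("tablet",))
    assert not f.matches("Tabletop Solution")
    assert f.matches("Chewable TABLET")
    with pytest.raises(ValueError):
        DoseFormFilter(())


def test_nameless_scd_without_dose_form_relationship_errors():
    scd = atom("1", "a1", "RXNORM", "SCD", "")
    with pytest.raises(ValueError):
        is_discrete_solid_form(scd, [], [])


@pytest.fixture
def chain_tables():
    """SCD -> SCDC ('acetaminophen 325 MG') -> IN with RXN_STRENGTH."""
    atoms = [
        atom("100", "c1", "RXNORM", "SCD",
             "acetaminophen 325 MG Oral Tablet"),
        atom("101", "c2", "RXNORM", "SCDC", "acetaminophen 325 MG"),
        atom("102", "c3", "RXNORM", "IN", "acetaminophen"),
    ]
    rels = [
        RelationshipRecord("101", "", "100", "", "consists_of", "RXNORM"),
        RelationshipRecord("102", "", "101", "", "has_ingredient",
                           "RXNORM"),
    ]
    sats = [AttributeRecord("101", "c2", "RXN_STRENGTH", "325 MG",
                            "RXNORM")]
    return atoms, rels, sats


def test_single_chain_yields_one_record(chain_tables):
    atoms, rels, sats = chain_tables
    records, report = extract_strengths(atoms, rels, sats)
    assert len(records) == 1
    rec = records[0]
    assert (rec.scd_rxcui, rec.ingredient_rxcui, rec.value, rec.unit) == \
        ("100", "102", 325.0, "MG")
    assert report.n_scds_solid == 1


def test_scd_without_components_warns(chain_tables):
    atoms, _, sats = chain_tables
    records, report = extract_strengths(atoms, [], sats)
    assert records == []
    assert any("consists_of" in w for w in report.warnings)


def test_two_ingredient_scd_yields_two_records(chain_tables):
    atoms, rels, sats = chain_tables
    atoms += [
        atom("103", "c4", "RXNORM", "SCDC", "caffeine 65 MG"),
        atom("104", "c5", "RXNORM", "IN", "caffeine"),
    ]
    rels += [
        RelationshipRecord("103", "", "100", "", "consists_of", "RXNORM"),
        RelationshipRecord("104", "", "103", "", "has_ingredient",
                           "RXNORM"),
    ]
    sats += [AttributeRecord("103", "c4", "RXN_STRENGTH", "65 MG",
                             "RXNORM")]
    records, _ = extract_strengths(atoms, rels, sats)
    assert {(r.ingredient_rxcui, r.value) for r in records} == {
        ("102", 325.0), ("104", 65.0)}


def test_non_solid_scd_yields_no_records(chain_tables):
    atoms, rels, sats = chain_tables
    atoms[0] = atom("100", "c1", "RXNORM", "SCD",
                    "acetaminophen 32.5 MG/ML Oral Solution")
    sats = [AttributeRecord("101", "c2", "RXN_STRENGTH", "32.5 MG/ML",
                            "RXNORM")]
    records, report = extract_strengths(atoms, rels, sats)
    assert records == []
    assert report.n_scds_solid == 0


def test_missing_and_rejected_strengths_reported(chain_tables):
    atoms, rels, _ = chain_tables
    records, report = extract_strengths(atoms, rels, [])
    assert records == [] and report.n_missing_strength == 1
    bad = [AttributeRecord("101", "c2", "RXN_STRENGTH", "325 PEBBLES",
                           "RXNORM")]
    records, report = extract_strengths(atoms, rels, bad)
    assert records == [] and report.n_rejected == 1
    assert report.rejections[0].reason == "unknown-unit"


def test_agrees_with_brute_force_join_on_fixture(fixture_bundle):
    conso_b, rel_b, sat_b = fixture_bundle["blobs"]
    records, _ = extract_strengths(fixture_bundle["atoms"],
                                   fixture_bundle["rels"],
                                   fixture_bundle["sats"])
    got = {(r.scd_rxcui, r.ingredient_rxcui, r.value, r.unit)
           for r in records}
    assert got == brute_force_strengths(conso_b, rel_b, sat_b)
    assert got == fixture_bundle["manifest"].expected_strengths


def test_record_count_bounded_by_parsable_components(fixture_bundle):
    records, _ = extract_strengths(fixture_bundle["atoms"],
                                   fixture_bundle["rels"],
                                   fixture_bundle["sats"])
    parsable = 0
    strengths = {a.rxcui: a.atv for a in fixture_bundle["sats"]
                 if a.atn == "RXN_STRENGTH"}
    for rel in fixture_bundle["rels"]:
        if rel.rela != "consists_of":
            continue
        atv = strengths.get(rel.rxcui1)
        if atv and not isinstance(parse_strength_string(atv),
                                  StrengthRejection):
            parsable += 1
    assert len(records) <= parsable
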