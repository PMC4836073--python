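import io

import pytest
from hypothesis import settings

from rxowl import build_scaffold, parse_rrf
from rxowl.synthetic_fixtures import FixtureSpec, generate_fixture

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scaffold():
    return build_scaffold()


@pytest.fixture(scope="session")
def fixture_bundle():
    """A mid-size synthetic release: raw blobs, parsed tables, manifest."""
    spec = FixtureSpec(seed=17, n_ingredients=8, n_scds=12,
                       n_sbds_per_scd=2, n_excipients_per_sbd=3,
                       fraction_scd_only_products=0.3,
                       fraction_non_solid_forms=0.25)
    conso_b, rel_b, sat_b, manifest = generate_fixture(spec)
    return {
        "blobs": (conso_b, rel_b, sat_b),
        "atoms": parse_rrf("CONSO", io.BytesIO(conso_b)),
        "rels": parse_rrf("REL", io.BytesIO(rel_b)),
        "sats": parse_rrf("SAT", io.BytesIO(sat_b)),
        "manifest": manifest,
    }


@pytest.fixture(scope="session")
def built_ontology(fixture_bundle, scaffold):
    """The fixture release assembled into an axiom set."""
    from rxowl import (extract_excipient_links, extract_strengths,
                       load_cyp_table, resolve_molecules)
    from rxowl.owl_model import assemble_ontology

    atoms = fixture_bundle["atoms"]
    rels = fixture_bundle["rels"]
    links, _ = extract_excipient_links(atoms, rels)
    strengths, _ = extract_strengths(atoms, rels, fixture_bundle["sats"])
    cyps = resolve_molecules(
        load_cyp_table(fixture_bundle["manifest"].cyp_table_csv), atoms)
    return assemble_ontology(scaffold, links, strengths, cyps, atoms, rels)
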