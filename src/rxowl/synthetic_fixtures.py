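"""Synthetic RxNorm-style release generator with a ground-truth manifest.

Real RxNorm releases are licensed and far too large to ship, so every
pipeline stage is exercised against generated RRF triples that emulate
the structures extraction depends on: normalized ``RXNORM`` atoms of
term types IN/SCD/SBD/SCDC/DF, ``MTHSPL`` drug-product atoms carrying
``has_inactive_ingredient`` rows, ``consists_of``/``has_ingredient``
chains, ``has_dose_form`` links, ``RXN_STRENGTH`` attributes, and
tradename links from branded to clinical drugs.

The generator also plants the two traps the method must survive:
*SCD-only products* (SPL products whose concept has no branded-drug
atom — their excipient rows must be excluded, the way a topical cream
shared by dozens of label-only products would be) and *non-solid dose
forms* (whose concentration-style strengths are out of scope and must
yield no strength records).

Alongside the tables it emits a :class:`Manifest` holding the exact
expected extraction outputs, derived *by construction* while planting —
never by running the pipeline — so the manifest is an independent
oracle.  No attempt is made at statistical realism of ingredient
frequencies; the point is structural coverage.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from .role_taxonomy import ISOENZYMES, MODES

# Packaged word fragments: names stay readable in failure reports.
_PREFIXES = [
    "zal", "tor", "mev", "cal", "dex", "flu", "gab", "hal", "ibu", "jan",
    "kel", "lor", "met", "nar", "oxi", "pra", "quin", "ris", "sul", "tam",
    "val", "war", "xan", "ery", "zon",
]
_MIDDLES = ["a", "o", "i", "e", "u", "ami", "oxa", "ipra", "eta", "ulo"]
_SUFFIXES = ["pril", "olol", "statin", "mycin", "azole", "idine", "oxacin",
             "parin", "mab", "fenac", "setron", "zepam"]
_EXCIPIENT_WORDS = [
    "povidone", "talc", "lactose", "starch", "cellulose", "stearate",
    "sucrose", "gelatin", "dextrose", "glycol", "silica", "carbomer",
    "mannitol", "sorbitol", "shellac", "dye",
]
_BRAND_WORDS = ["Vexor", "Calmia", "Durol", "Zentra", "Plenix", "Ortavan",
                "Lumexa", "Britol", "Quantor", "Selvia", "Normax", "Tavero"]

_SOLID_FORMS = ["Oral Tablet", "Oral Capsule", "Oral Caplet",
                "Delayed Release Oral Capsule",
                "Extended Release Oral Tablet"]
_NON_SOLID_FORMS = ["Topical Cream", "Oral Solution", "Injectable Solution",
                    "Ophthalmic Solution"]

_STRENGTH_VALUES = [5, 10, 20, 25, 40, 50, 100, 200, 250, 325, 500]


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_ingredients: int = 8
    n_scds: int = 10
    n_sbds_per_scd: int = 2
    n_excipients_per_sbd: int = 3
    n_excipient_pool: int = 10
    fraction_scd_only_products: float = 0.2
    fraction_non_solid_forms: float = 0.2
    malformed_row_count: int = 0
    #: fraction of active-ingredient molecules given CYP assignments
    fraction_cyp_assigned: float = 0.5

    def validate(self) -> None:
        for name in ("n_ingredients", "n_scds", "n_sbds_per_scd",
                     "n_excipients_per_sbd", "n_excipient_pool",
                     "malformed_row_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("fraction_scd_only_products",
                     "fraction_non_solid_forms", "fraction_cyp_assigned"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_scds > 0 and self.n_ingredients == 0:
            raise ValueError("clinical drugs requested but zero ingredients")
        if (self.n_scds > 0 and self.n_sbds_per_scd > 0
                and self.n_excipients_per_sbd > 0
                and self.n_excipient_pool == 0):
            raise ValueError("excipient links requested but empty pool")
        if self.n_excipients_per_sbd > self.n_excipient_pool:
            raise ValueError(
                "n_excipients_per_sbd exceeds the excipient pool")


@dataclass
class Manifest:
    """Ground truth planted into the tables, by construction."""

    spec: FixtureSpec
    n_atoms: int = 0
    n_relationships: int = 0
    n_attributes: int = 0
    ingredient_rxcuis: Dict[str, str] = field(default_factory=dict)  # name->cui
    excipient_rxcuis: Dict[str, str] = field(default_factory=dict)
    scd_rxcuis: List[str] = field(default_factory=list)
    sbd_to_scd: Dict[str, str] = field(default_factory=dict)
    solid_scds: Set[str] = field(default_factory=set)
    non_solid_scds: Set[str] = field(default_factory=set)
    scd_only_product_rows: int = 0
    expected_excipient_links: Set[Tuple[str, str]] = field(
        default_factory=set)
    expected_strengths: Set[Tuple[str, str, float, str]] = field(
        default_factory=set)
    #: "ISO:mode" -> sorted product rxcuis a disposition query must return
    expected_disposition_products: Dict[str, List[str]] = field(
        default_factory=dict)
    cyp_rows: List[Tuple[str, str, str]] = field(default_factory=list)

    @property
    def cyp_table_csv(self) -> str:
        lines = ["molecule,isoenzyme,mode"]
        lines += [f"{m},{i},{mo}" for m, i, mo in self.cyp_rows]
        return "\n".join(lines) + "\n"

    def as_json(self) -> str:
        return json.dumps({
            "spec": vars(self.spec),
            "n_atoms": self.n_atoms,
            "n_relationships": self.n_relationships,
            "n_attributes": self.n_attributes,
            "ingredient_rxcuis": self.ingredient_rxcuis,
            "excipient_rxcuis": self.excipient_rxcuis,
            "scd_rxcuis": self.scd_rxcuis,
            "sbd_to_scd": self.sbd_to_scd,
            "solid_scds": sorted(self.solid_scds),
            "non_solid_scds": sorted(self.non_solid_scds),
            "scd_only_product_rows": self.scd_only_product_rows,
            "expected_excipient_links": sorted(
                list(p) for p in self.expected_excipient_links),
            "expected_strengths": sorted(
                list(s) for s in self.expected_strengths),
            "expected_disposition_products":
                self.expected_disposition_products,
            "cyp_rows": [list(r) for r in self.cyp_rows],
        }, indent=2, sort_keys=True)


class _Minter:
    """Sequential identifiers from a seed-dependent offset, so fixture
    ids never collide with real low-numbered RxCUIs."""

    def __init__(self, seed: int):
        self.next_cui = 9_000_000 + (seed % 9000) * 100_000
        self.next_aui = self.next_cui * 10

    def cui(self) -> str:
        self.next_cui += 1
        return str(self.next_cui)

    def aui(self) -> str:
        self.next_aui += 1
        return str(self.next_aui)


def _conso_line(rxcui, rxaui, sab, tty, name, suppress="N") -> str:
    f = [""] * 18
    f[0], f[7], f[11], f[12], f[14], f[16] = (
        rxcui, rxaui, sab, tty, name, suppress)
    return "|".join(f) + "|"


def _rel_line(rxcui1, rxaui1, rxcui2, rxaui2, rela, sab) -> str:
    f = [""] * 16
    f[0], f[1], f[4], f[5], f[7], f[10], f[14] = (
        rxcui1, rxaui1, rxcui2, rxaui2, rela, sab, "N")
    return "|".join(f) + "|"


def _sat_line(rxcui, rxaui, atn, atv, sab) -> str:
    f = [""] * 13
    f[0], f[3], f[8], f[9], f[10], f[11] = (
        rxcui, rxaui, atn, sab, atv, "N")
    return "|".join(f) + "|"


def _unique_name(rng: random.Random, taken: Set[str]) -> str:
    for _ in range(100):
        name = (rng.choice(_PREFIXES) + rng.choice(_MIDDLES)
                + rng.choice(_SUFFIXES))
        if name not in taken:
            taken.add(name)
            return name
    name = f"{rng.choice(_PREFIXES)}{len(taken)}{rng.choice(_SUFFIXES)}"
    taken.add(name)
    return name


def generate_fixture(spec: FixtureSpec
                     ) -> Tuple[bytes, bytes, bytes, Manifest]:
    """Emit (RXNCONSO, RXNREL, RXNSAT) byte streams plus the manifest.

    Deterministic: the same spec (seed included) always yields
    byte-identical files.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    minter = _Minter(spec.seed)
    manifest = Manifest(spec=spec)
    conso: List[str] = []
    rel: List[str] = []
    sat: List[str] = []
    taken_names: Set[str] = set()

    # --- active ingredient molecules (RXNORM/IN)
    ingredients: List[Tuple[str, str]] = []  # (rxcui, name)
    for _ in range(spec.n_ingredients):
        name = _unique_name(rng, taken_names)
        cui = minter.cui()
        conso.append(_conso_line(cui, minter.aui(), "RXNORM", "IN", name))
        ingredients.append((cui, name))
        manifest.ingredient_rxcuis[name] = cui

    # --- excipient molecules (RXNORM/IN, plus an MTHSPL substance atom)
    excipients: List[Tuple[str, str, str]] = []  # (rxcui, name, spl_aui)
    for i in range(spec.n_excipient_pool):
        base = _EXCIPIENT_WORDS[i % len(_EXCIPIENT_WORDS)]
        name = base if i < len(_EXCIPIENT_WORDS) else f"{base} {i}"
        cui = minter.cui()
        conso.append(_conso_line(cui, minter.aui(), "RXNORM", "IN", name))
        spl_aui = minter.aui()
        conso.append(_conso_line(cui, spl_aui, "MTHSPL", "SU", name))
        excipients.append((cui, name, spl_aui))
        manifest.excipient_rxcuis[name] = cui

    # --- dose forms (RXNORM/DF)
    df_atoms: Dict[str, str] = {}  # form name -> rxcui
    for form in _SOLID_FORMS + _NON_SOLID_FORMS:
        cui = minter.cui()
        conso.append(_conso_line(cui, minter.aui(), "RXNORM", "DF", form))
        df_atoms[form] = cui

    # --- CYP assignments over a subset of the molecules
    molecule_dispositions: Dict[str, List[Tuple[str, str]]] = {}
    for cui, name in ingredients:
        if rng.random() >= spec.fraction_cyp_assigned:
            continue
        iso = rng.choice(ISOENZYMES)
        modes = (list(MODES) if rng.random() < 0.3
                 else [rng.choice(MODES)])
        molecule_dispositions[cui] = [(iso, mode) for mode in modes]
        for iso_, mode in molecule_dispositions[cui]:
            manifest.cyp_rows.append((name, iso_, mode))

    disposition_products: Dict[str, Set[str]] = {
        f"{iso}:{mode}": set() for iso in ISOENZYMES for mode in MODES}

    # --- clinical drugs with components, strengths and dose forms
    scds: List[Tuple[str, str, bool]] = []  # (rxcui, name, is_solid)
    for _ in range(spec.n_scds):
        is_solid = rng.random() >= spec.fraction_non_solid_forms
        form = (rng.choice(_SOLID_FORMS) if is_solid
                else rng.choice(_NON_SOLID_FORMS))
        n_ing = 2 if (rng.random() < 0.25 and len(ingredients) >= 2) else 1
        chosen = rng.sample(ingredients, n_ing)
        scd_cui = minter.cui()
        parts = []
        for ing_cui, ing_name in chosen:
            value = rng.choice(_STRENGTH_VALUES)
            unit = "MG" if rng.random() < 0.85 else "MCG"
            strength = (f"{value} {unit}" if is_solid
                        else f"{value} {unit}/ML")
            parts.append((ing_cui, ing_name, value, unit, strength))
        scd_name = " / ".join(f"{n} {s}" for _, n, _, _, s in parts) \
            + f" {form}"
        conso.append(_conso_line(scd_cui, minter.aui(), "RXNORM", "SCD",
                                 scd_name))
        rel.append(_rel_line(df_atoms[form], "", scd_cui, "",
                             "has_dose_form", "RXNORM"))
        for ing_cui, ing_name, value, unit, strength in parts:
            scdc_cui = minter.cui()
            scdc_aui = minter.aui()
            conso.append(_conso_line(scdc_cui, scdc_aui, "RXNORM", "SCDC",
                                     f"{ing_name} {strength}"))
            # entity2 RELA entity1: SCD consists_of SCDC
            rel.append(_rel_line(scdc_cui, "", scd_cui, "",
                                 "consists_of", "RXNORM"))
            rel.append(_rel_line(ing_cui, "", scdc_cui, "",
                                 "has_ingredient", "RXNORM"))
            sat.append(_sat_line(scdc_cui, scdc_aui, "RXN_STRENGTH",
                                 strength, "RXNORM"))
            if is_solid:
                manifest.expected_strengths.add(
                    (scd_cui, ing_cui, float(value), unit))
        scds.append((scd_cui, scd_name, is_solid))
        manifest.scd_rxcuis.append(scd_cui)
        (manifest.solid_scds if is_solid
         else manifest.non_solid_scds).add(scd_cui)
        if is_solid:
            for ing_cui, _, _, _, _ in parts:
                for iso, mode in molecule_dispositions.get(ing_cui, ()):
                    disposition_products[f"{iso}:{mode}"].add(scd_cui)

    # --- branded drugs, SPL product atoms, excipient rows
    for scd_cui, scd_name, is_solid in scds:
        for _ in range(spec.n_sbds_per_scd):
            brand = f"{rng.choice(_BRAND_WORDS)} {rng.choice(_BRAND_WORDS)}"
            sbd_cui = minter.cui()
            conso.append(_conso_line(sbd_cui, minter.aui(), "RXNORM",
                                     "SBD", f"{scd_name} [{brand}]"))
            # SBD tradename_of SCD
            rel.append(_rel_line(scd_cui, "", sbd_cui, "",
                                 "tradename_of", "RXNORM"))
            manifest.sbd_to_scd[sbd_cui] = scd_cui
            if is_solid:
                for key in disposition_products:
                    if scd_cui in disposition_products[key]:
                        disposition_products[key].add(sbd_cui)
            if spec.n_excipients_per_sbd == 0:
                continue
            spl_prod_aui = minter.aui()
            conso.append(_conso_line(sbd_cui, spl_prod_aui, "MTHSPL",
                                     "DP", brand))
            for exc_cui, _, exc_aui in rng.sample(
                    excipients, spec.n_excipients_per_sbd):
                # product (entity2) has_inactive_ingredient exc (entity1);
                # atom-level identifiers only, as SPL rows come.
                rel.append(_rel_line("", exc_aui, "", spl_prod_aui,
                                     "has_inactive_ingredient", "MTHSPL"))
                manifest.expected_excipient_links.add((sbd_cui, exc_cui))

    # --- SCD-only trap products: SPL products mapped to a clinical
    # drug concept with no branded atom; their rows must be excluded.
    for scd_cui, scd_name, _ in scds:
        if rng.random() >= spec.fraction_scd_only_products:
            continue
        trap_aui = minter.aui()
        conso.append(_conso_line(scd_cui, trap_aui, "MTHSPL", "DP",
                                 f"Label-only {scd_name}"))
        for exc_cui, _, exc_aui in rng.sample(
                excipients, min(2, len(excipients))):
            rel.append(_rel_line("", exc_aui, "", trap_aui,
                                 "has_inactive_ingredient", "MTHSPL"))
            manifest.scd_only_product_rows += 1

    manifest.expected_disposition_products = {
        key: sorted(products)
        for key, products in disposition_products.items()}
    manifest.n_atoms = len(conso)
    manifest.n_relationships = len(rel)
    manifest.n_attributes = len(sat)

    # --- malformed lines (lenient-mode fixtures only)
    for i in range(spec.malformed_row_count):
        conso.append(f"BAD|LINE|{i}|")

    rng.shuffle(conso)
    rng.shuffle(rel)
    rng.shuffle(sat)

    def blob(lines: List[str]) -> bytes:
        return ("\n".join(lines) + "\n" if lines else "").encode("utf-8")

    return blob(conso), blob(rel), blob(sat), manifest


def write_fixture(spec: FixtureSpec, directory) -> Manifest:
    """Write RXNCONSO.RRF / RXNREL.RRF / RXNSAT.RRF plus manifest.json
    into ``directory``; returns the manifest."""
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    conso, rel, sat, manifest = generate_fixture(spec)
    (directory / "RXNCONSO.RRF").write_bytes(conso)
    (directory / "RXNREL.RRF").write_bytes(rel)
    (directory / "RXNSAT.RRF").write_bytes(sat)
    (directory / "manifest.json").write_text(manifest.as_json())
    (directory / "cyp_table.csv").write_text(manifest.cyp_table_csv)
    return manifest
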