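"""Independent brute-force oracles used by the tests.

These work on raw pipe-split rows (not the package's record types) and
re-derive expected outputs by exhaustive joins, so they share no code
path with the extraction pipeline they check.
"""

import re

SUPPRESSED = {"Y", "O"}


def split_rows(blob: bytes, n_fields: int):
    rows = []
    for line in blob.decode("utf-8").splitlines():
        if not line:
            continue
        parts = line.split("|")
        if len(parts) == n_fields + 1 and parts[-1] == "":
            rows.append(parts[:-1])
    return rows


def brute_force_excipient_links(conso_blob: bytes, rel_blob: bytes):
    """Exhaustive three-table join for (SBD product, IN excipient) pairs."""
    conso = [r for r in split_rows(conso_blob, 18)
             if r[16] not in SUPPRESSED]
    rel = [r for r in split_rows(rel_blob, 16) if r[14] not in SUPPRESSED]
    aui_to_cui = {r[7]: r[0] for r in conso}
    sbd = {r[0] for r in conso if r[11] == "RXNORM" and r[12] == "SBD"}
    ins = {r[0] for r in conso if r[11] == "RXNORM" and r[12] == "IN"}
    links = set()
    for r in rel:
        if r[10] != "MTHSPL" or r[7] != "has_inactive_ingredient":
            continue
        # entity2 has_inactive_ingredient entity1
        product = r[4] or aui_to_cui.get(r[5])
        ingredient = r[0] or aui_to_cui.get(r[1])
        if product in sbd and ingredient in ins:
            links.add((product, ingredient))
    return links


_NUM_UNIT = re.compile(r"^\s*(\d+(?:\.\d+)?)\s+(MG|MCG|G|UNT|MEQ)\s*$",
                       re.IGNORECASE)


def brute_force_strengths(conso_blob: bytes, rel_blob: bytes,
                          sat_blob: bytes,
                          tokens=("tablet", "capsule", "caplet")):
    """Exhaustive SCD -> SCDC -> IN join with strength-string parsing."""
    conso = [r for r in split_rows(conso_blob, 18)
             if r[16] not in SUPPRESSED]
    rel = [r for r in split_rows(rel_blob, 16) if r[14] not in SUPPRESSED]
    sat = [r for r in split_rows(sat_blob, 13) if r[11] not in SUPPRESSED]
    scd = {r[0] for r in conso if r[11] == "RXNORM" and r[12] == "SCD"}
    scdc = {r[0] for r in conso if r[11] == "RXNORM" and r[12] == "SCDC"}
    ins = {r[0] for r in conso if r[11] == "RXNORM" and r[12] == "IN"}
    df_names = {r[0]: r[14] for r in conso
                if r[11] == "RXNORM" and r[12] == "DF"}

    solid = set()
    for r in rel:
        if r[7] == "has_dose_form" and r[4] in scd and r[0] in df_names:
            words = re.findall(r"[a-z]+", df_names[r[0]].lower())
            if any(t in words for t in tokens):
                solid.add(r[4])
    consists = [(r[4], r[0]) for r in rel
                if r[10] == "RXNORM" and r[7] == "consists_of"
                and r[4] in scd and r[0] in scdc]
    has_ing = [(r[4], r[0]) for r in rel
               if r[10] == "RXNORM" and r[7] == "has_ingredient"
               and r[4] in scdc and r[0] in ins]
    strength = {r[0]: r[10] for r in sat if r[8] == "RXN_STRENGTH"}

    out = set()
    for s, c in consists:
        if s not in solid:
            continue
        atv = strength.get(c)
        if atv is None or "/" in atv:
            continue
        m = _NUM_UNIT.match(atv)
        if not m:
            continue
        for c2, i in has_ing:
            if c2 == c:
                out.add((s, i, float(m.group(1)), m.group(2).upper()))
    return out


def brute_force_disposition_products(axioms, disposition_iri,
                                     active_role_iri):
    """Scan every declared class; a class qualifies if any superclass in
    its asserted-subclass closure carries an active-ingredient aggregate
    whose grain molecule bears the disposition."""
    from rxowl.owl_model import And, Named, Some
    from rxowl.owl_model import BEARER_OF, HAS_GRANULAR_PART, HAS_PROPER_PART

    bearers = {s for s, e in axioms.subclass_axioms
               if isinstance(e, Some) and e.prop == BEARER_OF
               and isinstance(e.filler, Named)
               and e.filler.iri == disposition_iri}

    def has_pattern(cls):
        for s, e in axioms.subclass_axioms:
            if s != cls or not isinstance(e, Some):
                continue
            if e.prop != HAS_PROPER_PART or not isinstance(e.filler, And):
                continue
            ops = e.filler.operands
            roles = {o.filler.iri for o in ops
                     if isinstance(o, Some) and o.prop == BEARER_OF
                     and isinstance(o.filler, Named)}
            grains = {o.filler.iri for o in ops
                      if isinstance(o, Some) and o.prop == HAS_GRANULAR_PART
                      and isinstance(o.filler, Named)}
            if active_role_iri in roles and grains & bearers:
                return True
        return False

    def ancestors(cls):
        out = {cls}
        changed = True
        while changed:
            changed = False
            for s, e in axioms.subclass_axioms:
                if s in out and isinstance(e, Named) and e.iri not in out:
                    out.add(e.iri)
                    changed = True
        return out

    return {cls for cls in axioms.declarations
            if axioms.declarations[cls] == "Class"
            and any(has_pattern(a) for a in ancestors(cls))}


def brute_force_excipient_products(axioms, ingredient_iri,
                                   excipient_role_iris):
    """Scan every declared class for an excipient-pattern ancestor whose
    grain is ``ingredient_iri`` and whose borne role is an excipient role."""
    from rxowl.owl_model import And, Named, Some
    from rxowl.owl_model import BEARER_OF, HAS_GRANULAR_PART, HAS_PROPER_PART

    def has_pattern(cls):
        for s, e in axioms.subclass_axioms:
            if s != cls or not isinstance(e, Some):
                continue
            if e.prop != HAS_PROPER_PART or not isinstance(e.filler, And):
                continue
            ops = e.filler.operands
            roles = {o.filler.iri for o in ops
                     if isinstance(o, Some) and o.prop == BEARER_OF
                     and isinstance(o.filler, Named)}
            grains = {o.filler.iri for o in ops
                      if isinstance(o, Some) and o.prop == HAS_GRANULAR_PART
                      and isinstance(o.filler, Named)}
            if (roles & set(excipient_role_iris)
                    and ingredient_iri in grains):
                return True
        return False

    def ancestors(cls):
        out = {cls}
        changed = True
        while changed:
            changed = False
            for s, e in axioms.subclass_axioms:
                if s in out and isinstance(e, Named) and e.iri not in out:
                    out.add(e.iri)
                    changed = True
        return out

    return {cls for cls in axioms.declarations
            if axioms.declarations[cls] == "Class"
            and any(has_pattern(a) for a in ancestors(cls))}
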