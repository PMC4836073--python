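"""The fixed ontology scaffold: excipient roles, the active ingredient
role, and CYP-isoenzyme binding dispositions.

Excipients are modeled realist-style: the excipient is a scattered
molecular aggregate (all the molecules of one kind added to a product),
and what makes it an excipient is a *role* the aggregate bears — a role
realized during manufacture, administration, identification or
preservation of the product.  A general ``excipient role`` sits at the
root with seventeen specific subtypes below it, each placed under the
genus its textual definition names (e.g. the glidant, anti-adherent and
anti-friction roles are kinds of lubricant role; the enteric coating
role is a kind of protective coating role).

Active-ingredient-hood is likewise a role of an aggregate, not a
property of single molecules: one molecule of an antacid neutralizes no
clinically relevant acid; the aggregate delivered in a tablet does.

Binding of a small molecule to a cytochrome P450 isoenzyme is instead a
*disposition* of the molecule (its tendency to bind is internal to its
physical structure, not socially conferred).  Two disposition classes
distinguish substrate binding (the molecule is destroyed while the
enzyme does its job) from inhibitory binding (the enzyme's active site
is subsequently unable to bind its substrates), each specialized for
CYP2C19 and CYP2D6.  The generic ``binding`` / ``protein binding`` /
``enzyme binding`` chain is imported from the Gene Ontology as
MIREOT-style stubs (IRI + label + definition only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

#: Namespace in which non-imported terms are minted.
NAMESPACE = "https://w3id.org/rxowl/"

GO_NS = "http://purl.obolibrary.org/obo/"


@dataclass(frozen=True)
class OntologyTerm:
    iri: str
    label: str
    parent_iris: Tuple[str, ...] = ()
    definition: str = ""
    #: True for declared external stub parents (BFO/GO imports).
    external: bool = False


# Packaged label -> numeric id table: minting is deterministic so that
# rebuilds and diffs are byte-stable.
_ID_TABLE: Dict[str, int] = {
    "role": 1,
    "disposition": 2,
    "excipient role": 10,
    "lubricant excipient role": 11,
    "glidant excipient role": 12,
    "anti-adherent excipient role": 13,
    "anti-friction excipient role": 14,
    "binding excipient role": 15,
    "coating excipient role": 16,
    "protective coating excipient role": 17,
    "enteric coating excipient role": 18,
    "administration coating excipient role": 19,
    "flavor coating excipient role": 20,
    "lubricant coating excipient role": 21,
    "color excipient role": 22,
    "flavor excipient role": 23,
    "disintegrant excipient role": 24,
    "preservative excipient role": 25,
    "sorbent excipient role": 26,
    "vehicle excipient role": 27,
    "active ingredient role": 30,
    "enzyme active site binding disposition": 40,
    "function-inhibiting enzyme-binding disposition": 41,
    "CYP2C19 active site binding disposition": 42,
    "function-inhibiting CYP2C19 binding disposition": 43,
    "CYP2D6 active site binding disposition": 44,
    "function-inhibiting CYP2D6 binding disposition": 45,
}

_GO_IDS = {
    "binding": "GO_0005488",
    "protein binding": "GO_0005515",
    "enzyme binding": "GO_0019899",
}


def iri_for(label: str) -> str:
    """Deterministic IRI for a scaffold label."""
    if label in _GO_IDS:
        return GO_NS + _GO_IDS[label]
    try:
        num = _ID_TABLE[label]
    except KeyError:
        raise KeyError(f"no packaged id for label {label!r}") from None
    return f"{NAMESPACE}RXOWL_{num:07d}"


def _term(label, parents=(), definition="", external=False) -> OntologyTerm:
    return OntologyTerm(
        iri=iri_for(label),
        label=label,
        parent_iris=tuple(iri_for(p) for p in parents),
        definition=definition,
        external=external,
    )


# (label, parent label, definition) — definitions quoted from the
# project's curated role analysis; parents are each definition's genus.
_EXCIPIENT_ROLES: List[Tuple[str, str, str]] = [
    ("excipient role", "role",
     "a role of a scattered molecular aggregate in aiding the manufacture, "
     "prolonging the shelf life, aiding the identification, or ensuring "
     "proper administration of a drug product"),
    ("lubricant excipient role", "excipient role",
     "An excipient role that is realized by a process of drug "
     "administration or a process of drug manufacturing and results in "
     "either 1) decreased adhesion between drug ingredients and "
     "manufacturing equipment or between drug ingredients and some part of "
     "an organism; 2) decreased friction between drug ingredients and "
     "manufacturing equipment or between drug ingredients and some part of "
     "an organism; or 3) decreased cohesion among particles within the "
     "drug preparation"),
    ("glidant excipient role", "lubricant excipient role",
     "A lubricant excipient role that is realized by a process of drug "
     "administration or a process of drug manufacturing and results in "
     "decreased cohesion or friction among particles within a drug "
     "preparation"),
    ("anti-adherent excipient role", "lubricant excipient role",
     "A lubricant excipient role that is realized by a process of drug "
     "administration or a process of drug manufacturing and results in "
     "decreased adhesion between drug ingredients and manufacturing "
     "equipment or between drug ingredients and some part of an organism"),
    ("anti-friction excipient role", "lubricant excipient role",
     "A lubricant excipient that is realized by a process of drug "
     "administration or a process of drug manufacturing and results in "
     "decreased friction between drug ingredients and manufacturing "
     "equipment or between drug ingredients and some part of an organism"),
    ("binding excipient role", "excipient role",
     "An excipient role that is realized by a process of drug "
     "manufacturing and results in increased volume or cohesion of the "
     "drug product."),
    ("coating excipient role", "excipient role",
     "An excipient role borne by an aggregate of molecules on the surface "
     "of a solid drug product that is realized by a process of delaying "
     "interaction between entities outside the drug product and the other "
     "ingredients in the drug product."),
    ("protective coating excipient role", "coating excipient role",
     "A coating excipient role that is realized by delaying denaturation, "
     "disintegration, or some other method of destruction of a drug "
     "preparation including its active ingredients."),
    ("enteric coating excipient role", "protective coating excipient role",
     "A protective coating excipient role that is realized by a process of "
     "delaying release of one or more active ingredients from the drug "
     "product until some targeted time or location, typically the small or "
     "large intestine, within an organism."),
    ("administration coating excipient role", "coating excipient role",
     "A coating excipient role that is realized by facilitating a process "
     "of drug administration"),
    ("flavor coating excipient role", "administration coating excipient role",
     "An administration coating excipient role that is realized by a drug "
     "manufacturing process that results in the drug product bearing a "
     "particular flavor quality."),
    ("lubricant coating excipient role",
     "administration coating excipient role",
     "An administration coating excipient role that is realized by "
     "decreased friction between the drug preparation and some part of an "
     "organism during drug administration"),
    ("color excipient role", "excipient role",
     "An excipient role that is realized by a process of drug "
     "manufacturing that results in a particular, desired color quality of "
     "the drug product."),
    ("flavor excipient role", "excipient role",
     "An excipient role that is realized by a process of drug "
     "manufacturing that results in the drug product bearing a particular "
     "flavor quality."),
    ("disintegrant excipient role", "excipient role",
     "An excipient role that is realized by a process of drug "
     "administration followed by the drug product breaking apart"),
    ("preservative excipient role", "excipient role",
     "An excipient role that is realized by increasing the duration of "
     "time that a drug product is effective or by inhibiting contamination "
     "of the drug product with a microorganism"),
    ("sorbent excipient role", "excipient role",
     "An excipient role that is realized by its bearer binding with water "
     "in the environment to prevent water binding with other ingredients "
     "in the drug product."),
    ("vehicle excipient role", "excipient role",
     "An excipient role that is realized by a completed process of the "
     "active ingredient reaching its intended destination during drug "
     "administration"),
]

ACTIVE_INGREDIENT_DEFINITION = (
    "a role borne by an aggregate of molecules that is a proper part of a "
    "drug product and that is realized by (1) administration of the drug "
    "to an organism followed by (2) some change in the structure or "
    "functioning of some part of the organism or its endosymbiotic "
    "organisms."
)

ENZYME_BINDING_DEFINITION = (
    "interacting selectively and non-covalently with any enzyme"
)
ACTIVE_SITE_DEFINITION = (
    "a disposition borne by some molecular entity that is realized by "
    "binding to some enzyme and being destroyed in a process that realizes "
    "some function of said enzyme"
)
FUNCTION_INHIBITING_DEFINITION = (
    "a disposition borne by some molecular entity that is realized by 1) "
    "binding to some enzyme and 2) subsequent inability of the active site "
    "of the enzyme to bind its substrate(s)."
)

ISOENZYMES = ("CYP2C19", "CYP2D6")
MODES = ("substrate", "inhibitor")


def role_stub() -> OntologyTerm:
    """Declared external stub parent for the role branch."""
    return _term("role", external=True)


def disposition_stub() -> OntologyTerm:
    """Declared external stub parent for the disposition branch."""
    return _term("disposition", external=True)


def build_excipient_taxonomy() -> List[OntologyTerm]:
    """The ``excipient role`` root and its seventeen subtypes.

    Each subtype is placed under the genus named by its definition; the
    root's parent is the external ``role`` stub.
    """
    return [role_stub()] + [
        _term(label, (parent,), definition)
        for label, parent, definition in _EXCIPIENT_ROLES
    ]


def build_active_ingredient_term() -> OntologyTerm:
    """The ``active ingredient role`` term (outside the excipient branch)."""
    return _term("active ingredient role", ("role",),
                 ACTIVE_INGREDIENT_DEFINITION)


def disposition_label(isoenzyme: str, mode: str) -> str:
    """Scaffold label of the CYP-specific disposition for a binding mode."""
    if isoenzyme not in ISOENZYMES:
        raise ValueError(f"unknown isoenzyme {isoenzyme!r}")
    if mode == "substrate":
        return f"{isoenzyme} active site binding disposition"
    if mode == "inhibitor":
        return f"function-inhibiting {isoenzyme} binding disposition"
    raise ValueError(f"unknown binding mode {mode!r}")


def build_binding_terms() -> List[OntologyTerm]:
    """GO stubs plus the enzyme-binding disposition branch.

    Returns the imported ``binding`` -> ``protein binding`` -> ``enzyme
    binding`` chain, the two new disposition classes, and the four
    CYP-specific subclasses (2 isoenzymes x {substrate, inhibitor}).
    """
    terms = [
        disposition_stub(),
        _term("binding", (), external=True),
        _term("protein binding", ("binding",), external=True),
        _term("enzyme binding", ("protein binding",),
              ENZYME_BINDING_DEFINITION, external=True),
        _term("enzyme active site binding disposition", ("disposition",),
              ACTIVE_SITE_DEFINITION),
        _term("function-inhibiting enzyme-binding disposition",
              ("disposition",), FUNCTION_INHIBITING_DEFINITION),
    ]
    for iso in ISOENZYMES:
        terms.append(_term(disposition_label(iso, "substrate"),
                           ("enzyme active site binding disposition",)))
        terms.append(_term(disposition_label(iso, "inhibitor"),
                           ("function-inhibiting enzyme-binding disposition",)))
    return terms


def build_scaffold() -> List[OntologyTerm]:
    """The full scaffold: excipient branch, active ingredient role,
    binding branch.  Labels are unique; stub duplicates are collapsed."""
    seen: dict = {}
    for term in (build_excipient_taxonomy()
                 + [build_active_ingredient_term()]
                 + build_binding_terms()):
        if term.label in seen and seen[term.label] != term:
            raise ValueError(f"conflicting scaffold terms for {term.label!r}")
        seen[term.label] = term
    return list(seen.values())


def _children_map(terms: Iterable[OntologyTerm]) -> dict:
    by_iri = {t.iri: t for t in terms}
    children: dict = {iri: [] for iri in by_iri}
    for t in terms:
        for p in t.parent_iris:
            if p in children:
                children[p].append(t.iri)
    return children


def count_strict_descendants(terms: Iterable[OntologyTerm],
                             root_label: str) -> int:
    """Number of terms strictly below ``root_label`` in the is-a closure."""
    terms = list(terms)
    labels = {t.label: t for t in terms}
    if root_label not in labels:
        raise KeyError(f"unknown root label {root_label!r}")
    children = _children_map(terms)
    seen: set = set()
    stack = [labels[root_label].iri]
    while stack:
        for child in children[stack.pop()]:
            if child not in seen:
                seen.add(child)
                stack.append(child)
    return len(seen)


def check_acyclic(terms: Iterable[OntologyTerm]) -> None:
    """Raise ValueError if the is-a graph has a cycle (it never should)."""
    terms = list(terms)
    state: dict = {}  # 0 visiting, 1 done
    parents = {t.iri: [p for p in t.parent_iris] for t in terms}

    def visit(iri: str) -> None:
        if state.get(iri) == 1:
            return
        if state.get(iri) == 0:
            raise ValueError(f"cycle through {iri}")
        state[iri] = 0
        for p in parents.get(iri, ()):
            visit(p)
        state[iri] = 1

    for t in terms:
        visit(t.iri)


def scaffold_tsv(terms: Iterable[OntologyTerm]) -> str:
    """Dump the scaffold as TSV (iri, label, parents, definition)."""
    lines = ["iri\tlabel\tparents\tdefinition"]
    for t in sorted(terms, key=lambda t: t.iri):
        lines.append("\t".join(
            [t.iri, t.label, ";".join(t.parent_iris), t.definition]))
    return "\n".join(lines) + "\n"
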