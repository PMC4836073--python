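"""Class-expression AST, axiom patterns, and a deterministic OWL
serializer/parser.

Drug-product classes are axiomatized with three patterns:

* active ingredient (optionally with strength)::

      product SubClassOf has_proper_part some
          ('scattered molecular aggregate'
           and (has_granular_part some <ingredient>)
           and (bearer_of some 'active ingredient role')
           and (bearer_of some (mass
                and (has_specified_value "325")
                and (has_measurement_unit value milligram))))

* excipient: the same aggregate shape with an excipient role in place
  of the active ingredient role and no mass conjunct;

* CYP binding: ``<molecule> SubClassOf bearer_of some <disposition>``.

Strength axioms attach at the clinical-drug (SCD) level and are
inherited by the branded drugs (SBDs) below; excipient axioms attach at
the branded-drug level, because each brand typically has its own set of
excipients.

The document format is OWL 2 functional-style syntax with full IRIs and
lexicographically sorted axioms, so the same axiom set always produces
byte-identical output regardless of insertion order; ``parse`` is the
exact inverse of ``serialize``.  An RDF/XML export (via rdflib) is
provided as a convenience wrapper.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, List, Optional, Set, Tuple, Union

from . import role_taxonomy as tax
from .cyp_dispositions import CypRecord
from .excipient_extraction import ExcipientLink
from .rrf_io import AtomRecord, RelationshipRecord, index_atoms
from .strength_extraction import StrengthRecord

NAMESPACE = tax.NAMESPACE
ONTOLOGY_IRI = NAMESPACE + "ontology"

RDFS_LABEL = "http://www.w3.org/2000/01/rdf-schema#label"
DEFINITION_IRI = NAMESPACE + "definition"
RXCUI_IRI = NAMESPACE + "RxCUI"

# ---------------------------------------------------------------------------
# Vocabulary: classes, properties and unit individuals minted in the
# artifact namespace (labels match common OBO usage; no live import).

_VOCAB_IDS = {
    "scattered molecular aggregate": 100,
    "mass": 101,
    "has_proper_part": 110,
    "has_granular_part": 111,
    "bearer_of": 112,
    "has_measurement_unit": 113,
    "has_specified_value": 114,
    "milligram": 120,
    "microgram": 121,
    "gram": 122,
    "unit": 123,
    "milliequivalent": 124,
}


def vocab_iri(label: str) -> str:
    return f"{NAMESPACE}RXOWL_{_VOCAB_IDS[label]:07d}"


SMA = vocab_iri("scattered molecular aggregate")
MASS = vocab_iri("mass")
HAS_PROPER_PART = vocab_iri("has_proper_part")
HAS_GRANULAR_PART = vocab_iri("has_granular_part")
BEARER_OF = vocab_iri("bearer_of")
HAS_MEASUREMENT_UNIT = vocab_iri("has_measurement_unit")
HAS_SPECIFIED_VALUE = vocab_iri("has_specified_value")

#: unit symbol (as in strength strings) -> unit individual label
UNIT_INDIVIDUALS = {
    "MG": "milligram",
    "MCG": "microgram",
    "G": "gram",
    "UNT": "unit",
    "MEQ": "milliequivalent",
}


def unit_iri(symbol: str) -> str:
    return vocab_iri(UNIT_INDIVIDUALS[symbol])


def concept_iri(rxcui: str) -> str:
    """Class IRI for an RxNorm concept (drug product or ingredient)."""
    return f"{NAMESPACE}RXCUI_{rxcui}"


# ---------------------------------------------------------------------------
# Class-expression AST

@dataclass(frozen=True)
class Named:
    iri: str


@dataclass(frozen=True)
class And:
    operands: Tuple["ClassExpression", ...]

    def __post_init__(self):
        if len(self.operands) < 2:
            raise ValueError("And needs at least 2 operands")


@dataclass(frozen=True)
class Some:
    prop: str
    filler: "ClassExpression"


@dataclass(frozen=True)
class HasValue:
    prop: str
    individual: str


@dataclass(frozen=True)
class DataHasValue:
    prop: str
    literal: str


ClassExpression = Union[Named, And, Some, HasValue, DataHasValue]

DECL_KINDS = ("Class", "ObjectProperty", "DataProperty", "NamedIndividual",
              "AnnotationProperty")


class AxiomSet:
    """Declarations, subclass axioms and annotations, with set semantics.

    Every IRI referenced in an expression is declared as it is added, so
    the declaration-closure invariant holds by construction.
    """

    def __init__(self):
        self.declarations: Dict[str, str] = {}  # iri -> kind
        self.subclass_axioms: Set[Tuple[str, ClassExpression]] = set()
        #: (annotation property iri, subject iri, literal value)
        self.annotations: Set[Tuple[str, str, str]] = set()

    def __eq__(self, other):
        return (isinstance(other, AxiomSet)
                and self.declarations == other.declarations
                and self.subclass_axioms == other.subclass_axioms
                and self.annotations == other.annotations)

    def __len__(self):
        return (len(self.declarations) + len(self.subclass_axioms)
                + len(self.annotations))

    def declare(self, iri: str, kind: str) -> None:
        if kind not in DECL_KINDS:
            raise ValueError(f"unknown declaration kind {kind!r}")
        prev = self.declarations.get(iri)
        if prev is not None and prev != kind:
            raise ValueError(
                f"{iri} already declared as {prev}, cannot redeclare "
                f"as {kind}")
        self.declarations[iri] = kind

    def _declare_expression(self, expr: ClassExpression) -> None:
        if isinstance(expr, Named):
            self.declare(expr.iri, "Class")
        elif isinstance(expr, And):
            for op in expr.operands:
                self._declare_expression(op)
        elif isinstance(expr, Some):
            self.declare(expr.prop, "ObjectProperty")
            self._declare_expression(expr.filler)
        elif isinstance(expr, HasValue):
            self.declare(expr.prop, "ObjectProperty")
            self.declare(expr.individual, "NamedIndividual")
        elif isinstance(expr, DataHasValue):
            self.declare(expr.prop, "DataProperty")
        else:
            raise TypeError(f"not a class expression: {expr!r}")

    def add_subclass(self, subject_iri: str, superclass: ClassExpression
                     ) -> None:
        self.declare(subject_iri, "Class")
        self._declare_expression(superclass)
        self.subclass_axioms.add((subject_iri, superclass))

    def annotate(self, subject_iri: str, prop_iri: str, value: str) -> None:
        self.declare(prop_iri, "AnnotationProperty")
        self.annotations.add((prop_iri, subject_iri, value))


# ---------------------------------------------------------------------------
# Axiom patterns

def _taxonomy_branch(taxonomy: Iterable[tax.OntologyTerm], root_label: str
                     ) -> Set[str]:
    """IRIs of root_label and everything below it in the scaffold."""
    terms = list(taxonomy)
    labels = {t.label: t for t in terms}
    root = labels[root_label].iri
    children: Dict[str, List[str]] = {}
    for t in terms:
        for p in t.parent_iris:
            children.setdefault(p, []).append(t.iri)
    branch = {root}
    stack = [root]
    while stack:
        for c in children.get(stack.pop(), ()):
            if c not in branch:
                branch.add(c)
                stack.append(c)
    return branch


def emit_active_ingredient_expression(
    ingredient_iri: str,
    strength: Optional[Tuple[float, str]] = None,
) -> ClassExpression:
    """The active-ingredient aggregate pattern, with an optional mass
    value-specification conjunct.

    ``strength`` is ``(value, unit_individual_iri)``; the value is
    rendered as a plain literal (325 -> ``"325"``).
    """
    conjuncts: List[ClassExpression] = [
        Named(SMA),
        Some(HAS_GRANULAR_PART, Named(ingredient_iri)),
        Some(BEARER_OF, Named(tax.iri_for("active ingredient role"))),
    ]
    if strength is not None:
        value, u_iri = strength
        if value <= 0:
            raise ValueError("strength value must be positive")
        literal = f"{value:g}"
        conjuncts.append(
            Some(BEARER_OF, And((
                Named(MASS),
                DataHasValue(HAS_SPECIFIED_VALUE, literal),
                HasValue(HAS_MEASUREMENT_UNIT, u_iri),
            ))))
    return Some(HAS_PROPER_PART, And(tuple(conjuncts)))


def emit_excipient_expression(
    excipient_iri: str,
    role_iri: str,
    taxonomy: Optional[Iterable[tax.OntologyTerm]] = None,
) -> ClassExpression:
    """The excipient aggregate pattern; the role must sit in the
    excipient branch of the scaffold."""
    terms = list(taxonomy) if taxonomy is not None else tax.build_scaffold()
    if role_iri not in _taxonomy_branch(terms, "excipient role"):
        raise ValueError(
            f"role {role_iri} is not in the excipient role branch")
    return Some(HAS_PROPER_PART, And((
        Named(SMA),
        Some(HAS_GRANULAR_PART, Named(excipient_iri)),
        Some(BEARER_OF, Named(role_iri)),
    )))


def emit_cyp_axiom(
    molecule_iri: str,
    disposition_iri: str,
    taxonomy: Optional[Iterable[tax.OntologyTerm]] = None,
) -> Tuple[str, ClassExpression]:
    """``molecule SubClassOf bearer_of some disposition``; the
    disposition must be a known enzyme-binding disposition."""
    terms = list(taxonomy) if taxonomy is not None else tax.build_scaffold()
    branch = (_taxonomy_branch(terms, "enzyme active site binding disposition")
              | _taxonomy_branch(
                  terms, "function-inhibiting enzyme-binding disposition"))
    if disposition_iri not in branch:
        raise ValueError(
            f"{disposition_iri} is not an enzyme-binding disposition")
    return (molecule_iri, Some(BEARER_OF, Named(disposition_iri)))


# ---------------------------------------------------------------------------
# Assembly

@dataclass
class AssembleReport:
    n_strength_axioms: int = 0
    n_excipient_axioms: int = 0
    n_cyp_axioms: int = 0
    n_sbd_scd_edges: int = 0
    skipped: List[str] = dc_field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "strength_axioms": self.n_strength_axioms,
            "excipient_axioms": self.n_excipient_axioms,
            "cyp_axioms": self.n_cyp_axioms,
            "sbd_scd_edges": self.n_sbd_scd_edges,
            "skipped": list(self.skipped),
        }


def _preferred_label(atom_list: List[AtomRecord]) -> str:
    order = {"IN": 0, "SCD": 1, "SBD": 2, "SCDC": 3, "DF": 4}
    return sorted(atom_list,
                  key=lambda a: (order.get(a.tty, 9), a.rxaui))[0].name


def add_scaffold(axioms: AxiomSet,
                 taxonomy: Iterable[tax.OntologyTerm]) -> None:
    for term in taxonomy:
        axioms.declare(term.iri, "Class")
        axioms.annotate(term.iri, RDFS_LABEL, term.label)
        if term.definition:
            axioms.annotate(term.iri, DEFINITION_IRI, term.definition)
        for parent in term.parent_iris:
            axioms.add_subclass(term.iri, Named(parent))


def assemble_ontology(
    taxonomy: Iterable[tax.OntologyTerm],
    excipient_links: Iterable[ExcipientLink],
    strength_records: Iterable[StrengthRecord],
    cyp_records: Iterable[CypRecord],
    atoms: Iterable[AtomRecord],
    relationships: Iterable[RelationshipRecord] = (),
    *,
    excipient_role_map: Optional[Dict[str, str]] = None,
    report: Optional[AssembleReport] = None,
) -> AxiomSet:
    """Wire extracted facts into one axiom set.

    Strength (active-ingredient) expressions attach to SCD-level
    classes; excipient expressions attach to SBD-level classes; each SBD
    becomes a subclass of its SCD when a tradename relationship links
    them, so SBDs inherit strengths through the hierarchy.  Every
    concept class is annotated with its RxCUI and display name.  Links
    whose concepts have no atoms are reported and skipped.

    ``excipient_role_map`` optionally refines the role of individual
    excipients (excipient rxcui -> role label); everything else gets the
    generic ``excipient role``, since SPL data does not say which
    subtype an inactive ingredient plays.
    """
    taxonomy = list(taxonomy)
    atoms = list(atoms)
    rep = report if report is not None else AssembleReport()
    axioms = AxiomSet()
    add_scaffold(axioms, taxonomy)

    by_rxcui = index_atoms(atoms, sab_filter="RXNORM")
    tax_by_label = {t.label: t for t in taxonomy}

    def declare_concept(rxcui: str) -> Optional[str]:
        if rxcui not in by_rxcui:
            return None
        iri = concept_iri(rxcui)
        if iri not in axioms.declarations:
            axioms.declare(iri, "Class")
            axioms.annotate(iri, RXCUI_IRI, rxcui)
            axioms.annotate(iri, RDFS_LABEL,
                            _preferred_label(by_rxcui[rxcui]))
        return iri

    for record in strength_records:
        scd = declare_concept(record.scd_rxcui)
        ing = declare_concept(record.ingredient_rxcui)
        if scd is None or ing is None:
            rep.skipped.append(
                f"strength {record.scd_rxcui}->{record.ingredient_rxcui}: "
                "unknown concept")
            continue
        axioms.add_subclass(scd, emit_active_ingredient_expression(
            ing, (record.value, unit_iri(record.unit))))
        rep.n_strength_axioms += 1

    for link in excipient_links:
        sbd = declare_concept(link.product_rxcui)
        exc = declare_concept(link.excipient_rxcui)
        if sbd is None or exc is None:
            rep.skipped.append(
                f"excipient {link.product_rxcui}->{link.excipient_rxcui}: "
                "unknown concept")
            continue
        role_label = (excipient_role_map or {}).get(
            link.excipient_rxcui, "excipient role")
        role = tax_by_label[role_label].iri
        axioms.add_subclass(
            sbd, emit_excipient_expression(exc, role, taxonomy))
        rep.n_excipient_axioms += 1

    # SBD SubClassOf SCD via tradename correspondence.
    sbd_index = index_atoms(atoms, sab_filter="RXNORM", tty_filter="SBD")
    scd_index = index_atoms(atoms, sab_filter="RXNORM", tty_filter="SCD")
    for rel in relationships:
        if rel.rela not in ("has_tradename", "tradename_of"):
            continue
        a, b = rel.rxcui1, rel.rxcui2
        if a in sbd_index and b in scd_index:
            sbd_cui, scd_cui = a, b
        elif b in sbd_index and a in scd_index:
            sbd_cui, scd_cui = b, a
        else:
            continue
        sbd = declare_concept(sbd_cui)
        scd = declare_concept(scd_cui)
        edge = (sbd, Named(scd))
        if edge not in axioms.subclass_axioms:
            axioms.add_subclass(sbd, Named(scd))
            rep.n_sbd_scd_edges += 1

    for rec in cyp_records:
        if not rec.resolved_rxcui:
            rep.skipped.append(f"cyp {rec.molecule_name}: unresolved")
            continue
        mol = declare_concept(rec.resolved_rxcui)
        if mol is None:
            rep.skipped.append(f"cyp {rec.molecule_name}: unknown concept")
            continue
        label = tax.disposition_label(rec.isoenzyme, rec.mode)
        subject, expr = emit_cyp_axiom(mol, tax_by_label[label].iri,
                                       taxonomy)
        axioms.add_subclass(subject, expr)
        rep.n_cyp_axioms += 1

    return axioms


# ---------------------------------------------------------------------------
# Functional-style serialization (deterministic) and parsing

def _escape(value: str) -> str:
    return value.replace("\\", "\\\\").replace('"', '\\"')


def _unescape(value: str) -> str:
    return re.sub(r"\\(.)", r"\1", value, flags=re.DOTALL)


def render_expression(expr: ClassExpression) -> str:
    if isinstance(expr, Named):
        return f"<{expr.iri}>"
    if isinstance(expr, And):
        inner = " ".join(render_expression(op) for op in expr.operands)
        return f"ObjectIntersectionOf({inner})"
    if isinstance(expr, Some):
        return (f"ObjectSomeValuesFrom(<{expr.prop}> "
                f"{render_expression(expr.filler)})")
    if isinstance(expr, HasValue):
        return f"ObjectHasValue(<{expr.prop}> <{expr.individual}>)"
    if isinstance(expr, DataHasValue):
        return f'DataHasValue(<{expr.prop}> "{_escape(expr.literal)}")'
    raise TypeError(f"not a class expression: {expr!r}")


def serialize(axioms: AxiomSet) -> str:
    """Render an axiom set as a functional-style document with axioms
    sorted lexicographically: equal sets give byte-identical text."""
    lines: List[str] = []
    for iri, kind in axioms.declarations.items():
        lines.append(f"Declaration({kind}(<{iri}>))")
    for subject, expr in axioms.subclass_axioms:
        lines.append(f"SubClassOf(<{subject}> {render_expression(expr)})")
    for prop, subject, value in axioms.annotations:
        lines.append(
            f'AnnotationAssertion(<{prop}> <{subject}> "{_escape(value)}")')
    lines.sort()
    body = "".join(line + "\n" for line in lines)
    return (f"Prefix(owl:=<http://www.w3.org/2002/07/owl#>)\n"
            f"Ontology(<{ONTOLOGY_IRI}>\n{body})\n")


class OWLParseError(ValueError):
    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


_TOKEN_RE = re.compile(
    r"""
    (?P<iri><[^<>\s]*>)
  | (?P<string>"(?:[^"\\]|\\.)*")
  | (?P<name>[A-Za-z][A-Za-z0-9_]*:?=?)
  | (?P<lpar>\()
  | (?P<rpar>\))
  | (?P<ws>\s+)
    """,
    re.VERBOSE,
)


def _tokenize(text: str):
    tokens = []  # (kind, value, lineno)
    lineno = 1
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise OWLParseError(lineno,
                                f"unexpected character {text[pos]!r}")
        kind = m.lastgroup
        value = m.group()
        if kind != "ws":
            tokens.append((kind, value, lineno))
        lineno += value.count("\n")
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens):
        self.tokens = tokens
        self.i = 0

    @property
    def _lineno(self):
        if self.i < len(self.tokens):
            return self.tokens[self.i][2]
        return self.tokens[-1][2] if self.tokens else 1

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self, kind=None, value=None):
        tok = self.peek()
        if tok is None:
            raise OWLParseError(self._lineno, "unexpected end of document")
        if kind and tok[0] != kind:
            raise OWLParseError(tok[2],
                                f"expected {kind}, found {tok[1]!r}")
        if value and tok[1] != value:
            raise OWLParseError(tok[2],
                                f"expected {value!r}, found {tok[1]!r}")
        self.i += 1
        return tok

    def iri(self) -> str:
        return self.next("iri")[1][1:-1]

    def string(self) -> str:
        return _unescape(self.next("string")[1][1:-1])

    def expression(self) -> ClassExpression:
        tok = self.peek()
        if tok is None:
            raise OWLParseError(self._lineno, "expected class expression")
        if tok[0] == "iri":
            return Named(self.iri())
        name = self.next("name")[1]
        self.next("lpar")
        if name == "ObjectIntersectionOf":
            operands = []
            while self.peek() and self.peek()[0] != "rpar":
                operands.append(self.expression())
            self.next("rpar")
            if len(operands) < 2:
                raise OWLParseError(
                    tok[2], "ObjectIntersectionOf needs >= 2 operands")
            return And(tuple(operands))
        if name == "ObjectSomeValuesFrom":
            prop = self.iri()
            filler = self.expression()
            self.next("rpar")
            return Some(prop, filler)
        if name == "ObjectHasValue":
            prop = self.iri()
            individual = self.iri()
            self.next("rpar")
            return HasValue(prop, individual)
        if name == "DataHasValue":
            prop = self.iri()
            literal = self.string()
            self.next("rpar")
            return DataHasValue(prop, literal)
        raise OWLParseError(tok[2], f"unknown expression kind {name!r}")

    def axiom(self, axioms: AxiomSet) -> None:
        tok = self.next("name")
        name = tok[1]
        self.next("lpar")
        if name == "Declaration":
            kind = self.next("name")[1]
            if kind not in DECL_KINDS:
                raise OWLParseError(tok[2],
                                    f"unknown declaration kind {kind!r}")
            self.next("lpar")
            iri = self.iri()
            self.next("rpar")
            self.next("rpar")
            axioms.declarations[iri] = kind
        elif name == "SubClassOf":
            subject = self.iri()
            expr = self.expression()
            self.next("rpar")
            axioms.subclass_axioms.add((subject, expr))
        elif name == "AnnotationAssertion":
            prop = self.iri()
            subject = self.iri()
            value = self.string()
            self.next("rpar")
            axioms.annotations.add((prop, subject, value))
        else:
            raise OWLParseError(tok[2], f"unknown axiom kind {name!r}")


def parse(text: str) -> AxiomSet:
    """Parse a functional-style document back into an AxiomSet.

    ``parse(serialize(a)) == a`` for every axiom set this package
    produces; malformed documents raise :class:`OWLParseError` with the
    offending line number.
    """
    parser = _Parser(_tokenize(text))
    # prefix declarations are accepted and ignored (full IRIs are used)
    while True:
        tok = parser.peek()
        if tok is None:
            raise OWLParseError(1, "missing Ontology(...) block")
        if tok[0] == "name" and tok[1] == "Prefix":
            parser.next("name")
            parser.next("lpar")
            parser.next("name")  # e.g. owl:=
            parser.iri()
            parser.next("rpar")
        else:
            break
    parser.next("name", "Ontology")
    parser.next("lpar")
    parser.iri()
    axioms = AxiomSet()
    while parser.peek() and parser.peek()[0] != "rpar":
        parser.axiom(axioms)
    parser.next("rpar")
    if parser.peek() is not None:
        raise OWLParseError(parser.peek()[2],
                            "trailing content after ontology block")
    return axioms


# ---------------------------------------------------------------------------
# RDF/XML convenience export (rdflib-backed)

def to_rdflib_graph(axioms: AxiomSet):
    from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, URIRef
    from rdflib.collection import Collection

    OWL = Namespace("http://www.w3.org/2002/07/owl#")
    g = Graph()
    g.bind("owl", OWL)
    g.add((URIRef(ONTOLOGY_IRI), RDF.type, OWL.Ontology))
    kind_map = {
        "Class": OWL.Class,
        "ObjectProperty": OWL.ObjectProperty,
        "DataProperty": OWL.DatatypeProperty,
        "NamedIndividual": OWL.NamedIndividual,
        "AnnotationProperty": OWL.AnnotationProperty,
    }
    for iri, kind in axioms.declarations.items():
        g.add((URIRef(iri), RDF.type, kind_map[kind]))

    def node(expr: ClassExpression):
        if isinstance(expr, Named):
            return URIRef(expr.iri)
        b = BNode()
        if isinstance(expr, And):
            g.add((b, RDF.type, OWL.Class))
            lst = BNode()
            Collection(g, lst, [node(op) for op in expr.operands])
            g.add((b, OWL.intersectionOf, lst))
        elif isinstance(expr, Some):
            g.add((b, RDF.type, OWL.Restriction))
            g.add((b, OWL.onProperty, URIRef(expr.prop)))
            g.add((b, OWL.someValuesFrom, node(expr.filler)))
        elif isinstance(expr, HasValue):
            g.add((b, RDF.type, OWL.Restriction))
            g.add((b, OWL.onProperty, URIRef(expr.prop)))
            g.add((b, OWL.hasValue, URIRef(expr.individual)))
        elif isinstance(expr, DataHasValue):
            g.add((b, RDF.type, OWL.Restriction))
            g.add((b, OWL.onProperty, URIRef(expr.prop)))
            g.add((b, OWL.hasValue, Literal(expr.literal)))
        return b

    for subject, expr in axioms.subclass_axioms:
        g.add((URIRef(subject), RDFS.subClassOf, node(expr)))
    for prop, subject, value in axioms.annotations:
        g.add((URIRef(subject), URIRef(prop), Literal(value)))
    return g


def serialize_rdfxml(axioms: AxiomSet) -> str:
    return to_rdflib_graph(axioms).serialize(format="xml")
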