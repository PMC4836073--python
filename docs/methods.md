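# Methods

## Scope and data model

`rxowl` turns three RxNorm-format RRF tables into an OWL ontology of
drug products. The tables are read positionally (RXNCONSO 18 fields,
RXNREL 16, RXNSAT 13, trailing pipe, no header, UTF-8); the column maps
are configurable because other dialects of the format exist. Rows whose
suppression flag is `Y` or `O` are dropped by default (a flag retains
them). Two error modes exist: *strict* aborts on the first malformed
line with its line number; *lenient* (the default) skips malformed
lines, logs them, and collects them on a report, so one bad row in a
multi-million-line release never kills a build.

Relationship rows follow the RxNorm convention that `RELA` names the
relationship of the second-column entity to the first (entity2 RELA
entity1). A `ColumnMap.invert_rel_direction` flag flips this for
sources with the opposite convention; the synthetic generator, the
extraction joins and the test oracles all share whichever convention is
configured. Both the concept and atom identifier columns are consulted
when resolving a relationship side: SPL-derived rows are matched at the
atom level and mapped to concepts through the atom table.

## Excipient extraction

Excipient facts exist only under source `MTHSPL` as
`has_inactive_ingredient` rows. Extraction resolves both sides of each
row to concept identifiers, keeps the product side only if its concept
has a `RXNORM`/`SBD` atom, requires the ingredient side to resolve to a
`RXNORM`/`IN` atom, and collapses duplicates (the same product–excipient
pair repeated across SPLs yields one link; a report counts raw rows).

Products whose only normalized atom is an SCD are excluded and counted.
Rationale: many label-only products with no branded-drug concept of
their own are mapped to a single clinical-drug concept, which
consequently accumulates the union of all their excipients; asserting
those links would attribute one brand's excipients to every brand. A
concept carrying *both* SBD and SCD atoms is kept — the exclusion only
bites for SCD-only concepts.

Extracted excipients are assigned the generic `excipient role`: SPL
data does not state which subtype role (binder, coating, …) an inactive
ingredient plays in a given product. An optional curated
excipient→role-label map can refine individual assignments.

Coverage is reported as linked-SBDs / total-SBDs rounded to three
decimals (5,743 of 21,191 → 0.271).

## Strength extraction

Strengths are extracted only for *discrete solid dose forms* (default
token set {tablet, capsule, caplet}, matched case-insensitively as
whole words, configurable), because for those the strength string is
the total mass per dosing unit. Other forms carry concentrations
(mass per mL/g of product), which cannot be converted to a total mass
without package quantities; they are detected and skipped, never
guessed. The dose form of a clinical drug is taken from its
`has_dose_form` relationship to a `DF` atom when present, else from the
trailing dose-form phrase of its name (the text after the last strength
token).

For each qualifying SCD the walk is `consists_of` → SCDC →
`has_ingredient` → IN, reading the SCDC's `RXN_STRENGTH` attribute.
The strength grammar is `NUMBER WHITESPACE UNIT`: any string containing
`/` is rejected as a concentration, unit symbols outside the packaged
table {MG, MCG, G, UNT, MEQ} are rejected with a reason, decimal values
use `.` only and thousands separators are rejected. An *empty*
attribute string is an error (data corruption), distinct from a
rejection (out-of-scope but well-formed data). One record is produced
per (SCD, ingredient); misses are counted on the report.

## The role/disposition scaffold

The scaffold is fixed and code-generated: an `excipient role` root with
17 subtype classes placed under the genus each textual definition
names — glidant, anti-adherent and anti-friction under lubricant;
protective and administration coatings under coating, with enteric
under protective and flavor/lubricant coatings under administration;
the remaining nine directly under the root. Single inheritance is used
throughout: `lubricant coating excipient role` sits only under
`administration coating excipient role`, as its definition's genus
states, despite its name — which also keeps the lubricant branch at
exactly its three enumerated subtypes. The strict-descendant counts
(excipient 17, coating 5, lubricant 3) are structural invariants of the
package, checked against an independent graph-library traversal in the
tests.

`active ingredient role` is a sibling concern, not an excipient
subtype: the same substance (calcium carbonate, say) can be active in
an antacid and inert elsewhere, so activeness is a role of the
aggregate in a particular product, realized only upon administration.

CYP binding is modeled as a *disposition* of the molecule — the
tendency to bind is internal to molecular structure, not conferred by
use. Two classes split it by what realization does: `enzyme active
site binding disposition` (the molecule is metabolized) and
`function-inhibiting enzyme-binding disposition` (the enzyme's active
site is blocked), each with CYP2C19- and CYP2D6-specific subclasses.
These two roots are deliberately *not* placed under the imported GO
`binding` chain: the GO terms are molecular-function classes and are
imported only as MIREOT-style stubs (IRI, label, definition) for
reference; the disposition classes get an external `disposition` stub
parent instead.

IRIs are minted from a fixed namespace plus a packaged label→number
table, so rebuilds are byte-stable and diffs meaningful.

## CYP table and resolution

Substrate/inhibitor assignments come from a curated CSV
(`molecule,isoenzyme,mode`) in the style of published P450 interaction
tables; the repository ships a small demonstration table (12
assignments over 8 molecules, including esomeprazole as the classic
both-modes CYP2C19 case) and accepts user tables in the same schema.
Isoenzymes and modes are closed vocabularies; rows outside them are
rejected per-row and reported. Molecules are resolved to ingredient
concepts by exact case-insensitive name equality against `RXNORM`/`IN`
atoms — no fuzzy matching, because a wrong match asserts a false
pharmacological claim; unresolved names are kept and reported for
curation.

## Ontology assembly and serialization

Assembly declares one class per referenced concept (annotated with its
RxCUI and preferred name), attaches active-ingredient/strength
expressions to SCD classes and excipient expressions to SBD classes,
adds `SBD SubClassOf SCD` edges wherever a tradename relationship links
the two (orientation decided by term type, so either relationship
direction is accepted), and one `bearer_of some disposition` axiom per
resolved CYP assignment. The aggregate + `has_granular_part` pattern
is used uniformly for both ingredient kinds. Links referencing unknown
concepts are reported and skipped, never fatal.

The document format is OWL 2 functional-style syntax with full IRIs and
lexicographically sorted axioms: the same axiom set serializes to
byte-identical text regardless of construction order, and the packaged
parser inverts serialization exactly (property-tested on random axiom
sets, including literals with quotes, backslashes and newlines). The
serializer/parser pair is implemented in the package because
byte-stable round-tripping is a core contract here; RDF/XML export is a
thin rdflib wrapper for interoperability.

## Queries

Queries are structural: pattern-matching over asserted axioms plus the
reflexive-transitive closure of asserted named subclass edges. No
description-logic reasoner runs — a documented limitation (hierarchies
that exist only by inference are invisible), acceptable because this
package asserts the SBD→SCD edges it relies on. Disposition queries
find molecules bearing the requested disposition, then products whose
active-ingredient conjunct grains them, then everything below those
products in the closure; excipient queries additionally require the
aggregate's borne role to lie in the excipient branch, so a substance
present only as an active ingredient never matches an excipient query.
DDI candidates for an isoenzyme are the ordered cross product of its
inhibitor products and substrate products minus self-pairs. Results are
IRI-sorted and carry evidence paths (the axioms traversed).

## Synthetic releases and what they show

The generator plants internally consistent IN/SCD/SBD/SCDC/DF atoms,
SPL product atoms, the relationship chains, strength attributes and
tradename edges, plus the two traps the method must survive: SCD-only
SPL products (whose excipient rows must be excluded) and non-solid dose
forms (whose concentration strengths must yield nothing). Expected
outputs are recorded in a manifest *while planting*, by construction —
never by running the pipeline — so manifest agreement is an independent
oracle. Identifiers are sequential from a seed-dependent offset in the
9-million range to avoid colliding with real low-numbered RxCUIs; names
are drawn from packaged word fragments so failures read well. Default
sizes (8 ingredients, 10 clinical drugs, 2 brands each, 3 excipients
per brand, 20 % SCD-only and 20 % non-solid fractions, half the
molecules CYP-assigned) give every code path traffic while keeping a
release under a hundred products; the acceptance script varies sizes up
to 25 clinical drugs across 20 seeded releases.

What passing these tests does **not** show: robustness to the full
messiness of real releases (suppressed-atom edge cases at scale,
source-specific term types beyond those emulated, name collisions
between ingredients), statistical realism of ingredient frequencies, or
the published full-release counts, which require the licensed data.
The pipeline's *logic* — joins, exclusions, filters, placement,
serialization, querying — is exactly what the fixtures exercise.

## Numerical and tie-break choices

Strength values are parsed as floats and rendered back with `%g` (so
`325` stays `325`, `0.25` stays `0.25`); validation requires strictly
positive values. Duplicate axioms are set-collapsed. Preferred class
labels pick the atom with the most specific useful term type
(IN < SCD < SBD < SCDC < DF) breaking ties by atom identifier. Display
coverage rounds to three decimals. Where a concept maps to several
same-name ingredient atoms, resolution groups by concept so the result
is a single RxCUI.
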