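# rxowl

Build an OWL drug ontology — excipients, active-ingredient strengths,
and cytochrome-P450 binding dispositions — from RxNorm-format release
files, and query it structurally.

## The problem

RxNorm distributes normalized drug nomenclature as pipe-delimited RRF
tables, but three clinically important kinds of knowledge are either
buried in them or absent:

1. **Excipients.** Inactive ingredients cause allergic reactions and
   modulate drug effects, yet RxNorm only carries them as
   `has_inactive_ingredient` rows harvested from FDA Structured Product
   Labels (source `MTHSPL`), disconnected from the normalized `RXNORM`
   concepts an ontology is built on.
2. **Strengths.** The mass of active ingredient per tablet/capsule/
   caplet lives on *semantic clinical drug components* (SCDCs), one hop
   away from the clinical drug, as `RXN_STRENGTH` attribute strings.
3. **CYP450 binding.** Whether a molecule is a substrate and/or
   inhibitor of an isoenzyme such as CYP2C19 or CYP2D6 — the raw
   material of drug–drug-interaction screening — is not in RxNorm at
   all and must come from curated pharmacology tables.

`rxowl` extracts all three, represents them with realist ontology
patterns, and answers questions like *"which drug products contain an
active ingredient whose molecules inhibit CYP2C19?"* directly from the
asserted axioms.

## The representation

An ingredient in a product is a *scattered molecular aggregate* (all
the molecules of one kind), and what makes it active or an excipient is
a **role** borne by that aggregate. A clinical drug with 325 mg of an
active ingredient is axiomatized as

    SubClassOf(drug,
      has_proper_part some ('scattered molecular aggregate'
        and (has_granular_part some ingredient)
        and (bearer_of some 'active ingredient role')
        and (bearer_of some (mass
          and (has_specified_value "325")
          and (has_measurement_unit value milligram)))))

Excipients use the same aggregate shape with one of 18 excipient-role
classes (a root `excipient role` plus 17 subtypes: lubricants with
glidant/anti-adherent/anti-friction subtypes, a five-member coating
branch, binding, color, flavor, disintegrant, preservative, sorbent and
vehicle roles). CYP binding is a **disposition** of the molecule
itself: `molecule SubClassOf bearer_of some
'function-inhibiting CYP2C19 binding disposition'`, with substrate
(active-site) and inhibitor disposition classes for each isoenzyme
under two new disposition roots, next to MIREOT-style stubs of the Gene
Ontology `binding` / `protein binding` / `enzyme binding` chain.

Strength axioms attach at the clinical-drug (SCD) level; branded drugs
(SBDs) are subclasses of their clinical drug and inherit them.
Excipient axioms attach at the branded-drug level, because each brand
has its own excipients — and products whose SPL data maps only to an
SCD are excluded, since those concepts accumulate the excipients of
many unrelated label-only products.

## Worked example

Real RxNorm releases are licensed, so the package ships a generator for
synthetic releases with a ground-truth manifest:

```sh
rxowl simulate --out demo --seed 7 --n-scds 6
rxowl build --rxnorm-dir demo --out demo/drug.ofn \
            --cyp-table demo/cyp_table.csv
```

The build report (stdout) includes:

```
"excipients":  {"rows": 36, "resolved": 36, "excluded_scd_only": 0, ...},
"excipient_links": 36,
"strengths":   {"scds_considered": 6, "scds_solid_form": 5,
                "strength_records": 6, ...},
"assembly":    {"strength_axioms": 6, "excipient_axioms": 36,
                "cyp_axioms": 5, "sbd_scd_edges": 12, ...}
```

— all 36 planted product–excipient rows resolved into links; 5 of the
6 clinical drugs are discrete solid forms and yielded 6 strength
records (one is a two-ingredient combination); 12 branded drugs were
placed under their clinical drugs. Querying the built ontology:

```sh
rxowl query --ontology demo/drug.ofn --cyp CYP2C19 --mode inhibitor
```

returns the two `gabaolol` clinical drugs **and** their four branded
products — the branded drugs match through the subclass closure even
though the disposition axiom is asserted once, on the molecule:

```
.../RXCUI_9700033 | gabaolol 325 MCG Oral Caplet
.../RXCUI_9700040 | gabaolol 200 MG Oral Tablet
.../RXCUI_9700046 | gabaolol 325 MCG Oral Caplet [Lumexa Lumexa]
...
```

`rxowl query --ddi --cyp CYP2C19` lists (inhibitor product, substrate
product) candidate pairs for interaction screening. The same
functionality is available as a library (`rxowl.extract_excipient_links`,
`rxowl.extract_strengths`, `rxowl.assemble_ontology`,
`rxowl.products_with_disposition`, …).

The ontology file is OWL 2 functional-style syntax with sorted axioms:
the same inputs always produce a byte-identical document, and
`rxowl.parse` inverts `rxowl.serialize` exactly. RDF/XML export is
available with `--format rdfxml`.

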