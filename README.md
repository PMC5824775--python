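# ontoqc

Find curation errors in term-annotated datasets using ontologies.

Manually curated databases in the life sciences often start with
"home-made" flat vocabularies — lists of assay names, cell types,
disease labels — that grow organically as curators meet new terms in
the literature. Lining those vocabularies up against formal ontologies
(OBO Foundry resources such as OBI, CL/CLO, DO, or the NCBI taxonomy)
exposes characteristic error classes, and `ontoqc` detects all of them
from a curated table plus the relevant ontology files:

| error class | what it is | detector |
|---|---|---|
| `redundant` | several legacy terms map to one ontology term (synonym drift, e.g. CCL4 vs MIP1b) | `detect_redundancy` |
| `imprecise` | one legacy term matches several ontology terms (ambiguous abbreviations, e.g. IL-1) | `detect_imprecision` |
| `rare-outlier` | a term used so rarely it is likely a typo or mis-pick | `flag_rare_terms` |
| `vague` | a non-leaf term used where more specific descendants exist | `flag_vague_usage` |
| `sibling-variant` | a rare term next to a dominant sibling (fragments grouping; advisory) | `flag_rare_sibling_variants` |
| `cross-field-violation` | a record contradicting an ontology axiom that links two fields | `validate` |

The toolkit also builds application-specific **pruned views** — the
ancestrally closed subgraph of an ontology covering exactly the terms a
dataset uses — and exports them as hierarchical "Finder" browse trees,
and it compiles **cross-field rules** from ontology logical definitions
(e.g. *dengue fever `has_material_basis_in` dengue virus*) into
executable record checks with auto-fill suggestions.

It is written for biocurators and data engineers auditing curated
tables, and works with OBO 1.2/1.4 flat files, NCBI-taxonomy-style
`nodes.dmp`/`names.dmp` dumps, and TSV/CSV tables.

## Worked example

```python
from ontoqc import load_obo, map_all, detect_redundancy, detect_imprecision, demo_bundle

paths = demo_bundle("demo")          # writes a small worked-example bundle
graph = load_obo(paths["cytokine"])
records = map_all({"CCL4", "MIP1b", "IL-1"}, graph)
for rec in records:
    print(rec.legacy_term, rec.status, [c.ontology_id for c in rec.candidates])
for cluster in detect_redundancy(records):
    print("redundant:", sorted(cluster.legacy_terms), "->", cluster.ontology_id)
for rec in detect_imprecision(records):
    print("imprecise:", rec.legacy_term, [c.ontology_id for c in rec.candidates])
```

prints

```
CCL4 unique ['OBI:0001378']
IL-1 ambiguous ['OBI:0001745', 'OBI:0001842']
MIP1b unique ['OBI:0001378']
redundant: ['CCL4', 'MIP1b'] -> OBI:0001378
imprecise: IL-1 ['OBI:0001745', 'OBI:0001842']
```

`CCL4` and `MIP1b` are era-specific synonyms of the same cytokine, so
both legacy assay names resolve to one assay term — a redundancy the
curator should merge. `IL-1` is too vague to map: it matches both the
IL-1α and the IL-1β assay, so the original publication must decide.

The `examples/` directory holds one short script per capability
(mapping, pruning, cross-field rules, the full audit). The same
functionality is available from a shell:

```bash
ontoqc fixtures demo --out-dir demo
ontoqc run --config demo/config.yaml --out-dir out --no-fail-on-error
```

which writes per-stage TSVs, a Finder tree JSON and a unified
`report.tsv` with one row per flag (field, subject, error class,
evidence, suggestion, severity, parameters hash).

## Synthetic fixtures with ground truth

`ontoqc.fixtures` generates toy ontologies (with redundancy and
imprecision bait synonyms and relationship axioms) and curated tables
with all six error classes injected at configurable rates, plus a
machine-readable ledger of exactly what was injected.
`evaluate_against_ledger` scores any pipeline run against that ledger
as per-class precision/recall — on a noiseless fixture every detector
recovers the ledger exactly.

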