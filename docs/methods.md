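# Methods

## Graph model and its deliberate restriction

`ontoqc` reasons over OBO-graph semantics only: terms with CURIEs,
labels, scoped synonyms, an acyclic `is_a` hierarchy with multiple
parents allowed, and named relationships between terms. No
description-logic reasoning is performed; what a reasoner would
contribute for these tasks is the transitive `is_a` closure, which the
package computes directly by breadth-first traversal. This keeps every
detection procedure exact, fast and testable. All algorithms are
defined on DAGs — cell- and assay-type ontologies routinely give a
term several parents — and never assume trees.

Obsolete terms are retained in the graph but never offered as mapping
candidates; a match that lands on an obsolete term follows
`replaced_by` exactly once and notes the event in the mapping record.
Dangling parent or relationship targets are recorded in graph metadata
by default (real ontology slices are frequently incomplete) and raise
only in strict mode.

## Term mapping

Matching is tiered and the tiers are never merged:

1. curated overrides (always win, marked `curated`);
2. exact string match against labels and synonyms of trusted scopes;
3. normalized match (case folding, Greek transliteration, `-_/` →
   space, punctuation stripped) only when tier 2 is empty;
4. fuzzy match (difflib ratio), strictly opt-in and reported with its
   score.

The default trusted synonym scope is EXACT plus primary labels.
Broader scopes (RELATED/BROAD/NARROW) are opt-in because they
manufacture false ambiguity: the informative collisions in cytokine
nomenclature come from genuine exact synonyms, not from loosely
related names. Ambiguous mappings are never auto-resolved — deciding
what an author meant by "IL-1" requires re-reading the publication,
which is curator work; the tool reports all candidates and defers.
Ties among several exact hits are likewise all reported.

Redundancy clusters group *uniquely* mapped legacy terms by target, so
redundancy and imprecision are disjoint evidence classes over one
mapping table by construction.

## Census and rare-term flags

The census is an exact multiset count per field; empty cells are a
completeness statistic, never terms. Multi-valued cells split on a
configurable delimiter (default `;`). Rare-term flagging is threshold
scrutiny, not an outlier model: a term is flagged when its count falls
below `min_count` (default 3) or its share below `min_fraction`
(default 0.001). Both defaults are package choices — "infrequent" is
inherently qualitative — and are echoed into every output header.
Usage is counted per record; counting per source reference instead
would need a reference-id column and is left to the caller's table
design.

## Pruning, vagueness and sibling variants

A pruned view keeps exactly the used terms plus all their `is_a`
ancestors (ancestral closure), with the induced edges; pruning is
idempotent and monotone in the usage set, and both properties are
asserted in tests against brute-force closure oracles.

Vague-usage flags are two-tier because the severity genuinely differs:
a used term whose descendants are themselves used (strong signal — the
dataset proves a finer term was applicable) versus a used term whose
descendants are merely available (weak signal, advisory). Sibling
variants — a rarely used term under the same parent as a dominant
sibling — are flagged as advisory with the highest-count sibling as
the comparator; the default ratio threshold is 0.01, a package choice
exposed in config. A rare sibling is not wrong, but harmonizing it
lets related records group together.

Finder trees list children lexicographically by label; a DAG node with
several kept parents appears under each of them, with repeat
appearances marked `repeat: true` and not re-expanded, keeping the
document linear in the view size while hiding no parentage. An
optional single-child-chain collapse pass exists for display only and
is never used in computation. Exports are validated against the
schema shipped at `src/ontoqc/finder_tree.schema.json` and serialized
canonically (sorted keys), so re-exports are byte-identical.

## Cross-field validation

`compile_rules` turns relationship axioms (default relation
`has_material_basis_in`; configurable, since relation labels vary
across ontology releases) into rules: if the trigger field holds the
trigger term or a descendant, the required field must hold the
required term or a descendant. Descendant-or-equal semantics is the
default because axioms are typically stated at species level while
records may carry strains or serotypes; equality-only mode is a config
switch. When several rules fire for one record the record passes if it
satisfies any of them (a disease may list several material bases), and
the disagreement is reported on a diagnostics channel. Empty trigger
fields never fire; empty required fields yield a `missing-value`
verdict plus an auto-fill suggestion — unless two rules would suggest
different terms, in which case no suggestion is emitted (auto-picking
would recreate the imprecision error class). Suggestions are advisory
and never applied to the input table; `apply_suggestions` exists for
what-if analysis and the closure property (fill everything suggested,
re-validate, no missing-value verdicts remain and no new violations
appear) is tested.

## Synthetic data generator

The generator emulates a curated corpus annotated against one or more
ontologies. Background usage follows a Zipf profile with exponent 1.0
over ontology leaves — curated datasets are heavily skewed toward a
few workhorse terms — allocated deterministically (largest-remainder
rounding) with a floor count so that no background term trips the
default rare/sibling thresholds. Background records use leaves only,
and background siblings receive adjacent Zipf ranks, so their count
ratios stay far above the sibling threshold. Errors of the six classes
are injected into disjoint records: singleton typo strings
(rare-outlier), both EXACT synonyms of a bait term (redundant, at
least `floor` records per synonym so the census never confounds the
classes), ambiguous synonym strings (imprecise), usage of depth-1
internal nodes (vague; their used siblings are other baits with
comparable counts), one rare leaf next to a deliberately dominant
sibling (sibling-variant), and records contradicting a relationship
axiom (cross-field), accompanied by clean trigger records and
empty-required records as autofill bait. Default rates are 0.3–1.2%
per class, in the range a mature curated corpus plausibly accumulates.

What the fixtures do **not** emulate: free-text noise beyond injected
typos, multi-label cells, curator drift over time, inter-ontology
bridging, or incomplete ontology coverage of the domain. Perfect
recovery on these fixtures therefore demonstrates correctness of the
detection logic under clean conditions, not expected precision on a
real corpus, where thresholds will trade precision against recall.

## Numerical and engineering choices

Deterministic ordering everywhere: mappings lexicographic by legacy
term, clusters by size then id, flags by count then term, reports in
stage order; all serializations sort keys. Re-running any stage on
identical inputs is byte-identical, which the acceptance script
verifies. All randomness in the generator flows from a single seed
through `random.Random`. Problem sizes used by the tests and the
acceptance script — fixtures of 400–1000 records over ontologies of
60–120 terms, 100 random DAGs of up to 200 nodes for the traversal
oracles — keep every property exhaustively checkable by brute force
while exercising all code paths.

## Known limitations

- No OWL/DL reasoning: equivalence axioms and logical definitions
  beyond binary term-to-term relationships are out of scope.
- Cross-ontology bridging (e.g. cell-type vs cell-line vocabularies)
  is not inferred; mappings cross graphs only where the input graphs
  state the links.
- Rule checking is binary trigger→required; cardinality or negation
  constraints are not expressible.
- The rare-term and sibling thresholds are deliberately simple; they
  rank candidates for human review and must not be read as error
  probabilities.
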