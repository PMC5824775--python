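"""Map a legacy assay vocabulary and surface redundancy/imprecision.

Builds the cytokine worked-example ontology, maps three legacy assay
names against it, and prints the two classic mapping error classes.
"""

import tempfile
from pathlib import Path

from ontoqc import (detect_imprecision, detect_redundancy, load_obo,
                    map_all, demo_bundle)

with tempfile.TemporaryDirectory() as tmp:
    paths = demo_bundle(tmp)
    graph = load_obo(paths["cytokine"])

    legacy = {"CCL4", "MIP1b", "IL-1"}
    records = map_all(legacy, graph)
    for rec in records:
        ids = ", ".join(c.ontology_id for c in rec.candidates) or "-"
        print(f"{rec.legacy_term:8s} {rec.status:10s} {ids}")

    for cluster in detect_redundancy(records):
        print(f"redundant: {sorted(cluster.legacy_terms)} all denote "
              f"{cluster.ontology_id} ({graph[cluster.ontology_id].label})")
    for rec in detect_imprecision(records):
        print(f"imprecise: {rec.legacy_term!r} could mean any of "
              f"{[c.ontology_id for c in rec.candidates]}")

# CCL4 and MIP1b are era-specific synonyms of one cytokine, so both
# legacy assay names map to the same assay term (a redundancy to merge);
# "IL-1" is an abbreviation matching both the IL-1 alpha and IL-1 beta
# assays, so a curator must re-read the source publication to resolve it.
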