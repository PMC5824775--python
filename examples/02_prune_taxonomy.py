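"""Prune a taxonomy to the used taxa and flag questionable usage.

Loads a small NCBI-style dump, prunes it to what a dataset actually
uses, and prints the vague-parent and rare-sibling advisories.
"""

import tempfile

from ontoqc import (flag_rare_sibling_variants, flag_vague_usage,
                    load_ncbi_dump, demo_bundle, prune)

with tempfile.TemporaryDirectory() as tmp:
    paths = demo_bundle(tmp)
    taxa = load_ncbi_dump(paths["nodes"], paths["names"])

    # usage counts as a census would produce them: the mouse species
    # dominates, an odd sibling appears 3 times, and a non-leaf
    # herpesvirus taxon is used although its A/B children exist
    usage = {"NCBITaxon:10090": 990, "NCBITaxon:10095": 3,
             "NCBITaxon:10368": 5}
    view = prune(taxa, usage)
    print(f"pruned view: {len(view.kept)} of {len(taxa)} taxa kept")

    for f in flag_vague_usage(view, taxa):
        print(f"vague ({f.signal}): {f.term} used {f.count}x although "
              f"{len(f.available_descendants)} finer taxa are available: "
              f"{list(f.available_descendants)}")
    for s in flag_rare_sibling_variants(view, taxa, ratio_threshold=0.01):
        print(f"sibling-variant (advisory): {s.rare_term} used "
              f"{s.rare_count}x next to {s.common_sibling} "
              f"({s.common_count}x) — align for better grouping")

# The pruned view keeps used taxa plus their ancestry only.  Using the
# herpesvirus-6 parent where the A/B species exist is flagged as vague
# (weak signal: the children are merely available).  The 3 "Mus sp."
# records next to 990 "Mus musculus" records are not wrong, but they
# fragment grouping, so they are flagged as an advisory.
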