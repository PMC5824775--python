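"""Pruned views, vague/sibling flags and Finder tree export."""

import json

import pytest

from conftest import brute_force_ancestors, random_dag
from ontoqc.census import compute_census
from ontoqc.model import OntologyGraph, OntologyTerm
from ontoqc.ontology_io import load_ncbi_dump, load_obo
from ontoqc.pruner import (PruneError, collapse_single_child_chains,
                           export_finder_tree, finder_tree_json,
                           flag_rare_sibling_variants, flag_vague_usage,
                           prune, write_view)


@pytest.fixture(scope="module")
def taxonomy(bundle_dir):
    return load_ncbi_dump(bundle_dir / "ncbi_nodes.dmp",
                          bundle_dir / "ncbi_names.dmp")


def assert_ancestrally_closed(view, graph):
    for node in view.kept:
        assert graph.ancestors(node) <= view.kept
    assert {t for t, c in view.usage.items() if c > 0} <= view.kept
    for child, parent in view.edges:
        assert parent in graph.parents_of(child)


class TestPrune:
    def test_chain_closure(self, chain_graph):
        view = prune(chain_graph, {"T:C": 4})
        assert view.kept == {"T:A", "T:B", "T:C"}
        assert view.edges == {("T:B", "T:A"), ("T:C", "T:B")}
        assert view.usage == {"T:A": 0, "T:B": 0, "T:C": 4}

    def test_unused_mus_sp_excluded(self, taxonomy):
        view = prune(taxonomy, {"NCBITaxon:10090": 990})
        assert "NCBITaxon:10095" not in view.kept
        assert view.kept == {"NCBITaxon:1", "NCBITaxon:10088",
                             "NCBITaxon:10090"}

    def test_missing_used_curie_is_an_error_signal(self, taxonomy):
        with pytest.raises(PruneError) as err:
            prune(taxonomy, {"NCBITaxon:99999": 1})
        assert err.value.missing == ["NCBITaxon:99999"]

    def test_idempotent(self, taxonomy):
        usage = {"NCBITaxon:10090": 9, "NCBITaxon:10368": 3}
        v1 = prune(taxonomy, usage)
        sub = OntologyGraph({c: taxonomy.terms[c] for c in v1.kept})
        v2 = prune(sub, v1.usage)
        assert (v1.kept, v1.edges, v1.usage) == (v2.kept, v2.edges, v2.usage)

    def test_monotone_in_usage(self, taxonomy):
        small = prune(taxonomy, {"NCBITaxon:10090": 1})
        large = prune(taxonomy, {"NCBITaxon:10090": 1, "NCBITaxon:32603": 1})
        assert small.kept <= large.kept

    @pytest.mark.parametrize("seed", range(5))
    def test_kept_equals_brute_force_union(self, seed):
        import random
        g = random_dag(80, seed)
        rng = random.Random(seed + 1000)
        used = rng.sample(sorted(g.terms), 12)
        usage = {t: rng.randint(1, 9) for t in used}
        view = prune(g, usage)
        expected = set(used)
        for t in used:
            expected |= brute_force_ancestors(g, t)
        assert view.kept == expected
        assert_ancestrally_closed(view, g)


class TestVagueUsage:
    def test_hhv6_weak_signal_two_available_descendants(self, taxonomy):
        view = prune(taxonomy, {"NCBITaxon:10368": 3, "NCBITaxon:10090": 9})
        flags = flag_vague_usage(view, taxonomy)
        assert len(flags) == 1
        f = flags[0]
        assert f.term == "NCBITaxon:10368" and f.signal == "weak"
        assert f.available_descendants == ("NCBITaxon:32603",
                                           "NCBITaxon:32604")

    def test_used_descendant_is_strong_signal(self, taxonomy):
        view = prune(taxonomy, {"NCBITaxon:10368": 3, "NCBITaxon:32603": 5})
        f = [x for x in flag_vague_usage(view, taxonomy)
             if x.term == "NCBITaxon:10368"][0]
        assert f.signal == "strong"
        assert f.used_descendants == ("NCBITaxon:32603",)

    def test_leaf_only_usage_never_flagged(self, taxonomy):
        view = prune(taxonomy, {"NCBITaxon:10090": 5, "NCBITaxon:32604": 2})
        assert flag_vague_usage(view, taxonomy) == []


class TestSiblingVariants:
    def test_mus_sp_flagged_against_mus_musculus(self, taxonomy):
        usage = {"NCBITaxon:10090": 990, "NCBITaxon:10095": 3}
        view = prune(taxonomy, usage)
        flags = flag_rare_sibling_variants(view, taxonomy, 0.01)
        assert len(flags) == 1
        f = flags[0]
        assert (f.rare_term, f.common_sibling) == ("NCBITaxon:10095",
                                                   "NCBITaxon:10090")
        assert (f.rare_count, f.common_count) == (3, 990)
        assert f.severity == "advisory"

    def test_equal_counts_not_flagged(self, taxonomy):
        usage = {"NCBITaxon:10090": 10, "NCBITaxon:10095": 10}
        view = prune(taxonomy, usage)
        assert flag_rare_sibling_variants(view, taxonomy, 0.01) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_pair_scan(self, seed):
        import random
        g = random_dag(60, seed, max_parents=2)
        rng = random.Random(seed + 99)
        used = rng.sample(sorted(g.terms), 15)
        usage = {t: rng.choice([1, 2, 300, 500]) for t in used}
        view = prune(g, usage)
        ratio = 0.01
        flags = {(f.rare_term, f.common_sibling)
                 for f in flag_rare_sibling_variants(view, g, ratio)}
        # oracle: enumerate every used sibling pair, pick max-count mate
        expected = set()
        for r in used:
            sibs = set()
            for p in g.terms[r].parents:
                if p in g.terms:
                    sibs |= {c for c in g.terms
                             if p in g.terms[c].parents and c != r}
            cands = [s for s in sibs if s in usage]
            if not cands:
                continue
            best = max(cands, key=lambda s: (usage[s], s))
            if usage[r] / usage[best] < ratio:
                expected.add((r, best))
        assert flags == expected


class TestFinderTree:
    def test_chain_nests_three_levels(self, chain_graph):
        view = prune(chain_graph, {"T:C": 1})
        doc = export_finder_tree(view, chain_graph)
        root = doc["roots"][0]
        assert root["id"] == "T:A"
        assert root["children"][0]["id"] == "T:B"
        assert root["children"][0]["children"][0]["id"] == "T:C"

    def test_two_disjoint_assay_groups(self, bundle_dir):
        g = load_obo(bundle_dir / "assay_groups.obo")
        view = prune(g, {"OBI:1110181": 5, "OBI:1110191": 2})
        doc = export_finder_tree(view, g)
        (root,) = doc["roots"]
        groups = {c["id"]: c for c in root["children"]}
        assert set(groups) == {"OBI:1110180", "OBI:1110190"}
        assert [c["id"] for c in groups["OBI:1110180"]["children"]] == \
            ["OBI:1110181"]
        assert [c["id"] for c in groups["OBI:1110190"]["children"]] == \
            ["OBI:1110191"]

    def test_reexport_byte_identical(self, taxonomy):
        view = prune(taxonomy, {"NCBITaxon:10090": 9, "NCBITaxon:10368": 3})
        a = finder_tree_json(export_finder_tree(view, taxonomy))
        b = finder_tree_json(export_finder_tree(view, taxonomy))
        assert a == b
        json.loads(a)  # well-formed

    def test_dag_node_duplicated_under_each_parent_with_marker(self):
        g = OntologyGraph({
            "X:R": OntologyTerm("X:R", "root"),
            "X:A": OntologyTerm("X:A", "a", parents=["X:R"]),
            "X:B": OntologyTerm("X:B", "b", parents=["X:R"]),
            "X:C": OntologyTerm("X:C", "c", parents=["X:A", "X:B"]),
        })
        view = prune(g, {"X:C": 1})
        doc = export_finder_tree(view, g)
        (root,) = doc["roots"]
        cs = [kid["children"][0] for kid in root["children"]]
        assert [c["id"] for c in cs] == ["X:C", "X:C"]
        assert [c["repeat"] for c in cs] == [False, True]

    def test_collapse_pass_is_display_only(self, chain_graph):
        view = prune(chain_graph, {"T:C": 1})
        doc = export_finder_tree(view, chain_graph)
        collapsed = collapse_single_child_chains(doc["roots"][0])
        assert collapsed["id"] == "T:C" and "a / b / c" == collapsed["label"]
        # original document untouched
        assert doc["roots"][0]["id"] == "T:A"


def test_view_tsv_export_headers_carry_parameters(taxonomy, tmp_path):
    view = prune(taxonomy, {"NCBITaxon:10090": 2})
    nodes, edges = tmp_path / "n.tsv", tmp_path / "e.tsv"
    write_view(view, taxonomy, nodes, edges, params={"x": 1})
    head = nodes.read_text().splitlines()[0]
    assert head.startswith("#") and "params_hash=" in head
    assert len(edges.read_text().splitlines()) == 2 + len(view.edges)
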