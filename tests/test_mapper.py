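"""Legacy-term mapping, redundancy and imprecision detection."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontoqc.mapper import (detect_imprecision, detect_redundancy, map_all,
                           map_term, normalize_label, read_mappings,
                           write_mappings)
from ontoqc.model import (OntologyGraph, OntologyTerm, Synonym, SynonymScope)
from ontoqc.ontology_io import load_obo


@pytest.fixture(scope="module")
def cytokine(bundle_dir):
    return load_obo(bundle_dir / "cytokine.obo")


class TestNormalize:
    @pytest.mark.parametrize("raw,expected", [
        ("MIP-1b", "mip 1b"),
        ("IL-1α", "il 1alpha"),
        ("TNF_alpha / beta", "tnf alpha beta"),
        ("  CD8+   T cell ", "cd8 t cell"),
    ])
    def test_rules(self, raw, expected):
        assert normalize_label(raw) == expected

    @given(st.text(max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, s):
        once = normalize_label(s)
        assert normalize_label(once) == once


class TestMapTerm:
    def test_unique_exact_synonym_hit(self, cytokine):
        rec = map_term("CCL4", cytokine)
        assert rec.status == "unique"
        assert rec.candidates[0].ontology_id == "OBI:0001378"
        assert rec.candidates[0].match_kind == "exact-synonym"

    def test_shared_synonym_is_ambiguous(self, cytokine):
        rec = map_term("IL-1", cytokine)
        assert rec.status == "ambiguous"
        assert {c.ontology_id for c in rec.candidates} == {
            "OBI:0001745", "OBI:0001842"}

    def test_unknown_term_unmapped(self, cytokine):
        rec = map_term("no such term xyz", cytokine)
        assert rec.status == "unmapped" and rec.candidates == []

    def test_label_match(self, cytokine):
        rec = map_term("CCL4 release assay", cytokine)
        assert rec.status == "unique"
        assert rec.candidates[0].match_kind == "label"

    def test_normalized_fallback_never_mixed_with_exact(self, cytokine):
        rec = map_term("ccl4", cytokine)  # case differs: fallback tier
        assert rec.status == "unique"
        assert rec.candidates[0].match_kind == "normalized"

    def test_untrusted_scope_excluded_by_default(self):
        g = OntologyGraph({"X:1": OntologyTerm(
            "X:1", "thing", synonyms=[Synonym("alias", SynonymScope.RELATED)])})
        assert map_term("alias", g).status == "unmapped"
        rec = map_term("alias", g, scopes={SynonymScope.EXACT,
                                           SynonymScope.RELATED})
        assert rec.status == "unique"
        assert rec.candidates[0].match_kind == "scoped-synonym"

    def test_curated_override_wins(self, cytokine):
        rec = map_term("IL-1", cytokine,
                       curated_overrides={"IL-1": "OBI:0001745"})
        assert rec.status == "unique"
        assert rec.candidates[0].match_kind == "curated"

    def test_obsolete_hit_follows_replaced_by_and_notes(self):
        g = OntologyGraph({
            "X:1": OntologyTerm("X:1", "current"),
            "X:2": OntologyTerm("X:2", "retired name", obsolete=True,
                                replaced_by="X:1"),
        })
        rec = map_term("retired name", g)
        assert rec.status == "unique"
        assert rec.candidates[0].ontology_id == "X:1"
        assert "replaced by X:1" in rec.note

    def test_fuzzy_opt_in_reports_score(self, cytokine):
        assert map_term("CCL4 release asay", cytokine).status == "unmapped"
        rec = map_term("CCL4 release asay", cytokine, fuzzy_cutoff=0.8)
        assert rec.candidates and rec.candidates[0].match_kind == "fuzzy"
        assert 0.8 <= rec.candidates[0].score <= 1.0


class TestMapAll:
    def test_empty_input(self, cytokine):
        assert map_all([], cytokine) == []

    def test_lexicographic_and_idempotent(self, cytokine):
        terms = {"MIP1b", "CCL4", "IL-1"}
        recs1 = map_all(terms, cytokine)
        assert [r.legacy_term for r in recs1] == ["CCL4", "IL-1", "MIP1b"]
        assert recs1 == map_all(terms, cytokine)

    def test_status_partition(self, cytokine):
        terms = {"CCL4", "MIP1b", "IL-1", "junk1", "junk2"}
        recs = map_all(terms, cytokine)
        by_status = {s: sum(r.status == s for r in recs)
                     for s in ("unique", "ambiguous", "unmapped")}
        assert sum(by_status.values()) == len(terms)
        assert by_status == {"unique": 2, "ambiguous": 1, "unmapped": 2}


class TestDetection:
    def test_ccl4_mip1b_single_cluster(self, cytokine):
        recs = map_all({"CCL4", "MIP1b", "IL-1"}, cytokine)
        clusters = detect_redundancy(recs)
        assert len(clusters) == 1
        assert clusters[0].ontology_id == "OBI:0001378"
        assert clusters[0].legacy_terms == frozenset({"CCL4", "MIP1b"})

    def test_distinct_targets_no_cluster(self, cytokine):
        recs = map_all({"CCL4", "IL-1a"}, cytokine)
        assert detect_redundancy(recs) == []

    def test_imprecision_returns_all_candidates(self, cytokine):
        recs = map_all({"CCL4", "MIP1b", "IL-1"}, cytokine)
        amb = detect_imprecision(recs)
        assert [r.legacy_term for r in amb] == ["IL-1"]
        assert len(amb[0].candidates) == 2

    def test_redundancy_and_imprecision_disjoint(self, cytokine):
        recs = map_all({"CCL4", "MIP1b", "IL-1"}, cytokine)
        clustered = {t for c in detect_redundancy(recs)
                     for t in c.legacy_terms}
        ambiguous = {r.legacy_term for r in detect_imprecision(recs)}
        assert not clustered & ambiguous

    def test_injected_baits_recovered_exactly(self):
        from ontoqc.fixtures import make_toy_ontology
        graph, frag = make_toy_ontology(n_terms=100, n_shared_synonyms=4,
                                        n_ambiguous_synonyms=3, seed=11)
        legacy = set()
        for b in frag["shared_synonyms"]:
            legacy |= set(b["synonyms"])
        for b in frag["ambiguous_synonyms"]:
            legacy.add(b["synonym"])
        recs = map_all(legacy, graph)
        clusters = detect_redundancy(recs)
        assert len(clusters) == 4 and all(len(c) == 2 for c in clusters)
        assert {r.legacy_term for r in detect_imprecision(recs)} == {
            b["synonym"] for b in frag["ambiguous_synonyms"]}


def test_mapping_tsv_round_trip(cytokine, tmp_path):
    recs = map_all({"CCL4", "IL-1", "junk"}, cytokine)
    p = tmp_path / "m.tsv"
    write_mappings(recs, p)
    back = read_mappings(p)
    assert [(r.legacy_term, r.status,
             [c.ontology_id for c in r.candidates]) for r in back] == \
           [(r.legacy_term, r.status,
             [c.ontology_id for c in r.candidates]) for r in recs]
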