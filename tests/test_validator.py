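"""Cross-field rule compilation, validation and autofill."""

import pandas as pd
import pytest

from ontoqc.census import CuratedTable
from ontoqc.ontology_io import load_obo
from ontoqc.validator import (UnboundFieldError, apply_suggestions,
                              compile_rules, read_rules, suggest_autofill,
                              suggest_autofill_table, validate, write_rules)

FIELD_SPEC = {"disease": "curie", "immunogen": "curie"}


@pytest.fixture(scope="module")
def diseases(bundle_dir):
    return load_obo(bundle_dir / "do_slice.obo")


@pytest.fixture(scope="module")
def agents(bundle_dir):
    return load_obo(bundle_dir / "agents.obo")


@pytest.fixture(scope="module")
def dengue_rules(diseases):
    return compile_rules(diseases, {"has_material_basis_in"},
                         ("disease", "immunogen"))


def table_of(rows):
    df = pd.DataFrame(rows, columns=["record_id", "disease", "immunogen"])
    return CuratedTable(df, dict(FIELD_SPEC), id_field="record_id")


class TestCompileRules:
    def test_dengue_axiom_yields_one_rule(self, dengue_rules):
        assert len(dengue_rules) == 1
        r = dengue_rules[0]
        assert r.trigger_term == "DOID:12205"
        assert r.required_term == "NCBITaxon:12637"
        assert r.relation == "has_material_basis_in"

    def test_no_matching_relations_empty(self, diseases):
        assert compile_rules(diseases, {"never_heard_of"},
                             ("disease", "immunogen")) == []

    def test_injected_axiom_count_matches(self):
        from ontoqc.fixtures import make_toy_ontology
        graph, frag = make_toy_ontology(n_terms=80, n_axioms=4, seed=5)
        rules = compile_rules(graph, {"has_material_basis_in"},
                              ("disease", "immunogen"))
        assert len(rules) == 4
        assert {(r.trigger_term, r.required_term) for r in rules} == {
            (a["trigger"], a["target"]) for a in frag["axioms"]}

    def test_empty_relation_set_rejected(self, diseases):
        with pytest.raises(ValueError):
            compile_rules(diseases, set(), ("disease", "immunogen"))


class TestValidate:
    def test_consistent_record_passes(self, dengue_rules, diseases, agents):
        t = table_of([("r1", "DOID:12205", "NCBITaxon:12637")])
        assert validate(t, dengue_rules, agents, diseases) == []

    def test_contradiction_is_one_violation(self, dengue_rules, diseases,
                                            agents):
        t = table_of([("r1", "DOID:12205", "NCBITaxon:11676")])
        out = validate(t, dengue_rules, agents, diseases)
        assert len(out) == 1
        assert out[0].verdict == "violation"
        assert out[0].record_id == "r1"

    def test_descendant_terms_satisfy_by_subsumption(self, dengue_rules,
                                                     diseases, agents):
        # strain-level disease and serotype-level immunogen
        t = table_of([("r1", "DOID:12206", "NCBITaxon:11053")])
        assert validate(t, dengue_rules, agents, diseases) == []
        # brute-force oracle for the same subsumption decision
        assert "NCBITaxon:12637" in agents.ancestors("NCBITaxon:11053")
        assert "DOID:12205" in diseases.ancestors("DOID:12206")

    def test_equality_only_mode_flags_descendants(self, dengue_rules,
                                                  diseases, agents):
        t = table_of([("r1", "DOID:12205", "NCBITaxon:11053")])
        assert validate(t, dengue_rules, agents, diseases) == []
        strict = validate(t, dengue_rules, agents, diseases,
                          subsumption=False)
        assert len(strict) == 1 and strict[0].verdict == "violation"

    def test_empty_required_field_is_missing_value(self, dengue_rules,
                                                   diseases, agents):
        t = table_of([("r1", "DOID:12205", "")])
        out = validate(t, dengue_rules, agents, diseases)
        assert len(out) == 1 and out[0].verdict == "missing-value"

    def test_empty_trigger_never_fires(self, dengue_rules, diseases, agents):
        t = table_of([("r1", "", "NCBITaxon:11676")])
        assert validate(t, dengue_rules, agents, diseases) == []

    def test_unbound_field_errors(self, dengue_rules, agents):
        df = pd.DataFrame({"record_id": ["r1"], "disease": ["DOID:12205"]})
        t = CuratedTable(df, {"disease": "curie"}, id_field="record_id")
        with pytest.raises(UnboundFieldError):
            validate(t, dengue_rules, agents)

    def test_any_rule_satisfies_with_conflict_diagnostic(self, agents):
        from ontoqc.model import OntologyGraph, OntologyTerm
        g = OntologyGraph({
            "D:1": OntologyTerm("D:1", "dual-basis disease", relationships=[
                ("has_material_basis_in", "NCBITaxon:12637"),
                ("has_material_basis_in", "NCBITaxon:11676")])})
        rules = compile_rules(g, {"has_material_basis_in"},
                              ("disease", "immunogen"))
        t = table_of([("r1", "D:1", "NCBITaxon:11676")])
        diags = []
        assert validate(t, rules, agents, g, diagnostics=diags) == []
        assert diags and "disagree" in diags[0]


class TestAutofill:
    def test_empty_field_gets_suggestion(self, dengue_rules, diseases):
        recs = suggest_autofill({"disease": "DOID:12205", "immunogen": ""},
                                dengue_rules, diseases, record_id="r1")
        assert len(recs) == 1
        assert recs[0].suggested == "NCBITaxon:12637"
        assert recs[0].field == "immunogen"

    def test_non_empty_value_never_overwritten(self, dengue_rules, diseases):
        recs = suggest_autofill(
            {"disease": "DOID:12205", "immunogen": "NCBITaxon:11676"},
            dengue_rules, diseases)
        assert recs == []

    def test_no_rule_no_suggestion(self, dengue_rules, diseases):
        assert suggest_autofill({"disease": "DOID:934", "immunogen": ""},
                                dengue_rules, diseases) == []

    def test_conflicting_suggestions_suppressed(self):
        from ontoqc.model import OntologyGraph, OntologyTerm
        g = OntologyGraph({
            "D:1": OntologyTerm("D:1", "dual", relationships=[
                ("has_material_basis_in", "A:1"),
                ("has_material_basis_in", "A:2")])})
        rules = compile_rules(g, {"has_material_basis_in"},
                              ("disease", "immunogen"))
        diags = []
        recs = suggest_autofill({"disease": "D:1", "immunogen": ""}, rules, g,
                                record_id="r9", diagnostics=diags)
        assert recs == [] and diags and "ambiguous autofill" in diags[0]

    def test_apply_then_revalidate_closes(self, dengue_rules, diseases,
                                          agents):
        t = table_of([
            ("r1", "DOID:12205", "NCBITaxon:12637"),
            ("r2", "DOID:12205", ""),
            ("r3", "DOID:12205", "NCBITaxon:11676"),
        ])
        before = validate(t, dengue_rules, agents, diseases)
        assert {v.verdict for v in before} == {"missing-value", "violation"}
        sugg = suggest_autofill_table(t, dengue_rules, diseases)
        t2 = apply_suggestions(t, sugg)
        after = validate(t2, dengue_rules, agents, diseases)
        assert all(v.verdict == "violation" for v in after)
        assert {v.record_id for v in after} == {"r3"}  # no new violations


def test_rules_tsv_round_trip(dengue_rules, tmp_path):
    p = tmp_path / "rules.tsv"
    write_rules(dengue_rules, p)
    assert read_rules(p) == dengue_rules
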