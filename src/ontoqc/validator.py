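"""Cross-field consistency rules compiled from ontology axioms.

Disease ontologies logically define many diseases by their causative
agent (e.g. dengue fever *has_material_basis_in* dengue virus).  When
a curated table stores the disease and the causative immunogen in
independently curated columns, those axioms become executable checks:
every record whose disease field matches a rule's trigger must carry
the rule's required term — or a descendant of it — in the bound
companion field.  Records that leave the companion field empty get an
advisory auto-fill suggestion instead of a violation; suggestions are
never applied to the table.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .census import CuratedTable
from .model import OntologyGraph, OntoQCError

logger = logging.getLogger(__name__)

DEFAULT_RELATIONS = frozenset({"has_material_basis_in"})


class UnboundFieldError(OntoQCError):
    def __init__(self, fieldname: str):
        super().__init__(f"rule field not bound in table: {fieldname}")


@dataclass(frozen=True)
class CrossFieldRule:
    """If ``trigger_field`` holds ``trigger_term`` (or a descendant),
    ``required_field`` must hold ``required_term`` (or a descendant)."""

    trigger_field: str
    trigger_term: str
    required_field: str
    required_term: str
    relation: str
    source: str = "derived-from-ontology"  # or user-config

    def __post_init__(self):
        if self.trigger_field == self.required_field:
            raise ValueError("trigger and required fields must differ")


@dataclass(frozen=True)
class ValidationViolation:
    record_id: str
    rule: CrossFieldRule
    observed_value: str  # empty string for missing-value verdicts
    verdict: str  # violation | missing-value
    error_class: str = "cross-field-violation"


@dataclass(frozen=True)
class AutofillSuggestion:
    record_id: str
    field: str
    suggested: str
    rule: CrossFieldRule


def compile_rules(disease_graph: OntologyGraph,
                  relation_names: Iterable[str] = DEFAULT_RELATIONS,
                  field_binding: tuple[str, str] = ("disease", "immunogen"),
                  target_graph: OntologyGraph | None = None,
                  strict: bool = False) -> list[CrossFieldRule]:
    """Turn relationship axioms into cross-field rules.

    One rule per term relationship whose relation name is in
    ``relation_names``.  If ``target_graph`` is given, rules whose
    required term does not resolve there are skipped with a warning
    (lenient) or raise (strict) — relation targets often live in a
    different ontology than the triggers (taxa vs diseases).
    """
    names = set(relation_names)
    if not names:
        raise ValueError("relation_names must be non-empty")
    trigger_field, required_field = field_binding
    rules: list[CrossFieldRule] = []
    for curie in sorted(disease_graph.terms):
        for relation, target in disease_graph.terms[curie].relationships:
            if relation not in names:
                continue
            if target_graph is not None and target not in target_graph:
                msg = f"rule target {target} (from {curie}) unresolvable"
                if strict:
                    raise OntoQCError(msg)
                logger.warning(msg)
                continue
            rules.append(CrossFieldRule(
                trigger_field=trigger_field, trigger_term=curie,
                required_field=required_field, required_term=target,
                relation=relation))
    return rules


def _matches(graph: OntologyGraph, observed: str, target: str,
             subsumption: bool) -> bool:
    if observed == target:
        return True
    if subsumption and observed in graph:
        return graph.is_descendant(observed, target)
    return False


def validate(table: CuratedTable, rules: Sequence[CrossFieldRule],
             immunogen_graph: OntologyGraph,
             disease_graph: OntologyGraph | None = None,
             subsumption: bool = True,
             diagnostics: list[str] | None = None) -> list[ValidationViolation]:
    """Apply cross-field rules to every record.

    A record triggers a rule when its trigger-field value equals the
    trigger term or is a descendant of it.  It passes when the required
    field satisfies *any* triggered rule for that field (diseases may
    list several material bases); conflicting triggered rules are
    reported through ``diagnostics``.  An empty required field yields a
    ``missing-value`` verdict; an empty trigger field never fires.

    ``subsumption=False`` switches to equality-only matching.
    """
    for rule in rules:
        for f in (rule.trigger_field, rule.required_field):
            if f not in table.field_spec:
                raise UnboundFieldError(f)
    tgraph = disease_graph or immunogen_graph
    out: list[ValidationViolation] = []
    ids = table.record_ids()
    for idx, row in enumerate(table.df.to_dict("records")):
        rid = ids[idx]
        # group triggered rules by required field: any-rule-satisfies
        fired: dict[str, list[CrossFieldRule]] = {}
        for rule in rules:
            trigger_value = str(row.get(rule.trigger_field, "")).strip()
            if not trigger_value:
                continue
            if _matches(tgraph, trigger_value, rule.trigger_term, subsumption):
                fired.setdefault(rule.required_field, []).append(rule)
        for required_field, group in sorted(fired.items()):
            required_terms = {r.required_term for r in group}
            if len(required_terms) > 1 and diagnostics is not None:
                diagnostics.append(
                    f"record {rid}: rules for {required_field} disagree: "
                    + ", ".join(sorted(required_terms)))
            observed = str(row.get(required_field, "")).strip()
            if not observed:
                out.append(ValidationViolation(
                    record_id=rid, rule=group[0], observed_value="",
                    verdict="missing-value"))
                continue
            ok = any(_matches(immunogen_graph, observed, r.required_term,
                              subsumption) for r in group)
            if not ok:
                out.append(ValidationViolation(
                    record_id=rid, rule=group[0], observed_value=observed,
                    verdict="violation"))
    return out


def suggest_autofill(record: Mapping[str, str], rules: Sequence[CrossFieldRule],
                     graph: OntologyGraph, record_id: str = "",
                     subsumption: bool = True,
                     diagnostics: list[str] | None = None,
                     ) -> list[AutofillSuggestion]:
    """Suggest values for empty required fields of one record.

    Only advisory: a non-empty value is never overwritten, and if two
    triggered rules would fill the same field with different terms no
    suggestion is emitted (auto-picking would recreate the imprecision
    error class) — only a diagnostic.
    """
    proposals: dict[str, dict[str, CrossFieldRule]] = {}
    for rule in rules:
        trigger_value = str(record.get(rule.trigger_field, "")).strip()
        if not trigger_value:
            continue
        if not _matches(graph, trigger_value, rule.trigger_term, subsumption):
            continue
        if str(record.get(rule.required_field, "")).strip():
            continue  # never overwrite curated content
        proposals.setdefault(rule.required_field, {})[rule.required_term] = rule
    out: list[AutofillSuggestion] = []
    for fieldname, by_term in sorted(proposals.items()):
        if len(by_term) > 1:
            if diagnostics is not None:
                diagnostics.append(
                    f"record {record_id}: ambiguous autofill for {fieldname}: "
                    + ", ".join(sorted(by_term)))
            continue
        (term, rule), = by_term.items()
        out.append(AutofillSuggestion(record_id=record_id, field=fieldname,
                                      suggested=term, rule=rule))
    return out


def suggest_autofill_table(table: CuratedTable, rules: Sequence[CrossFieldRule],
                           graph: OntologyGraph, subsumption: bool = True,
                           diagnostics: list[str] | None = None,
                           ) -> list[AutofillSuggestion]:
    """Batch :func:`suggest_autofill` over a whole table."""
    out: list[AutofillSuggestion] = []
    ids = table.record_ids()
    for idx, row in enumerate(table.df.to_dict("records")):
        out.extend(suggest_autofill(row, rules, graph, record_id=ids[idx],
                                    subsumption=subsumption,
                                    diagnostics=diagnostics))
    return out


def apply_suggestions(table: CuratedTable,
                      suggestions: Iterable[AutofillSuggestion]) -> CuratedTable:
    """Return a copy of the table with suggestions filled in (for
    what-if analysis; the validator itself never mutates input)."""
    df = table.df.copy()
    ids = table.record_ids()
    pos = {rid: i for i, rid in enumerate(ids)}
    for s in suggestions:
        i = pos[s.record_id]
        if not str(df.iloc[i][s.field]).strip():
            df.iloc[i, df.columns.get_loc(s.field)] = s.suggested
    return CuratedTable(df=df, field_spec=dict(table.field_spec),
                        provenance=table.provenance + "+autofill",
                        id_field=table.id_field)


# ---------------------------------------------------------------------------
# round-trip I/O

_RULE_COLS = ["trigger_field", "trigger_term", "required_field",
              "required_term", "relation", "source"]


def write_rules(rules: Iterable[CrossFieldRule], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_RULE_COLS)
        for r in rules:
            w.writerow([getattr(r, c) for c in _RULE_COLS])


def read_rules(path: str | Path) -> list[CrossFieldRule]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [CrossFieldRule(**row)
                for row in csv.DictReader(fh, delimiter="\t")]


def write_violations(violations: Iterable[ValidationViolation],
                     path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["record_id", "verdict", "trigger_term", "required_term",
                    "observed_value", "relation"])
        for v in violations:
            w.writerow([v.record_id, v.verdict, v.rule.trigger_term,
                        v.rule.required_term, v.observed_value,
                        v.rule.relation])


def write_suggestions(suggestions: Iterable[AutofillSuggestion],
                      path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["record_id", "field", "suggested", "trigger_term"])
        for s in suggestions:
            w.writerow([s.record_id, s.field, s.suggested,
                        s.rule.trigger_term])


def load_rule_config(path: str | Path) -> dict:
    """Rule configuration: field bindings, relation names, strictness."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("relations", sorted(DEFAULT_RELATIONS))
    cfg.setdefault("strict", False)
    cfg.setdefault("subsumption", True)
    return cfg
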