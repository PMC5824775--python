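"""End-to-end pipeline: census → map → detect → prune → validate.

One YAML config names the ontologies, the curated table, the field
bindings and the thresholds; :func:`run_pipeline` executes every stage
in order and folds all findings into a single :class:`FlagReport` —
one row per (subject, error class, evidence, suggestion) — alongside
the raw stage outputs.  Re-running on identical inputs produces
byte-identical reports; all logging goes to stderr, never into data
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import census as census_mod
from . import mapper as mapper_mod
from . import pruner as pruner_mod
from . import validator as validator_mod
from .census import CuratedTable, RareTermFlag, UsageCensus
from .mapper import MappingRecord, RedundancyCluster
from .model import OntologyGraph, OntoQCError, SynonymScope
from .ontology_io import load_ncbi_dump, load_obo
from .pruner import (PrunedView, SiblingVariantFlag, VagueUsageFlag,
                     export_finder_tree, finder_tree_json)
from .validator import (AutofillSuggestion, CrossFieldRule,
                        ValidationViolation, apply_suggestions)

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["source_field", "subject", "error_class", "evidence",
                  "suggestion", "severity", "parameters_hash"]


@dataclass(frozen=True)
class FlagRow:
    source_field: str
    subject: str            # a record id or a term, depending on class
    error_class: str
    evidence: str
    suggestion: str
    severity: str           # error | advisory
    parameters_hash: str


@dataclass
class FlagReport:
    rows: list[FlagRow] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def errors(self) -> list[FlagRow]:
        return [r for r in self.rows if r.severity == "error"]

    def to_tsv(self) -> str:
        lines = ["# ontoqc report parameters="
                 + json.dumps(self.parameters, sort_keys=True)]
        lines.append("\t".join(REPORT_COLUMNS))
        for r in self.rows:
            lines.append("\t".join(getattr(r, c) for c in REPORT_COLUMNS))
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps({
            "parameters": self.parameters,
            "rows": [{c: getattr(r, c) for c in REPORT_COLUMNS}
                     for r in self.rows],
        }, indent=1, sort_keys=True)


@dataclass
class PipelineResult:
    """Raw stage outputs plus the unified report."""

    report: FlagReport
    censuses: dict[str, UsageCensus] = field(default_factory=dict)
    rare_flags: dict[str, list[RareTermFlag]] = field(default_factory=dict)
    mappings: dict[str, list[MappingRecord]] = field(default_factory=dict)
    clusters: dict[str, list[RedundancyCluster]] = field(default_factory=dict)
    imprecise: dict[str, list[MappingRecord]] = field(default_factory=dict)
    views: dict[str, PrunedView] = field(default_factory=dict)
    vague_flags: dict[str, list[VagueUsageFlag]] = field(default_factory=dict)
    sibling_flags: dict[str, list[SiblingVariantFlag]] = field(default_factory=dict)
    rules: list[CrossFieldRule] = field(default_factory=list)
    violations: list[ValidationViolation] = field(default_factory=list)
    suggestions: list[AutofillSuggestion] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)
    table: CuratedTable | None = None
    graphs: dict[str, OntologyGraph] = field(default_factory=dict)


def _params_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg["_base_dir"] = str(path.parent)
    return cfg


def _resolve(base: str, p: str | Path) -> Path:
    p = Path(p)
    return p if p.is_absolute() else Path(base) / p


def _load_graphs(cfg: dict) -> dict[str, OntologyGraph]:
    base = cfg.get("_base_dir", ".")
    strict = bool(cfg.get("strict", False))
    graphs: dict[str, OntologyGraph] = {}
    for name, spec in (cfg.get("ontologies") or {}).items():
        if isinstance(spec, dict):
            graphs[name] = load_ncbi_dump(
                _resolve(base, spec["nodes"]), _resolve(base, spec["names"]),
                prefix=spec.get("prefix", "NCBITaxon:"), strict=strict)
        else:
            graphs[name] = load_obo(_resolve(base, spec), strict=strict)
    return graphs


def run_pipeline(config: dict | str | Path,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the whole audit described by ``config``.

    Stages, in the order a curation audit proceeds: per-field usage
    census with rare-outlier flags; legacy-term mapping with
    redundancy/imprecision detection; ontology pruning with
    vague-usage and sibling-variant flags (plus a Finder tree export);
    cross-field rule compilation and validation with auto-fill
    suggestions.  Stage outputs are written under ``out_dir`` (or the
    config's ``out_dir``) with deterministic names.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    base = cfg.get("_base_dir", ".")
    thresholds = cfg.get("thresholds") or {}
    min_count = int(thresholds.get("min_count", census_mod.DEFAULT_MIN_COUNT))
    min_fraction = float(thresholds.get("min_fraction",
                                        census_mod.DEFAULT_MIN_FRACTION))
    sibling_ratio = float(thresholds.get("sibling_ratio",
                                         pruner_mod.DEFAULT_SIBLING_RATIO))
    delimiter = str(cfg.get("delimiter", census_mod.DEFAULT_DELIMITER))

    public_cfg = {k: v for k, v in cfg.items() if not k.startswith("_")}
    phash = _params_hash(public_cfg)
    report = FlagReport(parameters={"hash": phash, "config": public_cfg})
    result = PipelineResult(report=report)

    graphs = _load_graphs(cfg)
    result.graphs = graphs

    fields_cfg = cfg.get("fields") or {}
    field_spec = {name: (spec.get("kind", "curie") if isinstance(spec, dict)
                         else str(spec))
                  for name, spec in fields_cfg.items()}
    field_graph = {name: spec.get("ontology") for name, spec in
                   fields_cfg.items() if isinstance(spec, dict)}

    table = CuratedTable.read(_resolve(base, cfg["table"]), field_spec,
                              id_field=cfg.get("id_field"))
    result.table = table

    def add(source_field: str, subject: str, error_class: str,
            evidence: str, severity: str, suggestion: str = "") -> None:
        report.rows.append(FlagRow(source_field, subject, error_class,
                                   evidence, suggestion, severity, phash))

    # -- stage 1: census + rare outliers ---------------------------------
    for fieldname in cfg.get("census_fields", []):
        c = census_mod.compute_census(table, fieldname, delimiter=delimiter)
        result.censuses[fieldname] = c
        flags = census_mod.flag_rare_terms(c, min_count, min_fraction)
        result.rare_flags[fieldname] = flags
        for f in flags:
            add(fieldname, f.term, "rare-outlier",
                f"count={f.count} fraction={f.fraction:.6f} "
                f"min_count={min_count} min_fraction={min_fraction}",
                "error")

    # -- stage 2: mapping + redundancy/imprecision ------------------------
    scopes = frozenset(
        SynonymScope(s) for s in
        (cfg.get("mapping", {}) or {}).get("scopes", ["EXACT"]))
    for fieldname in cfg.get("map_fields", []):
        gname = field_graph.get(fieldname)
        if gname is None or gname not in graphs:
            raise OntoQCError(f"map field {fieldname} has no bound ontology")
        c = result.censuses.get(fieldname) or census_mod.compute_census(
            table, fieldname, delimiter=delimiter)
        mappings = mapper_mod.map_all(c.counts.keys(), graphs[gname],
                                      scopes=scopes)
        result.mappings[fieldname] = mappings
        clusters = mapper_mod.detect_redundancy(mappings)
        result.clusters[fieldname] = clusters
        for cl in clusters:
            add(fieldname, cl.ontology_id, "redundant",
                "legacy_terms=" + "|".join(sorted(cl.legacy_terms)), "error",
                suggestion=f"merge onto {cl.ontology_id}")
        ambiguous = mapper_mod.detect_imprecision(mappings)
        result.imprecise[fieldname] = ambiguous
        for rec in ambiguous:
            add(fieldname, rec.legacy_term, "imprecise",
                "candidates=" + "|".join(c.ontology_id
                                         for c in rec.candidates),
                "error", suggestion="review original publications")

    # -- stage 3: prune + vague / sibling flags + finder tree -------------
    finder_docs: dict[str, str] = {}
    for fieldname in cfg.get("prune_fields", []):
        gname = field_graph.get(fieldname)
        if gname is None or gname not in graphs:
            raise OntoQCError(f"prune field {fieldname} has no bound ontology")
        graph = graphs[gname]
        c = result.censuses.get(fieldname) or census_mod.compute_census(
            table, fieldname, delimiter=delimiter)
        view = pruner_mod.prune(graph, c.counts)
        result.views[fieldname] = view
        vague = pruner_mod.flag_vague_usage(view, graph)
        result.vague_flags[fieldname] = vague
        for v in vague:
            add(fieldname, v.term, "vague",
                f"signal={v.signal} used_descendants="
                + "|".join(v.used_descendants)
                + " available_descendants=" + "|".join(v.available_descendants),
                "error" if v.signal == "strong" else "advisory",
                suggestion="consider a more specific descendant")
        sib = pruner_mod.flag_rare_sibling_variants(view, graph, sibling_ratio)
        result.sibling_flags[fieldname] = sib
        for s in sib:
            add(fieldname, s.rare_term, "sibling-variant",
                f"common_sibling={s.common_sibling} "
                f"counts={s.rare_count}/{s.common_count}",
                "advisory", suggestion=f"align with {s.common_sibling}")
        finder_docs[fieldname] = finder_tree_json(export_finder_tree(
            view, graph, meta={"field": fieldname, "params_hash": phash}))

    # -- stage 4: cross-field rules ---------------------------------------
    rules_cfg = cfg.get("rules")
    if rules_cfg:
        tg = graphs[rules_cfg["trigger_ontology"]]
        rg = graphs[rules_cfg["required_ontology"]]
        rules = validator_mod.compile_rules(
            tg, relation_names=rules_cfg.get(
                "relations", sorted(validator_mod.DEFAULT_RELATIONS)),
            field_binding=(rules_cfg["trigger_field"],
                           rules_cfg["required_field"]),
            target_graph=rg if rules_cfg.get("check_targets") else None,
            strict=bool(cfg.get("strict", False)))
        result.rules = rules
        subsumption = bool(rules_cfg.get("subsumption", True))
        violations = validator_mod.validate(
            table, rules, rg, disease_graph=tg, subsumption=subsumption,
            diagnostics=result.diagnostics)
        result.violations = violations
        suggestions = validator_mod.suggest_autofill_table(
            table, rules, tg, subsumption=subsumption,
            diagnostics=result.diagnostics)
        result.suggestions = suggestions
        sugg_by_record = {(s.record_id, s.field): s.suggested
                          for s in suggestions}
        for v in violations:
            suggestion = ""
            if v.verdict == "missing-value":
                suggestion = sugg_by_record.get(
                    (v.record_id, v.rule.required_field), "")
            add(v.rule.required_field, v.record_id, "cross-field-violation",
                f"verdict={v.verdict} trigger={v.rule.trigger_term} "
                f"required={v.rule.required_term} observed={v.observed_value}",
                "error" if v.verdict == "violation" else "advisory",
                suggestion=suggestion)

    # -- outputs -----------------------------------------------------------
    out = out_dir or cfg.get("out_dir")
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.tsv").write_text(report.to_tsv(), encoding="utf-8")
        (out / "report.json").write_text(report.to_json(), encoding="utf-8")
        for fieldname, c in result.censuses.items():
            c.to_frame().to_csv(out / f"census_{fieldname}.tsv", sep="\t",
                                index=False)
        for fieldname, mappings in result.mappings.items():
            mapper_mod.write_mappings(mappings,
                                      out / f"mappings_{fieldname}.tsv")
            mapper_mod.write_clusters(result.clusters[fieldname],
                                      out / f"clusters_{fieldname}.tsv")
        for fieldname, view in result.views.items():
            pruner_mod.write_view(view, graphs[field_graph[fieldname]],
                                  out / f"view_nodes_{fieldname}.tsv",
                                  out / f"view_edges_{fieldname}.tsv",
                                  params={"hash": phash})
            (out / f"finder_{fieldname}.json").write_text(
                finder_docs[fieldname], encoding="utf-8")
        if result.rules:
            validator_mod.write_rules(result.rules, out / "rules.tsv")
            validator_mod.write_violations(result.violations,
                                           out / "violations.tsv")
            validator_mod.write_suggestions(result.suggestions,
                                            out / "suggestions.tsv")
        if result.diagnostics:
            (out / "diagnostics.txt").write_text(
                "\n".join(result.diagnostics) + "\n", encoding="utf-8")
    logger.info("pipeline finished: %d flags (%d errors)",
                len(report), len(report.errors()))
    return result


# ---------------------------------------------------------------------------
# scoring against a fixture ledger

def observed_sets(result: PipelineResult) -> dict[str, set]:
    """Canonical per-class comparison units from pipeline output."""
    out: dict[str, set] = {c: set() for c in (
        "rare-outlier", "redundant", "imprecise", "vague",
        "sibling-variant", "cross-field-violation")}
    for flags in result.rare_flags.values():
        out["rare-outlier"] |= {f.term for f in flags}
    for clusters in result.clusters.values():
        out["redundant"] |= {(c.ontology_id, tuple(sorted(c.legacy_terms)))
                             for c in clusters}
    for recs in result.imprecise.values():
        out["imprecise"] |= {r.legacy_term for r in recs}
    for flags in result.vague_flags.values():
        out["vague"] |= {f.term for f in flags}
    for flags in result.sibling_flags.values():
        out["sibling-variant"] |= {(f.rare_term, f.common_sibling)
                                   for f in flags}
    out["cross-field-violation"] |= {v.record_id for v in result.violations
                                     if v.verdict == "violation"}
    return out


def evaluate_against_ledger(result: PipelineResult, ledger) -> dict[str, dict]:
    """Per-class precision/recall of the pipeline against a ground-
    truth :class:`~ontoqc.fixtures.ErrorLedger`.  Empty-vs-empty
    classes score 1.0/1.0."""
    expected = ledger.expected_sets()
    observed = observed_sets(result)
    scores: dict[str, dict] = {}
    for cls in expected:
        exp, obs = expected[cls], observed.get(cls, set())
        tp = len(exp & obs)
        scores[cls] = {
            "tp": tp, "fp": len(obs - exp), "fn": len(exp - obs),
            "precision": tp / len(obs) if obs else (1.0 if not exp else 0.0),
            "recall": tp / len(exp) if exp else 1.0,
        }
    return scores
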