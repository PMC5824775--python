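"""Synthetic ontologies and curated tables with a ground-truth ledger.

Every detector in this package is exercised against generated inputs
whose injected errors are known exactly.  The generator emits:

* a toy DAG ontology (OBO) with controlled shape, redundancy bait
  (terms carrying two distinct EXACT synonyms), imprecision bait
  (one synonym string attached to two terms) and relationship axioms;
* a curated table whose background usage follows a Zipf(1.0) skew over
  ontology leaves — curated corpora are heavily skewed toward a few
  workhorse terms — with errors of all six classes injected into
  disjoint records;
* an :class:`ErrorLedger` recording exactly what was injected, so
  detector output can be scored as precision/recall.

Background records are constructed so that none of them trips the
default thresholds: every background term is used at least ``floor``
times, background siblings receive adjacent Zipf ranks (hence similar
counts), and only leaves are used outside the injected errors.  On a
noiseless fixture the detectors must therefore recover the ledger with
precision = recall = 1.0 — any deviation is an implementation bug.

A separate :func:`demo_bundle` writes a small hand-built worked-
example bundle (cytokine assay synonyms, a mouse/herpesvirus taxonomy
slice, a dengue disease slice) used throughout the documentation.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .census import CuratedTable, DEFAULT_MIN_COUNT, DEFAULT_MIN_FRACTION
from .model import OntologyGraph, OntologyTerm, OntoQCError, Synonym, SynonymScope
from .ontology_io import load_obo, write_obo
from .pruner import DEFAULT_SIBLING_RATIO

ERROR_CLASSES = (
    "rare-outlier", "redundant", "imprecise",
    "vague", "sibling-variant", "cross-field-violation",
)


class InfeasibleFixtureError(OntoQCError):
    pass


@dataclass(frozen=True)
class LedgerEntry:
    error_class: str
    payload: dict
    expected_detection: str  # "module.operation"


@dataclass
class ErrorLedger:
    """Machine-readable ground truth for one generated fixture."""

    entries: list[LedgerEntry] = field(default_factory=list)
    #: records that are deliberately clean but rule-relevant
    extras: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    detector_params: dict = field(default_factory=dict)

    def by_class(self, error_class: str) -> list[LedgerEntry]:
        return [e for e in self.entries if e.error_class == error_class]

    def expected_sets(self) -> dict[str, set]:
        """Canonical comparison unit per class (see evaluate_against)."""
        out: dict[str, set] = {c: set() for c in ERROR_CLASSES}
        for e in self.entries:
            p = e.payload
            if e.error_class == "rare-outlier":
                out[e.error_class].add(p["term"])
            elif e.error_class == "redundant":
                out[e.error_class].add(
                    (p["ontology_id"], tuple(sorted(p["legacy_terms"]))))
            elif e.error_class == "imprecise":
                out[e.error_class].add(p["legacy_term"])
            elif e.error_class == "vague":
                out[e.error_class].add(p["term"])
            elif e.error_class == "sibling-variant":
                out[e.error_class].add((p["rare_term"], p["common_sibling"]))
            elif e.error_class == "cross-field-violation":
                out[e.error_class].add(p["record_id"])
        return out

    def to_json(self) -> str:
        return json.dumps({
            "params": self.params,
            "detector_params": self.detector_params,
            "entries": [
                {"error_class": e.error_class, "payload": e.payload,
                 "expected_detection": e.expected_detection}
                for e in self.entries
            ],
            "extras": self.extras,
        }, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ErrorLedger":
        data = json.loads(text)
        return cls(
            entries=[LedgerEntry(d["error_class"], d["payload"],
                                 d["expected_detection"])
                     for d in data["entries"]],
            extras=data.get("extras", {}),
            params=data.get("params", {}),
            detector_params=data.get("detector_params", {}),
        )


# ---------------------------------------------------------------------------
# toy ontology

def make_toy_ontology(n_terms: int = 60, depth: int = 3, branching: int = 3,
                      n_shared_synonyms: int = 2, n_ambiguous_synonyms: int = 2,
                      seed: int = 0, n_axioms: int = 0,
                      n_extra_parents: int = 0,
                      out_path: str | Path | None = None,
                      ) -> tuple[OntologyGraph, dict]:
    """Generate a toy ontology with controlled shape and bait synonyms.

    The backbone is a ``branching``-ary tree (heap indexing, so shape
    is fully determined by ``n_terms`` and ``branching``); optional
    extra parents turn it into a proper DAG while preserving
    acyclicity.  ``n_shared_synonyms`` terms get two distinct EXACT
    synonyms each (redundancy bait); ``n_ambiguous_synonyms`` synonym
    strings are attached to two different terms each (imprecision
    bait); ``n_axioms`` terms get a ``has_material_basis_in``
    relationship to a leaf (cross-field rule bait).

    Returns the graph plus a ledger fragment describing the bait, and
    writes byte-deterministic OBO when ``out_path`` is given.
    """
    if n_terms < 1 or n_terms < depth:
        raise InfeasibleFixtureError("n_terms must be >= max(1, depth)")
    if branching < 1:
        raise InfeasibleFixtureError("branching must be >= 1")
    rng = random.Random(seed)
    ids = [f"TOY:{i:07d}" for i in range(1, n_terms + 1)]
    terms: dict[str, OntologyTerm] = {}
    for i, curie in enumerate(ids, start=1):
        parents = [] if i == 1 else [ids[(i - 2) // branching]]
        terms[curie] = OntologyTerm(id=curie, label=f"toy term {i:05d}",
                                    parents=parents)
    graph = OntologyGraph(terms, metadata={"format": "toy", "seed": seed})

    achieved = graph.max_depth()
    if achieved < depth:
        raise InfeasibleFixtureError(
            f"infeasible parameters: depth {depth} requested but "
            f"{n_terms} terms at branching {branching} reach only {achieved}")

    for _ in range(n_extra_parents):
        # child -> any lower-index node stays acyclic (edges always
        # point to strictly smaller heap indices)
        child_i = rng.randrange(branching + 1, n_terms)
        parent_i = rng.randrange(0, max(1, child_i - 1))
        child, parent = ids[child_i], ids[parent_i]
        if parent not in terms[child].parents:
            terms[child].parents.append(parent)
    graph.invalidate()
    graph.check_acyclic()

    pool = ids[1:]  # never bait the root
    need = n_shared_synonyms + 2 * n_ambiguous_synonyms + n_axioms
    if need > len(pool):
        raise InfeasibleFixtureError(
            f"infeasible parameters: {need} bait terms needed, "
            f"{len(pool)} available")
    picked = rng.sample(pool, need)
    it = iter(picked)

    fragment: dict = {"shared_synonyms": [], "ambiguous_synonyms": [],
                      "axioms": []}
    for k in range(n_shared_synonyms):
        t = next(it)
        syns = [f"shared synonym {k:03d} form a",
                f"shared synonym {k:03d} form b"]
        terms[t].synonyms.extend(Synonym(s, SynonymScope.EXACT) for s in syns)
        fragment["shared_synonyms"].append({"term": t, "synonyms": syns})
    for k in range(n_ambiguous_synonyms):
        a, b = next(it), next(it)
        syn = f"ambiguous synonym {k:03d}"
        for t in (a, b):
            terms[t].synonyms.append(Synonym(syn, SynonymScope.EXACT))
        fragment["ambiguous_synonyms"].append({"synonym": syn,
                                               "terms": sorted([a, b])})
    leaves = sorted(t for t in ids if not graph.children_of(t))
    for _ in range(n_axioms):
        trigger = next(it)
        target_pool = [l for l in leaves
                       if l != trigger and l not in picked]
        if not target_pool:
            raise InfeasibleFixtureError("no leaves left for axiom targets")
        target = rng.choice(target_pool)
        terms[trigger].relationships.append(("has_material_basis_in", target))
        fragment["axioms"].append({"trigger": trigger,
                                   "relation": "has_material_basis_in",
                                   "target": target})

    if out_path is not None:
        write_obo(graph, out_path, ontology_name="ontoqc-toy")
    return graph, fragment


# ---------------------------------------------------------------------------
# curated table with injected errors

DEFAULT_ERROR_RATES = {
    "rare-outlier": 0.005,
    "redundant": 0.012,
    "imprecise": 0.006,
    "vague": 0.006,
    "sibling-variant": 0.003,
    "cross-field-violation": 0.005,
}

FIELD_SPEC = {"assay": "legacy-text", "organism": "curie",
              "disease": "curie", "immunogen": "curie"}


def _zipf_counts(total: int, n_bins: int, floor: int) -> list[int]:
    """Deterministic Zipf(1.0) allocation with a per-bin floor."""
    if n_bins <= 0:
        return []
    counts = [floor] * n_bins
    rest = total - floor * n_bins
    if rest < 0:
        raise InfeasibleFixtureError("not enough records for the floor counts")
    weights = [1.0 / r for r in range(1, n_bins + 1)]
    wsum = sum(weights)
    shares = [rest * w / wsum for w in weights]
    extra = [int(math.floor(s)) for s in shares]
    leftovers = rest - sum(extra)
    order = sorted(range(n_bins), key=lambda i: (extra[i] - shares[i], i))
    for i in order[:leftovers]:
        extra[i] += 1
    return [c + e for c, e in zip(counts, extra)]


def _derive_bait(graph: OntologyGraph) -> dict:
    """Recover bait structure from any ontology by inspection."""
    syn_terms: dict[str, list[str]] = {}
    for curie in sorted(graph.terms):
        for syn in graph.terms[curie].synonyms:
            if syn.scope is SynonymScope.EXACT:
                syn_terms.setdefault(syn.text, []).append(curie)
    ambiguous = [{"synonym": s, "terms": sorted(ts)}
                 for s, ts in sorted(syn_terms.items()) if len(ts) >= 2]
    ambiguous_texts = {a["synonym"] for a in ambiguous}
    shared = []
    for curie in sorted(graph.terms):
        texts = [s.text for s in graph.terms[curie].synonyms
                 if s.scope is SynonymScope.EXACT
                 and s.text not in ambiguous_texts]
        if len(texts) >= 2:
            shared.append({"term": curie, "synonyms": texts[:2]})
    axioms = []
    for curie in sorted(graph.terms):
        for rel, tgt in graph.terms[curie].relationships:
            axioms.append({"trigger": curie, "relation": rel, "target": tgt})
    return {"shared_synonyms": shared, "ambiguous_synonyms": ambiguous,
            "axioms": axioms}


def make_curated_table(n_records: int, error_rates: dict[str, float] | None,
                       ontology: OntologyGraph | str | Path, seed: int = 0,
                       out_path: str | Path | None = None,
                       ledger_path: str | Path | None = None,
                       ) -> tuple[CuratedTable, ErrorLedger]:
    """Generate a curated table over an ontology with injected errors.

    ``error_rates`` maps error class -> fraction of records carrying
    that class (defaults: :data:`DEFAULT_ERROR_RATES`); rates must lie
    in [0, 1] and sum to at most 1.  Errors are injected into disjoint
    records.  The returned ledger records every injection and the
    detector parameters under which recovery is exact.
    """
    rates = dict(DEFAULT_ERROR_RATES if error_rates is None else error_rates)
    for c in rates:
        if c not in ERROR_CLASSES:
            raise ValueError(f"unknown error class: {c}")
        if not 0 <= rates[c] <= 1:
            raise ValueError(f"rate for {c} out of [0,1]")
    if sum(rates.values()) > 1:
        raise ValueError("error rates sum to more than 1")
    graph = ontology if isinstance(ontology, OntologyGraph) else load_obo(ontology)
    if not len(graph):
        raise InfeasibleFixtureError("empty ontology")
    rng = random.Random(seed)
    bait = _derive_bait(graph)

    k = {c: int(round(rates.get(c, 0.0) * n_records)) for c in ERROR_CLASSES}
    floor = max(DEFAULT_MIN_COUNT,
                math.ceil(DEFAULT_MIN_FRACTION * n_records))
    ratio = DEFAULT_SIBLING_RATIO

    leaves = sorted(t for t in graph.terms
                    if not graph.children_of(t) and not graph.terms[t].obsolete)
    roots = graph.roots
    internal = sorted(t for t in graph.terms
                      if graph.children_of(t) and t not in roots)
    if not leaves or not internal:
        raise InfeasibleFixtureError("ontology too shallow for fixtures")

    reserved: set[str] = set()   # terms background usage must avoid
    records: list[dict] = []     # {"assay","organism","disease","immunogen","_class"}
    entries: list[LedgerEntry] = []

    def blank(cls: str = "") -> dict:
        return {"assay": "", "organism": "", "disease": "", "immunogen": "",
                "_class": cls}

    # -- rare-outlier: singleton typo strings in the legacy assay field
    typos = [f"legacy typo {seed:04d}-{j:03d}" for j in range(k["rare-outlier"])]
    for t in typos:
        rec = blank("rare-outlier")
        rec["assay"] = t
        records.append(rec)
        entries.append(LedgerEntry("rare-outlier", {"term": t, "field": "assay"},
                                   "census.flag_rare_terms"))

    # -- redundant: both EXACT synonyms of a shared-synonym term in use
    n_clusters = 0 if k["redundant"] == 0 else max(1, k["redundant"] // (2 * floor))
    if n_clusters > len(bait["shared_synonyms"]):
        raise InfeasibleFixtureError(
            f"need {n_clusters} shared-synonym bait terms, ontology has "
            f"{len(bait['shared_synonyms'])}")
    for b in bait["shared_synonyms"][:n_clusters]:
        for syn in b["synonyms"][:2]:
            for _ in range(floor):
                rec = blank("redundant")
                rec["assay"] = syn
                records.append(rec)
        entries.append(LedgerEntry(
            "redundant",
            {"ontology_id": b["term"], "legacy_terms": sorted(b["synonyms"][:2])},
            "mapper.detect_redundancy"))

    # -- imprecise: legacy strings that match two ontology terms
    n_amb = 0 if k["imprecise"] == 0 else max(1, k["imprecise"] // floor)
    if n_amb > len(bait["ambiguous_synonyms"]):
        raise InfeasibleFixtureError(
            f"need {n_amb} ambiguous-synonym baits, ontology has "
            f"{len(bait['ambiguous_synonyms'])}")
    for b in bait["ambiguous_synonyms"][:n_amb]:
        for _ in range(floor):
            rec = blank("imprecise")
            rec["assay"] = b["synonym"]
            records.append(rec)
        entries.append(LedgerEntry(
            "imprecise", {"legacy_term": b["synonym"], "terms": b["terms"]},
            "mapper.detect_imprecision"))

    # -- vague: usage of internal (non-leaf) organism terms.  Baits are
    # depth-1 internal nodes so their used siblings are other baits
    # with comparable counts (no accidental sibling-variant flags).
    depth1_internal = [t for t in internal
                       if any(p in roots for p in graph.parents_of(t))]
    n_vague = 0 if k["vague"] == 0 else min(
        len(depth1_internal), max(1, k["vague"] // floor))
    if k["vague"] > 0 and not depth1_internal:
        raise InfeasibleFixtureError("no internal nodes for vague baits")
    vague_baits = depth1_internal[:n_vague]
    for j, b in enumerate(vague_baits):
        per = max(floor, k["vague"] // n_vague + (1 if j < k["vague"] % n_vague
                                                  else 0))
        reserved.add(b)
        for _ in range(per):
            rec = blank("vague")
            rec["organism"] = b
            records.append(rec)
        entries.append(LedgerEntry(
            "vague", {"term": b, "count": per}, "pruner.flag_vague_usage"))

    # -- sibling-variant: a rare leaf next to a dominant sibling leaf.
    sibling_common = sibling_rare = None
    rare_count = common_count = 0
    if k["sibling-variant"] > 0:
        parent = next(
            (p for p in internal
             if p not in vague_baits
             and len(graph.children_of(p)) >= 2
             and all(not graph.children_of(c) for c in graph.children_of(p))),
            None)
        if parent is None:
            raise InfeasibleFixtureError("no all-leaf sibling group available")
        kids = graph.children_of(parent)
        sibling_common, sibling_rare = kids[0], kids[1]
        reserved |= set(kids)  # background must not touch this family
        rare_count = max(floor, k["sibling-variant"])
        common_count = int(math.ceil(rare_count / ratio)) + 1
        for _ in range(rare_count):
            rec = blank("sibling-variant")
            rec["organism"] = sibling_rare
            records.append(rec)
        entries.append(LedgerEntry(
            "sibling-variant",
            {"rare_term": sibling_rare, "common_sibling": sibling_common,
             "rare_count": rare_count, "common_count": common_count},
            "pruner.flag_rare_sibling_variants"))

    # -- cross-field: records violating a relationship axiom, plus
    # clean trigger records and empty-required records (autofill bait)
    autofill_expected: list[dict] = []
    n_cross = k["cross-field-violation"]
    if n_cross > 0:
        if not bait["axioms"]:
            raise InfeasibleFixtureError("no relationship axioms for "
                                         "cross-field injection")
        axiom = bait["axioms"][0]
        target = axiom["target"]
        ok = {target} | graph.descendants(target)
        wrong_pool = [l for l in leaves if l not in ok and l != axiom["trigger"]]
        if not wrong_pool:
            raise InfeasibleFixtureError("no wrong-value leaf available")
        wrong = wrong_pool[0]
        for _ in range(max(floor, n_cross)):
            rec = blank("cross-field-violation")
            rec["disease"], rec["immunogen"] = axiom["trigger"], wrong
            records.append(rec)
        for _ in range(floor):  # clean trigger records (must not flag)
            rec = blank("clean-trigger")
            rec["disease"], rec["immunogen"] = axiom["trigger"], target
            records.append(rec)
        for _ in range(floor):  # empty required field -> autofill bait
            rec = blank("autofill")
            rec["disease"] = axiom["trigger"]
            records.append(rec)
            autofill_expected.append({"field": "immunogen",
                                      "suggested": target,
                                      "trigger": axiom["trigger"]})

    # -- background: Zipf-skewed usage over unreserved leaves ----------
    n_background = n_records - len(records) - common_count
    if n_background < floor:
        raise InfeasibleFixtureError(
            "error rates leave too few records for background usage")
    bg_leaves = [l for l in leaves if l not in reserved]
    n_bg = min(len(bg_leaves), max(1, n_background // (3 * floor)))
    bg_counts = _zipf_counts(n_background, n_bg, floor)
    organism_stream: list[str] = []
    if sibling_common is not None:
        organism_stream += [sibling_common] * common_count
    for leaf, c in zip(bg_leaves, bg_counts):
        organism_stream += [leaf] * c
    for org in organism_stream:
        rec = blank("background")
        rec["organism"] = org
        records.append(rec)

    # assay background: labels of background leaves, round-robin so
    # every background legacy string clears the rare thresholds
    bg_assay_slots = [r for r in records
                      if r["_class"] not in ("rare-outlier", "redundant",
                                             "imprecise")]
    n_assay = min(8, max(1, len(bg_assay_slots) // (2 * floor)))
    assay_bait_terms = ({b["term"] for b in bait["shared_synonyms"]}
                        | {t for b in bait["ambiguous_synonyms"]
                           for t in b["terms"]})
    assay_pool = [l for l in bg_leaves if l not in assay_bait_terms] or leaves
    assay_labels = [graph.terms[l].label for l in assay_pool[:n_assay]]
    for i, rec in enumerate(bg_assay_slots):
        rec["assay"] = assay_labels[i % len(assay_labels)]

    # organism for records that still lack one (assay-error records):
    # recycle the background stream so no new rare organism appears
    fill = [r for r in records if not r["organism"]]
    src = organism_stream or [bg_leaves[0]] * len(fill)
    for i, rec in enumerate(fill):
        rec["organism"] = src[i % len(src)]

    rng.shuffle(records)
    ids = [f"r{i:05d}" for i in range(1, len(records) + 1)]
    for rid, rec in zip(ids, records):
        rec["record_id"] = rid
    # per-record entries for cross-field violations and autofill
    for rec in records:
        if rec["_class"] == "cross-field-violation":
            entries.append(LedgerEntry(
                "cross-field-violation",
                {"record_id": rec["record_id"], "trigger": rec["disease"],
                 "observed": rec["immunogen"]},
                "validator.validate"))
    autofill_records = [
        {"record_id": rec["record_id"], "field": "immunogen",
         "suggested": autofill_expected[0]["suggested"]}
        for rec in records if rec["_class"] == "autofill"
    ] if autofill_expected else []

    df = pd.DataFrame(
        [{c: rec[c] for c in ("record_id", "assay", "organism",
                              "disease", "immunogen")}
         for rec in records])
    table = CuratedTable(df=df, field_spec=dict(FIELD_SPEC),
                         provenance="generated", id_field="record_id")
    ledger = ErrorLedger(
        entries=entries,
        extras={
            "autofill_records": autofill_records,
            "clean_trigger_records": [rec["record_id"] for rec in records
                                      if rec["_class"] == "clean-trigger"],
            "class_of_record": {rec["record_id"]: rec["_class"]
                                for rec in records
                                if rec["_class"] != "background"},
        },
        params={"n_records": len(records), "error_rates": rates, "seed": seed,
                "zipf_exponent": 1.0, "floor": floor},
        detector_params={"min_count": DEFAULT_MIN_COUNT,
                         "min_fraction": DEFAULT_MIN_FRACTION,
                         "sibling_ratio": ratio,
                         "census_fields": ["assay", "organism"],
                         "map_fields": ["assay"],
                         "prune_fields": ["organism"]},
    )
    if out_path is not None:
        table.write(out_path)
    if ledger_path is not None:
        Path(ledger_path).write_text(ledger.to_json(), encoding="utf-8")
    return table, ledger


def make_bundle(out_dir: str | Path, n_records: int = 1000,
                error_rates: dict[str, float] | None = None,
                seed: int = 0, n_terms: int = 120, depth: int = 3,
                branching: int = 3) -> dict:
    """Write a self-contained fixture bundle: ontology, table, ledger
    and a ready-to-run pipeline config.  Returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph, _ = make_toy_ontology(
        n_terms=n_terms, depth=depth, branching=branching,
        n_shared_synonyms=6, n_ambiguous_synonyms=6, n_axioms=3,
        seed=seed, out_path=out / "toy.obo")
    _, ledger = make_curated_table(
        n_records, error_rates, graph, seed=seed,
        out_path=out / "table.tsv", ledger_path=out / "ledger.json")
    config = {
        "ontologies": {"toy": "toy.obo"},
        "table": "table.tsv",
        "id_field": "record_id",
        "fields": {
            "assay": {"kind": "legacy-text", "ontology": "toy"},
            "organism": {"kind": "curie", "ontology": "toy"},
            "disease": {"kind": "curie", "ontology": "toy"},
            "immunogen": {"kind": "curie", "ontology": "toy"},
        },
        "census_fields": ["assay", "organism"],
        "map_fields": ["assay"],
        "prune_fields": ["organism"],
        "thresholds": dict(ledger.detector_params),
        "rules": {
            "trigger_field": "disease", "required_field": "immunogen",
            "trigger_ontology": "toy", "required_ontology": "toy",
            "relations": ["has_material_basis_in"],
        },
    }
    (out / "config.yaml").write_text(
        yaml.safe_dump(config, sort_keys=True), encoding="utf-8")
    return {"ontology": out / "toy.obo", "table": out / "table.tsv",
            "ledger": out / "ledger.json", "config": out / "config.yaml"}


# ---------------------------------------------------------------------------
# hand-built worked-example bundle

_CYTOKINE_OBO = """\
format-version: 1.2
ontology: ontoqc-cytokine-demo

[Term]
id: OBI:0000070
name: assay

[Term]
id: OBI:0001378
name: CCL4 release assay
synonym: "CCL4" EXACT []
synonym: "MIP1b" EXACT []
is_a: OBI:0000070

[Term]
id: OBI:0001745
name: IL-1alpha release assay
synonym: "IL-1a" EXACT []
synonym: "IL-1" EXACT []
is_a: OBI:0000070

[Term]
id: OBI:0001842
name: IL-1beta release assay
synonym: "IL-1b" EXACT []
synonym: "IL-1" EXACT []
is_a: OBI:0000070
"""

_NCBI_NODES = """\
1\t|\t1\t|\tno rank\t|
10088\t|\t1\t|\tgenus\t|
10090\t|\t10088\t|\tspecies\t|
10095\t|\t10088\t|\tspecies\t|
10239\t|\t1\t|\tsuperkingdom\t|
10368\t|\t10239\t|\tspecies\t|
32603\t|\t10368\t|\tno rank\t|
32604\t|\t10368\t|\tno rank\t|
"""

_NCBI_NAMES = """\
1\t|\troot\t|\t\t|\tscientific name\t|
10088\t|\tMus\t|\t\t|\tscientific name\t|
10088\t|\tmice\t|\t\t|\tgenbank common name\t|
10090\t|\tMus musculus\t|\t\t|\tscientific name\t|
10090\t|\tmouse\t|\t\t|\tgenbank common name\t|
10095\t|\tMus sp.\t|\t\t|\tscientific name\t|
10239\t|\tViruses\t|\t\t|\tscientific name\t|
10368\t|\tHuman herpesvirus 6\t|\t\t|\tscientific name\t|
10368\t|\tHHV-6\t|\t\t|\tsynonym\t|
32603\t|\tHuman betaherpesvirus 6A\t|\t\t|\tscientific name\t|
32604\t|\tHuman betaherpesvirus 6B\t|\t\t|\tscientific name\t|
"""

_DO_SLICE_OBO = """\
format-version: 1.2
ontology: ontoqc-disease-demo

[Term]
id: DOID:0050117
name: disease by infectious agent

[Term]
id: DOID:934
name: viral infectious disease
is_a: DOID:0050117

[Term]
id: DOID:12205
name: dengue disease
is_a: DOID:934
relationship: has_material_basis_in NCBITaxon:12637

[Term]
id: DOID:12206
name: dengue hemorrhagic fever
is_a: DOID:12205
"""

_AGENTS_OBO = """\
format-version: 1.2
ontology: ontoqc-agents-demo

[Term]
id: NCBITaxon:10239
name: Viruses

[Term]
id: NCBITaxon:12637
name: Dengue virus
is_a: NCBITaxon:10239

[Term]
id: NCBITaxon:11053
name: Dengue virus 1
is_a: NCBITaxon:12637

[Term]
id: NCBITaxon:11676
name: Human immunodeficiency virus 1
is_a: NCBITaxon:10239
"""

_ASSAY_GROUPS_OBO = """\
format-version: 1.2
ontology: ontoqc-assay-groups-demo

[Term]
id: OBI:0000070
name: assay

[Term]
id: OBI:1110180
name: correlates of protection assay
is_a: OBI:0000070

[Term]
id: OBI:1110181
name: neutralization assay
is_a: OBI:1110180

[Term]
id: OBI:1110182
name: cytotoxicity assay
is_a: OBI:1110180

[Term]
id: OBI:1110190
name: in vivo protection assay
is_a: OBI:0000070

[Term]
id: OBI:1110191
name: protection from viral challenge assay
is_a: OBI:1110190
"""

_DEMO_ROWS = [
    # record_id, assay, organism, disease, immunogen
    ("r01", "CCL4", "NCBITaxon:10368", "", ""),
    ("r02", "CCL4", "NCBITaxon:10368", "", ""),
    ("r03", "CCL4", "NCBITaxon:10368", "", ""),
    ("r04", "MIP1b", "NCBITaxon:10090", "", ""),
    ("r05", "MIP1b", "NCBITaxon:10090", "", ""),
    ("r06", "MIP1b", "NCBITaxon:10090", "", ""),
    ("r07", "IL-1", "NCBITaxon:10090", "", ""),
    ("r08", "IL-1", "NCBITaxon:10090", "", ""),
    ("r09", "IL-1", "NCBITaxon:10090", "", ""),
    ("r10", "CCL4", "NCBITaxon:10090", "DOID:12205", "NCBITaxon:12637"),
    ("r11", "CCL4", "NCBITaxon:10090", "DOID:12205", "NCBITaxon:11676"),
    ("r12", "CCL4", "NCBITaxon:10090", "DOID:12205", ""),
    ("r13", "CCL4", "NCBITaxon:10090", "", "NCBITaxon:11676"),
    ("r14", "CCL4", "NCBITaxon:10090", "DOID:12206", "NCBITaxon:11053"),
    ("r15", "MIP1b", "NCBITaxon:10090", "", ""),
]


def demo_bundle(out_dir: str | Path) -> dict:
    """Write the hand-built worked-example bundle.

    Contents: a cytokine-assay OBO slice whose synonyms reproduce the
    classic redundancy (CCL4/MIP1b -> one assay term) and imprecision
    (IL-1 -> IL-1α or IL-1β assay) patterns; a tiny NCBI-style
    taxonomy dump with the Mus and herpesvirus-6 families; a disease
    slice whose dengue term carries a has_material_basis_in axiom; a
    matching agents slice; a Finder demo ontology with two disjoint
    protection-assay groups; a 15-record curated table exercising all
    of it; and a pipeline config plus expected-flag ledger.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "cytokine.obo").write_text(_CYTOKINE_OBO, encoding="utf-8")
    (out / "ncbi_nodes.dmp").write_text(_NCBI_NODES, encoding="utf-8")
    (out / "ncbi_names.dmp").write_text(_NCBI_NAMES, encoding="utf-8")
    (out / "do_slice.obo").write_text(_DO_SLICE_OBO, encoding="utf-8")
    (out / "agents.obo").write_text(_AGENTS_OBO, encoding="utf-8")
    (out / "assay_groups.obo").write_text(_ASSAY_GROUPS_OBO, encoding="utf-8")
    df = pd.DataFrame(_DEMO_ROWS, columns=["record_id", "assay", "organism",
                                           "disease", "immunogen"])
    df.to_csv(out / "demo_table.tsv", sep="\t", index=False)

    ledger = ErrorLedger(
        entries=[
            LedgerEntry("redundant",
                        {"ontology_id": "OBI:0001378",
                         "legacy_terms": ["CCL4", "MIP1b"]},
                        "mapper.detect_redundancy"),
            LedgerEntry("imprecise",
                        {"legacy_term": "IL-1",
                         "terms": ["OBI:0001745", "OBI:0001842"]},
                        "mapper.detect_imprecision"),
            LedgerEntry("vague",
                        {"term": "NCBITaxon:10368", "count": 3},
                        "pruner.flag_vague_usage"),
            LedgerEntry("cross-field-violation",
                        {"record_id": "r11", "trigger": "DOID:12205",
                         "observed": "NCBITaxon:11676"},
                        "validator.validate"),
        ],
        extras={"autofill_records": [
            {"record_id": "r12", "field": "immunogen",
             "suggested": "NCBITaxon:12637"}]},
        params={"bundle": "demo", "n_records": len(_DEMO_ROWS)},
        detector_params={"min_count": DEFAULT_MIN_COUNT,
                         "min_fraction": DEFAULT_MIN_FRACTION,
                         "sibling_ratio": DEFAULT_SIBLING_RATIO},
    )
    (out / "ledger.json").write_text(ledger.to_json(), encoding="utf-8")

    config = {
        "ontologies": {
            "assays": "cytokine.obo",
            "taxa": {"nodes": "ncbi_nodes.dmp", "names": "ncbi_names.dmp"},
            "diseases": "do_slice.obo",
            "agents": "agents.obo",
        },
        "table": "demo_table.tsv",
        "id_field": "record_id",
        "fields": {
            "assay": {"kind": "legacy-text", "ontology": "assays"},
            "organism": {"kind": "curie", "ontology": "taxa"},
            "disease": {"kind": "curie", "ontology": "diseases"},
            "immunogen": {"kind": "curie", "ontology": "agents"},
        },
        "census_fields": ["assay", "organism"],
        "map_fields": ["assay"],
        "prune_fields": ["organism"],
        "rules": {
            "trigger_field": "disease", "required_field": "immunogen",
            "trigger_ontology": "diseases", "required_ontology": "agents",
            "relations": ["has_material_basis_in"],
        },
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True),
                                     encoding="utf-8")
    return {name: out / fname for name, fname in [
        ("cytokine", "cytokine.obo"), ("nodes", "ncbi_nodes.dmp"),
        ("names", "ncbi_names.dmp"), ("do_slice", "do_slice.obo"),
        ("agents", "agents.obo"), ("assay_groups", "assay_groups.obo"),
        ("table", "demo_table.tsv"), ("ledger", "ledger.json"),
        ("config", "config.yaml")]}
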