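"""Map legacy flat-list terms onto ontology terms via labels and synonyms.

Home-made controlled vocabularies accumulate two characteristic error
classes once you line them up against a formal ontology:

* **redundancy** — several legacy terms denote the same concept and
  land on one ontology term (classic case: cytokine assays named after
  different-era synonyms of the same cytokine, e.g. CCL4 vs MIP1b);
* **imprecision** — one legacy term is too vague to land anywhere
  unique (e.g. "IL-1", which matches both an IL-1α and an IL-1β assay).

Matching is synonym-driven and exact-first.  Normalized matching (case,
punctuation, Greek letters) is a separate fallback tier so an exact hit
is never diluted; fuzzy matching is strictly opt-in and reported with
its similarity score.  Ambiguity is never auto-resolved — resolving it
requires re-reading the underlying publications, which is curator work.
"""

from __future__ import annotations

import csv
import difflib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .model import OntologyGraph, SynonymScope

#: Greek letters commonly embedded in biological term names.
_GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "π": "pi", "ρ": "rho",
    "σ": "sigma", "τ": "tau", "φ": "phi", "χ": "chi", "ψ": "psi", "ω": "omega",
}
_SEPARATORS = re.compile(r"[-_/]+")
_PUNCT = re.compile(r"[^\w\s]", flags=re.UNICODE)
_WS = re.compile(r"\s+")

DEFAULT_SCOPES = frozenset({SynonymScope.EXACT})


def normalize_label(text: str) -> str:
    """Normalize a term string for tolerant matching.

    Case-folds, transliterates Greek letters (α→alpha, β→beta, ...),
    turns ``-``, ``_`` and ``/`` into spaces, strips other punctuation
    and collapses whitespace.  Idempotent.
    """
    out = text.casefold()
    for greek, latin in _GREEK.items():
        out = out.replace(greek, latin)
    out = _SEPARATORS.sub(" ", out)
    out = _PUNCT.sub("", out)
    return _WS.sub(" ", out).strip()


@dataclass(frozen=True)
class Candidate:
    ontology_id: str
    matched_text: str
    match_kind: str  # label | exact-synonym | scoped-synonym | normalized | curated | fuzzy
    score: float = 1.0


@dataclass
class MappingRecord:
    """One legacy term's candidate matches, with provenance and status."""

    legacy_term: str
    candidates: list[Candidate] = field(default_factory=list)
    status: str = "unmapped"  # unique | ambiguous | unmapped
    note: str = ""

    def finalize(self) -> "MappingRecord":
        n = len(self.candidates)
        self.status = "unmapped" if n == 0 else "unique" if n == 1 else "ambiguous"
        return self


@dataclass(frozen=True)
class RedundancyCluster:
    """Several legacy terms that all map uniquely to one ontology term."""

    ontology_id: str
    legacy_terms: frozenset[str]

    def __len__(self) -> int:
        return len(self.legacy_terms)


class TermIndex:
    """Label/synonym lookup tables for one graph, built once.

    Obsolete terms are indexed so hits on them can be redirected via
    ``replaced_by`` (and flagged), but they are never candidates
    themselves.
    """

    def __init__(self, graph: OntologyGraph,
                 scopes: Iterable[SynonymScope] = DEFAULT_SCOPES):
        self.graph = graph
        self.scopes = frozenset(scopes)
        self.exact: dict[str, list[Candidate]] = {}
        self.normalized: dict[str, list[Candidate]] = {}
        for curie in sorted(graph.terms):
            term = graph.terms[curie]
            entries = [(term.label, "label")] if term.label else []
            for syn in term.synonyms:
                if syn.scope in self.scopes:
                    kind = ("exact-synonym" if syn.scope is SynonymScope.EXACT
                            else "scoped-synonym")
                    entries.append((syn.text, kind))
            for text, kind in entries:
                cand = Candidate(curie, text, kind)
                self.exact.setdefault(text, []).append(cand)
                self.normalized.setdefault(normalize_label(text), []).append(
                    Candidate(curie, text, "normalized"))


def _resolve_obsolete(cands: list[Candidate], graph: OntologyGraph,
                      notes: list[str]) -> list[Candidate]:
    out: list[Candidate] = []
    for c in cands:
        term = graph.terms.get(c.ontology_id)
        if term is not None and term.obsolete:
            if term.replaced_by and term.replaced_by in graph:
                notes.append(
                    f"obsolete {c.ontology_id} replaced by {term.replaced_by}")
                out.append(Candidate(term.replaced_by, c.matched_text,
                                     c.match_kind, c.score))
            else:
                notes.append(f"obsolete {c.ontology_id} dropped (no replacement)")
        else:
            out.append(c)
    # dedupe by target id, keeping the first (highest-priority) provenance
    seen: set[str] = set()
    deduped = []
    for c in out:
        if c.ontology_id not in seen:
            seen.add(c.ontology_id)
            deduped.append(c)
    return deduped


def map_term(legacy: str, graph: OntologyGraph | TermIndex,
             scopes: Iterable[SynonymScope] = DEFAULT_SCOPES,
             curated_overrides: Mapping[str, str] | None = None,
             fuzzy_cutoff: float | None = None) -> MappingRecord:
    """Map one legacy term to ontology candidates.

    Tiers, in order and never merged: curated override; exact string
    match on labels + trusted-scope synonyms; normalized match; fuzzy
    match (only if ``fuzzy_cutoff`` is given, reported with score).
    Status follows the candidate count: 1 → unique, ≥2 → ambiguous,
    0 → unmapped.
    """
    index = graph if isinstance(graph, TermIndex) else TermIndex(graph, scopes)
    notes: list[str] = []

    if curated_overrides and legacy in curated_overrides:
        target = curated_overrides[legacy]
        cands = _resolve_obsolete(
            [Candidate(target, legacy, "curated")], index.graph, notes)
        return MappingRecord(legacy, cands, note="; ".join(notes)).finalize()

    cands = _resolve_obsolete(list(index.exact.get(legacy, [])),
                              index.graph, notes)
    if not cands:
        cands = _resolve_obsolete(
            list(index.normalized.get(normalize_label(legacy), [])),
            index.graph, notes)
    if not cands and fuzzy_cutoff is not None:
        key = normalize_label(legacy)
        close = difflib.get_close_matches(key, index.normalized.keys(),
                                          n=5, cutoff=fuzzy_cutoff)
        fuzzy = []
        for match in close:
            score = difflib.SequenceMatcher(None, key, match).ratio()
            for c in index.normalized[match]:
                fuzzy.append(Candidate(c.ontology_id, c.matched_text,
                                       "fuzzy", round(score, 4)))
        cands = _resolve_obsolete(fuzzy, index.graph, notes)

    rec = MappingRecord(legacy, cands, note="; ".join(notes))
    return rec.finalize()


def map_all(legacy_terms: Iterable[str], graph: OntologyGraph,
            scopes: Iterable[SynonymScope] = DEFAULT_SCOPES,
            curated_overrides: Mapping[str, str] | None = None,
            fuzzy_cutoff: float | None = None) -> list[MappingRecord]:
    """Map a whole legacy vocabulary; deterministic lexicographic order."""
    index = TermIndex(graph, scopes)
    return [
        map_term(term, index, scopes, curated_overrides, fuzzy_cutoff)
        for term in sorted(set(legacy_terms))
    ]


def detect_redundancy(mappings: Iterable[MappingRecord]) -> list[RedundancyCluster]:
    """Group uniquely-mapped legacy terms by target; keep groups of ≥2.

    Each cluster is a set of legacy terms that all denote the same
    ontology concept — the many-to-one error class.  Sorted by cluster
    size descending, then by ontology id.
    """
    by_target: dict[str, set[str]] = {}
    for rec in mappings:
        if rec.status == "unique":
            by_target.setdefault(rec.candidates[0].ontology_id, set()).add(
                rec.legacy_term)
    clusters = [
        RedundancyCluster(oid, frozenset(terms))
        for oid, terms in by_target.items() if len(terms) >= 2
    ]
    clusters.sort(key=lambda c: (-len(c), c.ontology_id))
    return clusters


def detect_imprecision(mappings: Iterable[MappingRecord]) -> list[MappingRecord]:
    """The one-to-many error class: records too vague to map uniquely.

    Every returned record carries all its candidates so a curator can
    go back to the original publications; nothing is auto-picked.
    """
    return [rec for rec in mappings if rec.status == "ambiguous"]


# ---------------------------------------------------------------------------
# TSV round-trips

_MAPPING_COLUMNS = ["legacy_term", "status", "candidates", "match_kinds",
                    "matched_texts", "note"]


def write_mappings(mappings: Iterable[MappingRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_MAPPING_COLUMNS)
        for rec in mappings:
            w.writerow([
                rec.legacy_term, rec.status,
                "|".join(c.ontology_id for c in rec.candidates),
                "|".join(c.match_kind for c in rec.candidates),
                "|".join(c.matched_text for c in rec.candidates),
                rec.note,
            ])


def read_mappings(path: str | Path) -> list[MappingRecord]:
    out: list[MappingRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            ids = row["candidates"].split("|") if row["candidates"] else []
            kinds = row["match_kinds"].split("|") if row["match_kinds"] else []
            texts = row["matched_texts"].split("|") if row["matched_texts"] else []
            cands = [Candidate(i, t, k) for i, t, k in zip(ids, texts, kinds)]
            out.append(MappingRecord(row["legacy_term"], cands,
                                     row["status"], row["note"]))
    return out


def write_clusters(clusters: Iterable[RedundancyCluster], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["ontology_id", "size", "legacy_terms"])
        for c in clusters:
            w.writerow([c.ontology_id, len(c), "|".join(sorted(c.legacy_terms))])
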