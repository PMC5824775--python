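"""Application-specific pruned views of a large ontology.

A curated database typically uses a tiny fraction of a reference
hierarchy such as the NCBI taxonomy.  Pruning keeps exactly the used
terms plus their full is_a ancestry — an ancestrally closed subgraph —
so browse trees stay small while every used term keeps its path to a
root.  The pruned view doubles as an error detector:

* **vague usage** — a non-leaf term was used although more specific
  descendants exist (strong signal when descendants are themselves
  used; weak/advisory when they are merely available, as when Human
  herpesvirus 6 is curated instead of its A/B species);
* **sibling variants** — a rarely used term sitting next to a heavily
  used sibling (Mus sp. next to Mus musculus): not a true error, but
  it fragments grouping, so it is flagged as advisory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from pydantic import BaseModel

from .model import OntologyGraph, OntoQCError

DEFAULT_SIBLING_RATIO = 0.01


class PruneError(OntoQCError):
    def __init__(self, missing: list[str]):
        self.missing = sorted(missing)
        super().__init__(
            "used terms absent from the ontology (possible curation errors): "
            + ", ".join(self.missing))


@dataclass
class PrunedView:
    """Ancestrally closed subgraph covering exactly the used terms.

    ``usage`` carries the per-term counts through; ancestor-only nodes
    have count 0.
    """

    kept: set[str]
    edges: set[tuple[str, str]]  # (child, parent), both kept
    usage: dict[str, int]

    def roots(self, graph: OntologyGraph) -> list[str]:
        kept_parents = {c: [p for p in graph.parents_of(c) if p in self.kept]
                        for c in self.kept}
        return sorted(c for c, ps in kept_parents.items() if not ps)

    def used(self) -> set[str]:
        return {t for t, c in self.usage.items() if c > 0}


def prune(graph: OntologyGraph, usage: Mapping[str, int]) -> PrunedView:
    """Keep the used terms plus all their is_a ancestors.

    Terms with zero recorded usage are treated as unused.  A used CURIE
    missing from the graph raises :class:`PruneError` listing all
    offenders — that situation is itself a curation-error signal.
    """
    used = {t for t, c in usage.items() if c > 0}
    missing = [t for t in used if t not in graph]
    if missing:
        raise PruneError(missing)
    kept = set(used)
    for t in used:
        kept |= graph.ancestors(t)
    edges = {
        (child, parent)
        for child in kept
        for parent in graph.parents_of(child)
        if parent in kept
    }
    return PrunedView(kept=kept, edges=edges,
                      usage={t: usage.get(t, 0) for t in kept})


@dataclass(frozen=True)
class VagueUsageFlag:
    term: str
    used_descendants: tuple[str, ...]       # strong evidence
    available_descendants: tuple[str, ...]  # weak evidence
    count: int
    error_class: str = "vague"

    @property
    def signal(self) -> str:
        return "strong" if self.used_descendants else "weak"


def flag_vague_usage(view: PrunedView, graph: OntologyGraph) -> list[VagueUsageFlag]:
    """Flag every used term that has descendants in the full ontology.

    Leaves are never flagged.  Used descendants and merely-available
    descendants are reported separately: a used descendant means the
    dataset itself demonstrates a finer term was applicable.
    """
    used = view.used()
    flags = []
    for term in sorted(used):
        desc = graph.descendants(term)
        if not desc:
            continue
        flags.append(VagueUsageFlag(
            term=term,
            used_descendants=tuple(sorted(desc & used)),
            available_descendants=tuple(sorted(desc - used)),
            count=view.usage.get(term, 0),
        ))
    return flags


@dataclass(frozen=True)
class SiblingVariantFlag:
    rare_term: str
    common_sibling: str
    rare_count: int
    common_count: int
    error_class: str = "sibling-variant"
    severity: str = "advisory"


def flag_rare_sibling_variants(view: PrunedView, graph: OntologyGraph,
                               ratio_threshold: float = DEFAULT_SIBLING_RATIO,
                               ) -> list[SiblingVariantFlag]:
    """Flag used terms dwarfed by a sibling under the same is_a parent.

    A used term ``r`` is flagged when some used sibling ``s`` satisfies
    ``count(r)/count(s) < ratio_threshold``; the flag names the
    highest-count such sibling.  Advisory severity: the usage is not
    wrong per se, but aligning it with the dominant sibling lets
    related records group together.
    """
    if not 0 < ratio_threshold < 1:
        raise ValueError("ratio_threshold must be in (0, 1)")
    used = view.used()
    flags = []
    for rare in sorted(used):
        siblings: set[str] = set()
        for parent in graph.parents_of(rare):
            siblings |= set(graph.children_of(parent))
        siblings.discard(rare)
        used_sibs = [s for s in siblings if s in used]
        if not used_sibs:
            continue
        common = max(used_sibs, key=lambda s: (view.usage[s], s))
        if view.usage[rare] / view.usage[common] < ratio_threshold:
            flags.append(SiblingVariantFlag(
                rare_term=rare, common_sibling=common,
                rare_count=view.usage[rare],
                common_count=view.usage[common]))
    return flags


# ---------------------------------------------------------------------------
# Finder tree export

class FinderNode(BaseModel):
    id: str
    label: str
    count: int
    repeat: bool = False
    children: list["FinderNode"] = []


class FinderTree(BaseModel):
    meta: dict
    roots: list[FinderNode]


FINDER_SCHEMA_PATH = Path(__file__).parent / "finder_tree.schema.json"


def export_finder_tree(view: PrunedView, graph: OntologyGraph,
                       meta: dict | None = None) -> dict:
    """Render a pruned view as a nested browse tree ("Finder").

    Children are sorted lexicographically by label (then id).  A DAG
    node with several kept parents appears under each of them; repeat
    appearances carry ``repeat: true`` and omit their children so the
    document stays linear in the view size.  Output is validated
    against the shipped schema and is byte-deterministic.
    """
    children_of: dict[str, list[str]] = {k: [] for k in view.kept}
    for child, parent in view.edges:
        children_of[parent].append(child)

    def label(c: str) -> str:
        return graph.terms[c].label if c in graph else c

    emitted: set[str] = set()

    def build(curie: str) -> FinderNode:
        first = curie not in emitted
        emitted.add(curie)
        kids = sorted(children_of[curie], key=lambda c: (label(c), c))
        return FinderNode(
            id=curie, label=label(curie), count=view.usage.get(curie, 0),
            repeat=not first,
            children=[build(k) for k in kids] if first else [],
        )

    tree = FinderTree(
        meta={"node_count": len(view.kept), **(meta or {})},
        roots=[build(r) for r in view.roots(graph)],
    )
    return tree.model_dump()


def finder_tree_json(tree: dict) -> str:
    """Canonical byte-deterministic serialization of a finder tree."""
    FinderTree.model_validate(tree)  # schema check on export
    return json.dumps(tree, indent=1, sort_keys=True, ensure_ascii=False)


def write_finder_schema(path: str | Path = FINDER_SCHEMA_PATH) -> None:
    Path(path).write_text(
        json.dumps(FinderTree.model_json_schema(), indent=2, sort_keys=True),
        encoding="utf-8")


def collapse_single_child_chains(node: dict) -> dict:
    """Display-only pass: fold runs of single-child ancestors into one
    node labelled with the joined path.  Never used in computation."""
    node = dict(node)
    while len(node["children"]) == 1 and node["count"] == 0:
        child = node["children"][0]
        node = {**child, "label": f'{node["label"]} / {child["label"]}'}
    node["children"] = [collapse_single_child_chains(c) for c in node["children"]]
    return node


# ---------------------------------------------------------------------------
# TSV export of the view itself

def write_view(view: PrunedView, graph: OntologyGraph,
               nodes_path: str | Path, edges_path: str | Path,
               params: dict | None = None) -> None:
    header = "# ontoqc pruned view"
    if params:
        blob = json.dumps(params, sort_keys=True)
        digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
        header += f" params={blob} params_hash={digest}"
    with open(nodes_path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        fh.write("id\tlabel\tcount\n")
        for c in sorted(view.kept):
            lbl = graph.terms[c].label if c in graph else ""
            fh.write(f"{c}\t{lbl}\t{view.usage.get(c, 0)}\n")
    with open(edges_path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        fh.write("child\tparent\n")
        for child, parent in sorted(view.edges):
            fh.write(f"{child}\t{parent}\n")
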