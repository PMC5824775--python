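"""Core graph model: terms, scoped synonyms and the is_a DAG.

The model deliberately restricts itself to OBO-graph semantics — an
acyclic ``is_a`` hierarchy plus named (typed) relationships between
terms.  That is sufficient for every detection procedure in this
package (synonym-driven mapping, ancestral-closure pruning,
subsumption-based cross-field validation) and keeps the whole toolkit
testable without a description-logic reasoner.

Multiple ``is_a`` parents are first-class: cell and assay ontologies
are DAGs, never trees, and every algorithm here is defined on DAGs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping


class OntoQCError(Exception):
    """Base class for all errors raised by this package."""


class OboParseError(OntoQCError):
    """Malformed ontology input; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CycleError(OntoQCError):
    """The is_a relation contains a cycle."""

    def __init__(self, cycle: Iterable[str]):
        self.cycle = sorted(set(cycle))
        super().__init__("is_a cycle involving: " + ", ".join(self.cycle))


class DanglingReferenceError(OntoQCError):
    """A parent or relationship target does not resolve (strict mode)."""

    def __init__(self, refs: Iterable[tuple[str, str]]):
        self.refs = sorted(set(refs))
        msg = "; ".join(f"{src} -> {tgt}" for src, tgt in self.refs)
        super().__init__(f"dangling references: {msg}")


class UnknownTermError(OntoQCError, KeyError):
    def __init__(self, curie: str):
        self.curie = curie
        super().__init__(f"unknown term: {curie}")


class SynonymScope(str, Enum):
    """OBO synonym scopes.  RELATED is the default when none is stated."""

    EXACT = "EXACT"
    NARROW = "NARROW"
    BROAD = "BROAD"
    RELATED = "RELATED"


@dataclass(frozen=True)
class Synonym:
    text: str
    scope: SynonymScope = SynonymScope.RELATED


@dataclass
class OntologyTerm:
    """One ontology term: a CURIE, its label, synonyms and placement."""

    id: str
    label: str = ""
    synonyms: list[Synonym] = field(default_factory=list)
    parents: list[str] = field(default_factory=list)
    relationships: list[tuple[str, str]] = field(default_factory=list)
    obsolete: bool = False
    replaced_by: str | None = None
    xrefs: list[str] = field(default_factory=list)

    def synonym_texts(self, scopes: Iterable[SynonymScope] | None = None) -> list[str]:
        wanted = set(scopes) if scopes is not None else set(SynonymScope)
        return [s.text for s in self.synonyms if s.scope in wanted]


class OntologyGraph:
    """In-memory DAG of :class:`OntologyTerm` keyed by CURIE.

    Parent pointers live on the terms; a child index is built lazily.
    Graphs are treated as immutable once loaded — mutate ``terms`` only
    before traversal, or call :meth:`invalidate`.
    """

    def __init__(self, terms: Mapping[str, OntologyTerm] | None = None,
                 metadata: dict | None = None):
        self.terms: dict[str, OntologyTerm] = dict(terms or {})
        self.metadata: dict = metadata or {}
        #: (source, target) pairs whose target is absent from the graph
        self.dangling: list[tuple[str, str]] = []
        self._children: dict[str, list[str]] | None = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, curie: str) -> bool:
        return curie in self.terms

    def __iter__(self) -> Iterator[str]:
        return iter(self.terms)

    def __getitem__(self, curie: str) -> OntologyTerm:
        try:
            return self.terms[curie]
        except KeyError:
            raise UnknownTermError(curie) from None

    # -- structure -----------------------------------------------------------
    @property
    def roots(self) -> set[str]:
        """Parentless non-obsolete terms."""
        return {
            t.id for t in self.terms.values()
            if not t.obsolete and not [p for p in t.parents if p in self.terms]
        }

    def invalidate(self) -> None:
        self._children = None

    def children_index(self) -> dict[str, list[str]]:
        if self._children is None:
            idx: dict[str, list[str]] = {c: [] for c in self.terms}
            for term in self.terms.values():
                for p in term.parents:
                    if p in idx:
                        idx[p].append(term.id)
            for kids in idx.values():
                kids.sort()
            self._children = idx
        return self._children

    def parents_of(self, curie: str) -> list[str]:
        return [p for p in self[curie].parents if p in self.terms]

    def children_of(self, curie: str) -> list[str]:
        if curie not in self.terms:
            raise UnknownTermError(curie)
        return self.children_index()[curie]

    # -- traversal -----------------------------------------------------------
    def ancestors(self, curie: str) -> set[str]:
        """Transitive is_a closure above ``curie`` (excluding itself)."""
        seen: set[str] = set()
        queue = deque(self.parents_of(curie))
        while queue:
            node = queue.popleft()
            if node in seen:
                continue
            seen.add(node)
            queue.extend(p for p in self.parents_of(node) if p not in seen)
        return seen

    def descendants(self, curie: str) -> set[str]:
        """Transitive is_a closure below ``curie`` (excluding itself)."""
        seen: set[str] = set()
        queue = deque(self.children_of(curie))
        while queue:
            node = queue.popleft()
            if node in seen:
                continue
            seen.add(node)
            queue.extend(c for c in self.children_of(node) if c not in seen)
        return seen

    def is_descendant(self, child: str, putative_ancestor: str) -> bool:
        """True iff ``putative_ancestor`` is a strict is_a ancestor of ``child``."""
        if child == putative_ancestor:
            return False
        return putative_ancestor in self.ancestors(child)

    def max_depth(self) -> int:
        """Longest is_a path length from any root, in edges."""
        depth: dict[str, int] = {}

        def walk(node: str) -> int:
            if node in depth:
                return depth[node]
            parents = self.parents_of(node)
            d = 0 if not parents else 1 + max(walk(p) for p in parents)
            depth[node] = d
            return d

        return max((walk(t) for t in self.terms), default=0)

    def check_acyclic(self) -> None:
        """Raise :class:`CycleError` if the is_a relation has a cycle."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term in self.terms.values():
            for p in term.parents:
                if p in self.terms:
                    g.add_edge(term.id, p)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise CycleError([u for u, _ in cycle])

    def record_dangling(self, strict: bool = False) -> list[tuple[str, str]]:
        """Find parent/relationship targets missing from the graph.

        Lenient (default): store them in ``self.dangling`` and in
        ``metadata['dangling']``.  Strict: raise.
        """
        refs: list[tuple[str, str]] = []
        for term in self.terms.values():
            for p in term.parents:
                if p not in self.terms:
                    refs.append((term.id, p))
            for _, tgt in term.relationships:
                if tgt not in self.terms:
                    refs.append((term.id, tgt))
        if refs and strict:
            raise DanglingReferenceError(refs)
        self.dangling = sorted(set(refs))
        self.metadata["dangling"] = [list(r) for r in self.dangling]
        return self.dangling
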