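"""Read and write ontologies; expose the traversal primitives.

Two input dialects are supported:

* OBO 1.2/1.4 flat files (read via :mod:`obonet`, written by this
  module — scoped synonyms, ``is_a``, typed relationships,
  ``is_obsolete``/``replaced_by`` and xrefs round-trip losslessly);
* NCBI-taxonomy-style two-file dumps (``nodes.dmp`` + ``names.dmp``,
  pipe-delimited), the format large organism taxonomies ship in.

Every loaded graph is checked for is_a acyclicity, and dangling
parent/relationship targets are either recorded in graph metadata
(lenient, the default — real ontology slices are often incomplete) or
raised (``strict=True``).
"""

from __future__ import annotations

import io
import json
import re
from pathlib import Path

import obonet

from .model import (
    CycleError,
    OboParseError,
    OntologyGraph,
    OntologyTerm,
    Synonym,
    SynonymScope,
    UnknownTermError,
)

_SYNONYM_RE = re.compile(
    r'^"(?P<text>(?:[^"\\]|\\.)*)"\s*(?P<scope>EXACT|NARROW|BROAD|RELATED)?'
)
_STANZA_RE = re.compile(r"^\[[A-Za-z_-]+\]\s*$")
_TAG_RE = re.compile(r"^[A-Za-z0-9_-]+\s*:")


def _prescan_obo(path: str | Path) -> None:
    """Cheap line-level syntax check so parse errors carry line numbers."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if _STANZA_RE.match(line) or _TAG_RE.match(line):
                continue
            raise OboParseError(f"malformed line: {line!r}", line=lineno)


def _parse_synonym(raw: str) -> Synonym:
    m = _SYNONYM_RE.match(raw.strip())
    if not m:
        raise OboParseError(f"unparseable synonym clause: {raw!r}")
    text = m.group("text").replace('\\"', '"')
    scope = m.group("scope")
    return Synonym(text, SynonymScope(scope) if scope else SynonymScope.RELATED)


def load_obo(path: str | Path, strict: bool = False) -> OntologyGraph:
    """Parse an OBO flat file into an :class:`OntologyGraph`.

    Parameters
    ----------
    path:
        OBO 1.2/1.4 flat file.
    strict:
        If true, dangling parent/relationship targets raise; by default
        they are recorded in ``graph.metadata['dangling']``.

    Raises
    ------
    OboParseError
        On malformed input (with a 1-based line number where possible).
    CycleError
        If the is_a relation is cyclic.
    """
    _prescan_obo(path)
    try:
        net = obonet.read_obo(str(path), ignore_obsolete=False)
    except Exception as exc:  # obonet raises bare ValueError
        raise OboParseError(str(exc)) from exc

    terms: dict[str, OntologyTerm] = {}
    for node, attrs in net.nodes(data=True):
        if not attrs:
            continue  # ghost node created by an edge to a missing target
        obsolete = attrs.get("is_obsolete", "false") == "true"
        replaced = attrs.get("replaced_by", [None])[0]
        term = OntologyTerm(
            id=node,
            label=attrs.get("name", ""),
            synonyms=[_parse_synonym(s) for s in attrs.get("synonym", [])],
            parents=list(attrs.get("is_a", [])),
            relationships=[
                tuple(r.split(None, 1)) for r in attrs.get("relationship", [])
            ],
            obsolete=obsolete,
            replaced_by=replaced,
            xrefs=list(attrs.get("xref", [])),
        )
        if not obsolete and not term.label:
            raise OboParseError(f"non-obsolete term {node} has no name")
        terms[node] = term

    graph = OntologyGraph(terms, metadata={"source": str(path), "format": "obo"})
    graph.check_acyclic()
    graph.record_dangling(strict=strict)
    return graph


def write_obo(graph: OntologyGraph, path: str | Path,
              ontology_name: str = "ontoqc-export") -> None:
    """Serialize a graph back to an OBO flat file (deterministic order)."""
    buf = io.StringIO()
    buf.write("format-version: 1.2\n")
    buf.write(f"ontology: {ontology_name}\n")
    for curie in sorted(graph.terms):
        t = graph.terms[curie]
        buf.write("\n[Term]\n")
        buf.write(f"id: {t.id}\n")
        if t.label:
            buf.write(f"name: {t.label}\n")
        for syn in t.synonyms:
            text = syn.text.replace('"', '\\"')
            buf.write(f'synonym: "{text}" {syn.scope.value} []\n')
        for xref in t.xrefs:
            buf.write(f"xref: {xref}\n")
        for p in t.parents:
            buf.write(f"is_a: {p}\n")
        for rel, tgt in t.relationships:
            buf.write(f"relationship: {rel} {tgt}\n")
        if t.obsolete:
            buf.write("is_obsolete: true\n")
        if t.replaced_by:
            buf.write(f"replaced_by: {t.replaced_by}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _split_dmp_line(line: str) -> list[str]:
    # NCBI dump dialect: fields terminated by "\t|\t", record by "\t|".
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def load_ncbi_dump(nodes_path: str | Path, names_path: str | Path,
                   prefix: str = "NCBITaxon:", strict: bool = False) -> OntologyGraph:
    """Load an NCBI-taxonomy-style nodes/names dump pair.

    ``nodes`` rows give ``tax_id | parent_tax_id | rank | ...``; the row
    whose parent is itself is the root.  ``names`` rows give
    ``tax_id | name_txt | unique name | name class``; the scientific
    name becomes the term label and every other name class becomes a
    RELATED synonym.  Tax IDs are rendered as CURIEs with ``prefix``.
    """
    labels: dict[str, str] = {}
    synonyms: dict[str, list[Synonym]] = {}
    with open(names_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_dmp_line(line)
            if len(fields) < 4:
                raise OboParseError(
                    f"names row with {len(fields)} fields", line=lineno)
            tax_id, name_txt, _, name_class = (f.strip() for f in fields[:4])
            if not name_txt:
                raise OboParseError(f"empty name for tax ID {tax_id}", line=lineno)
            if name_class == "scientific name":
                labels[tax_id] = name_txt
            else:
                synonyms.setdefault(tax_id, []).append(
                    Synonym(name_txt, SynonymScope.RELATED))

    terms: dict[str, OntologyTerm] = {}
    with open(nodes_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_dmp_line(line)
            if len(fields) < 2:
                raise OboParseError(
                    f"nodes row with {len(fields)} fields", line=lineno)
            tax_id, parent_id = fields[0].strip(), fields[1].strip()
            if tax_id not in labels:
                raise OboParseError(
                    f"node {tax_id} has no scientific name", line=lineno)
            curie = prefix + tax_id
            parents = [] if parent_id == tax_id else [prefix + parent_id]
            terms[curie] = OntologyTerm(
                id=curie,
                label=labels[tax_id],
                synonyms=synonyms.get(tax_id, []),
                parents=parents,
            )

    graph = OntologyGraph(terms, metadata={
        "source": f"{nodes_path}+{names_path}", "format": "ncbi-dump",
        "prefix": prefix,
    })
    graph.check_acyclic()
    graph.record_dangling(strict=strict)
    return graph


# Module-level traversal wrappers: the functional surface other modules use.

def ancestors(graph: OntologyGraph, curie: str) -> set[str]:
    """All strict is_a ancestors of ``curie`` (empty for a root)."""
    return graph.ancestors(curie)


def descendants(graph: OntologyGraph, curie: str) -> set[str]:
    """All strict is_a descendants of ``curie`` (empty for a leaf)."""
    return graph.descendants(curie)


def is_descendant(graph: OntologyGraph, child: str, putative_ancestor: str) -> bool:
    """Strict subsumption test; ``is_descendant(g, x, x)`` is False."""
    if child not in graph:
        raise UnknownTermError(child)
    return graph.is_descendant(child, putative_ancestor)


def summarize(graph: OntologyGraph) -> dict:
    """JSON-able summary: sizes, roots, depth, dangling references."""
    return {
        "terms": len(graph),
        "obsolete": sum(t.obsolete for t in graph.terms.values()),
        "roots": sorted(graph.roots),
        "root_count": len(graph.roots),
        "max_depth": graph.max_depth(),
        "dangling_references": [list(r) for r in graph.dangling],
    }


def summary_json(graph: OntologyGraph) -> str:
    return json.dumps(summarize(graph), indent=2, sort_keys=True)
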