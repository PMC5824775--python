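import random

import pytest

from ontoqc.fixtures import demo_bundle
from ontoqc.model import OntologyGraph, OntologyTerm


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """The hand-built worked-example bundle, written once per session."""
    d = tmp_path_factory.mktemp("bundle")
    demo_bundle(d)
    return d


@pytest.fixture()
def chain_graph():
    """A is_a chain: C -> B -> A (A is the root)."""
    return OntologyGraph({
        "T:A": OntologyTerm("T:A", "a"),
        "T:B": OntologyTerm("T:B", "b", parents=["T:A"]),
        "T:C": OntologyTerm("T:C", "c", parents=["T:B"]),
    })


def random_dag(n_nodes: int, seed: int, max_parents: int = 3) -> OntologyGraph:
    """Random DAG: node i may only point at lower-indexed nodes, which
    guarantees acyclicity independently of the loader's check."""
    rng = random.Random(seed)
    terms = {}
    for i in range(n_nodes):
        curie = f"D:{i:04d}"
        k = rng.randint(1, max_parents) if i else 0
        parents = [f"D:{j:04d}" for j in
                   rng.sample(range(i), min(k, i))] if i else []
        terms[curie] = OntologyTerm(curie, f"node {i}", parents=parents)
    return OntologyGraph(terms)


def brute_force_ancestors(graph: OntologyGraph, curie: str) -> set[str]:
    """Independent oracle: recursive enumeration of all parent paths."""
    out = set()
    for p in graph.terms[curie].parents:
        if p in graph.terms:
            out.add(p)
            out |= brute_force_ancestors(graph, p)
    return out


def brute_force_descendants(graph: OntologyGraph, curie: str) -> set[str]:
    """Independent oracle: scan every term's full ancestor path set."""
    return {t for t in graph.terms
            if t != curie and curie in brute_force_ancestors(graph, t)}
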