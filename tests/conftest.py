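import networkx as nx
import numpy as np
import pytest

from malnet.schema import MalpracticeGraph


def untyped_graph(edges, nodes=None):
    """Build an untyped directed multigraph from an edge list."""
    g = nx.MultiDiGraph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return MalpracticeGraph(g)


def random_multidigraph(n, n_edges, seed, parallel=True):
    """Random directed multigraph on string-labelled nodes (no self-loops)."""
    rng = np.random.default_rng(seed)
    g = nx.MultiDiGraph()
    g.add_nodes_from(f"v{i}" for i in range(n))
    added = 0
    while added < n_edges:
        u, v = rng.integers(n, size=2)
        if u == v:
            continue
        if not parallel and g.has_edge(f"v{u}", f"v{v}"):
            continue
        g.add_edge(f"v{u}", f"v{v}")
        added += 1
    return MalpracticeGraph(g)


@pytest.fixture
def star_graph():
    """Center -> 4 leaves (N = 5)."""
    return untyped_graph([("c", f"l{i}") for i in range(4)])


@pytest.fixture
def path_graph():
    """A -> B -> C."""
    return untyped_graph([("A", "B"), ("B", "C")])


@pytest.fixture
def cycle_graph():
    """Directed triangle A -> B -> C -> A."""
    return untyped_graph([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def complete4_graph():
    """Complete directed graph on 4 nodes (12 edges)."""
    nodes = ["A", "B", "C", "D"]
    return untyped_graph([(u, v) for u in nodes for v in nodes if u != v])
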