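"""Graph primitives: total degree, degree distribution, shortest-path
lengths and geodesic counting on the directed multigraph.

Conventions (shared by every downstream stage):

* *degree* of a node is in-degree plus out-degree, **counting** the
  multiplicity of parallel typed edges — the per-case multi-edges are what
  make a hub a hub;
* *distances* are hop counts following edge direction, and a parallel edge
  bundle counts as a single hop (multiplicity does not shorten or multiply a
  path's length);
* unreachable is represented explicitly (absent key / ``math.inf``), never
  as 0 — the closeness "unreachable contributes 0" convention is applied
  only inside the centrality module.
"""

from __future__ import annotations

import math
from collections import Counter, deque
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .schema import MalpracticeGraph

__all__ = [
    "DegreeDistribution",
    "total_degree",
    "degree_sequence",
    "degree_distribution",
    "shortest_paths_from",
    "count_shortest_paths",
]


@dataclass(frozen=True)
class DegreeDistribution:
    """Histogram of total degrees: ``counts[k]`` = number of nodes with
    total degree k.  ``sum(counts.values()) == n_nodes`` always."""

    counts: dict[int, int]
    n_nodes: int

    @property
    def median(self) -> float:
        return float(np.median(self.as_sequence()))

    def as_sequence(self) -> np.ndarray:
        """Expand back to one degree per node (sorted ascending)."""
        return np.repeat(
            np.fromiter(sorted(self.counts), dtype=np.int64),
            [self.counts[k] for k in sorted(self.counts)],
        )


def total_degree(graph: MalpracticeGraph, node: str) -> int:
    """In-degree + out-degree of ``node``, counting edge multiplicity."""
    g = graph.g
    if node not in g:
        raise KeyError(f"unknown node {node!r}")
    return g.in_degree(node) + g.out_degree(node)


def degree_sequence(graph: MalpracticeGraph, nodes: list[str] | None = None) -> np.ndarray:
    """Total degree per node, in the order of ``nodes`` (default: graph order)."""
    g = graph.g
    if nodes is None:
        nodes = list(g.nodes)
    ind, outd = g.in_degree(nodes), g.out_degree(nodes)
    return np.asarray([ind[v] + outd[v] for v in nodes], dtype=np.int64)


def degree_distribution(graph: MalpracticeGraph) -> DegreeDistribution:
    """Histogram over total degrees of all nodes."""
    seq = degree_sequence(graph)
    return DegreeDistribution(dict(Counter(seq.tolist())), int(seq.size))


def _hop_graph(graph: MalpracticeGraph, undirected: bool) -> nx.DiGraph | nx.Graph:
    """Collapse parallel edges (hop semantics ignore multiplicity)."""
    g: nx.DiGraph | nx.Graph = nx.DiGraph(graph.g)
    if undirected:
        g = g.to_undirected(as_view=False)
    return g

def shortest_paths_from(
    graph: MalpracticeGraph, source: str, undirected: bool = False
) -> dict[str, int]:
    """Breadth-first hop distances from ``source`` following edge direction
    (or ignoring it with ``undirected=True``).  Unreachable nodes are absent
    from the returned map; ``result[source] == 0``.
    """
    if source not in graph.g:
        raise KeyError(f"unknown source {source!r}")
    return dict(nx.single_source_shortest_path_length(_hop_graph(graph, undirected), source))


def count_shortest_paths(graph: MalpracticeGraph, a: str, b: str) -> tuple[float, int]:
    """Length and number of distinct shortest directed paths from a to b.

    Paths are node sequences: a parallel edge bundle contributes one path.
    Returns ``(math.inf, 0)`` when b is unreachable from a.
    """
    if a == b:
        raise ValueError("endpoints must differ")
    g = graph.g
    for v in (a, b):
        if v not in g:
            raise KeyError(f"unknown node {v!r}")
    # BFS from a with path counting over deduplicated successors
    dist: dict[str, int] = {a: 0}
    sigma: dict[str, int] = {a: 1}
    queue = deque([a])
    while queue:
        u = queue.popleft()
        if u == b:
            break
        for w in set(g.successors(u)):
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = sigma[u]
                queue.append(w)
            elif dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    if b not in dist:
        return math.inf, 0
    return float(dist[b]), sigma[b]
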