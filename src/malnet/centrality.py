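"""The four hub-detection centrality metrics, implemented exactly as the
printed formulas define them.

* degree centrality          D(i) = d_i / (N - 1), d_i = in + out degree;
* closeness centrality       C(i) = (N - 1) / Σ_j D_ij, with the convention
  that an unreachable j contributes 0 to the sum (note: on disconnected
  graphs this convention can yield scores above 1 — it rewards reaching few
  nodes quickly; a harmonic variant is available for sanity comparisons);
* betweenness centrality     B(i) = Σ_{a≠b≠i} g_ab(i) / g_ab over ordered
  node pairs on the directed graph, unnormalized (Brandes accumulation);
* PageRank                   PR(i) = (1-d) + d Σ_{j→i} PR(j) / C(j), the
  classic unnormalized recurrence with damping d (default 0.85); C(j) is
  j's out-degree counting parallel-edge multiplicity, and each parallel
  edge j→i contributes its own PR(j)/C(j) term.  Dangling nodes distribute
  their rank uniformly over all nodes, which preserves the fixed-point
  property Σ PR = N on strongly connected graphs.

All metrics operate on the directed multigraph: degree and PageRank count
edge multiplicity; closeness and betweenness use hop distances, for which a
parallel bundle is a single edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .schema import MalpracticeGraph, NodeKind, RelationKind
from .graphops import degree_sequence

__all__ = [
    "CentralityScores",
    "HubTable",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "pagerank",
    "PageRankConvergenceError",
    "compute_centrality",
    "rank_hubs",
    "error_subgraph",
    "METRICS",
]

METRICS = ("degree", "closeness", "betweenness", "pagerank")


@dataclass
class CentralityScores:
    """Per-node scores for one metric, with the parameters that produced them."""

    metric: str
    scores: dict[str, float]
    params: dict = field(default_factory=dict)


@dataclass
class HubTable:
    """Ranked top-k table: rows of (rank, node id, node kind, score)."""

    metric: str
    rows: list[tuple[int, str, str, float]]
    k: int


# ---------------------------------------------------------------------------


def degree_centrality(graph: MalpracticeGraph) -> CentralityScores:
    """D(i) = d_i / (N - 1) with d_i the total (in+out) degree."""
    n = graph.n
    if n < 2:
        raise ValueError("degree centrality requires at least 2 nodes")
    nodes = list(graph.g.nodes)
    deg = degree_sequence(graph, nodes)
    return CentralityScores(
        "degree", {v: d / (n - 1) for v, d in zip(nodes, deg.tolist())}
    )


def _successor_lists(graph: MalpracticeGraph) -> tuple[list[str], dict[str, list[str]]]:
    g = graph.g
    nodes = list(g.nodes)
    succ = {v: sorted(set(g.successors(v))) for v in nodes}
    return nodes, succ


def closeness_centrality(
    graph: MalpracticeGraph, undirected: bool = False, harmonic: bool = False
) -> CentralityScores:
    """C(i) = (N - 1) / Σ_j D_ij, unreachable j contributing 0 to the sum.

    A node reaching no other node scores 0.  With ``harmonic=True`` the
    standard harmonic closeness Σ_j (1 / D_ij) / (N - 1) is returned instead
    (unreachable contributes 0 there too, without the inflation anomaly).
    """
    n = graph.n
    if n < 2:
        raise ValueError("closeness centrality requires at least 2 nodes")
    g = graph.g
    nodes = list(g.nodes)
    succ = {v: set(g.successors(v)) for v in nodes}
    if undirected:
        for u in nodes:
            for w in g.predecessors(u):
                succ[u].add(w)
    scores: dict[str, float] = {}
    from collections import deque

    for s in nodes:
        # BFS hop distances
        dist = {s: 0}
        dq = deque([s])
        while dq:
            u = dq.popleft()
            du = dist[u]
            for w in succ[u]:
                if w not in dist:
                    dist[w] = du + 1
                    dq.append(w)
        if harmonic:
            scores[s] = sum(1.0 / d for v, d in dist.items() if v != s) / (n - 1)
        else:
            total = sum(d for v, d in dist.items() if v != s)
            scores[s] = (n - 1) / total if total > 0 else 0.0
    return CentralityScores(
        "closeness", scores, {"undirected": undirected, "harmonic": harmonic}
    )


def betweenness_centrality(graph: MalpracticeGraph) -> CentralityScores:
    """Brandes' accumulation of B(i) = Σ_{a≠b≠i} g_ab(i)/g_ab.

    Ordered pairs on the directed graph, no normalization; pairs with no
    connecting path contribute 0.
    """
    from collections import deque

    nodes, succ = _successor_lists(graph)
    bet = {v: 0.0 for v in nodes}
    for s in nodes:
        # single-source shortest paths with path counting
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in nodes}
        sigma = {v: 0 for v in nodes}
        sigma[s] = 1
        dist = {s: 0}
        dq = deque([s])
        while dq:
            u = dq.popleft()
            stack.append(u)
            du = dist[u]
            for w in succ[u]:
                if w not in dist:
                    dist[w] = du + 1
                    dq.append(w)
                if dist[w] == du + 1:
                    sigma[w] += sigma[u]
                    pred[w].append(u)
        # back-propagation of dependencies
        delta = {v: 0.0 for v in stack}
        while stack:
            w = stack.pop()
            coeff = (1.0 + delta[w]) / sigma[w]
            for u in pred[w]:
                delta[u] += sigma[u] * coeff
            if w != s:
                bet[w] += delta[w]
    return CentralityScores("betweenness", bet)


class PageRankConvergenceError(RuntimeError):
    """PageRank failed to converge; ``last_scores`` holds the last iterate."""

    def __init__(self, message: str, last_scores: dict[str, float]):
        super().__init__(message)
        self.last_scores = last_scores


def pagerank(
    graph: MalpracticeGraph,
    d: float = 0.85,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> CentralityScores:
    """Fixed-point iteration of PR(i) = (1-d) + d Σ_{j→i} PR(j)/C(j).

    C(j) counts parallel edges; a dangling j (C(j)=0) spreads PR(j)/N to
    every node.  Iterates from all-ones until the maximum absolute score
    change drops below ``tol``; raises :class:`PageRankConvergenceError`
    after ``max_iter`` sweeps.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("damping d must be in [0, 1]")
    g = graph.g
    nodes = list(g.nodes)
    n = len(nodes)
    if n == 0:
        return CentralityScores("pagerank", {}, {"d": d, "tol": tol})
    idx = {v: i for i, v in enumerate(nodes)}
    out_deg = np.zeros(n)
    for u, v in g.edges():
        out_deg[idx[u]] += 1
    # multiplicity-weighted adjacency, destination-major
    src = np.fromiter((idx[u] for u, v in g.edges()), dtype=np.int64, count=g.number_of_edges())
    dst = np.fromiter((idx[v] for u, v in g.edges()), dtype=np.int64, count=g.number_of_edges())
    dangling = out_deg == 0
    inv_out = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, out_deg))

    pr = np.ones(n)
    for _ in range(max_iter):
        contrib = pr * inv_out
        new = np.full(n, 1.0 - d)
        np.add.at(new, dst, d * contrib[src])
        new += d * pr[dangling].sum() / n
        delta = np.abs(new - pr).max()
        pr = new
        if delta < tol:
            return CentralityScores(
                "pagerank",
                dict(zip(nodes, pr.tolist())),
                {"d": d, "tol": tol, "max_iter": max_iter},
            )
    raise PageRankConvergenceError(
        f"PageRank did not converge within {max_iter} iterations (d={d}, tol={tol})",
        dict(zip(nodes, pr.tolist())),
    )


_METRIC_FNS = {
    "degree": degree_centrality,
    "closeness": closeness_centrality,
    "betweenness": betweenness_centrality,
    "pagerank": pagerank,
}


def compute_centrality(graph: MalpracticeGraph, metric: str, **params) -> CentralityScores:
    """Dispatch to one of the four metrics by name."""
    try:
        fn = _METRIC_FNS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}") from None
    return fn(graph, **params)


def error_subgraph(graph: MalpracticeGraph) -> MalpracticeGraph:
    """Subgraph induced by error (E) nodes and their chronological Order
    edges — the network on which hub errors are ranked."""
    import networkx as nx

    sub = nx.MultiDiGraph()
    for v, attrs in graph.g.nodes(data=True):
        if attrs.get("kind") == NodeKind.ERROR.value:
            sub.add_node(v, **attrs)
    for u, v, data in graph.g.edges(data=True):
        if data.get("relation") == RelationKind.ORDER.value and u in sub and v in sub:
            sub.add_edge(u, v, **data)
    return MalpracticeGraph(sub)


def rank_hubs(
    scores: CentralityScores,
    k: int = 10,
    restrict: Optional[str] = None,
    graph: Optional[MalpracticeGraph] = None,
) -> HubTable:
    """Top-k nodes by score, descending; ties broken by lexicographic id.

    With ``restrict="error_subgraph"`` the same metric is recomputed on the
    error subgraph of ``graph`` (required) before ranking; an empty
    restriction set yields an empty table.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    src_graph = graph
    if restrict is not None:
        if restrict != "error_subgraph":
            raise ValueError(f"unknown restriction {restrict!r}")
        if graph is None:
            raise ValueError("restrict requires the graph")
        sub = error_subgraph(graph)
        if sub.n < 2:
            return HubTable(scores.metric, [], k)
        scores = compute_centrality(sub, scores.metric, **scores.params)
        src_graph = sub
    ordered = sorted(scores.scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    rows = []
    for rank, (node, score) in enumerate(ordered, 1):
        kind = ""
        if src_graph is not None and node in src_graph.g:
            kind = src_graph.g.nodes[node].get("kind", "") or ""
        rows.append((rank, node, kind, float(score)))
    return HubTable(scores.metric, rows, k)
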