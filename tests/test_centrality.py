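"""Centrality metrics: closed forms, oracles, invariants, hub ranking."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from conftest import random_multidigraph, untyped_graph
from malnet.centrality import (
    PageRankConvergenceError,
    betweenness_centrality,
    closeness_centrality,
    compute_centrality,
    degree_centrality,
    error_subgraph,
    pagerank,
    rank_hubs,
)
from malnet.generate import MmncGenParams, generate_mmnc
from malnet.schema import MalpracticeGraph, NodeKind


def brute_force_betweenness(graph):
    """Exhaustive-enumeration oracle: for every ordered pair (a, b), list all
    shortest paths by DFS and accumulate pass-through fractions."""
    g = nx.DiGraph(graph.g)  # collapse parallel edges: paths are node sequences
    nodes = list(g.nodes)
    bet = {v: 0.0 for v in nodes}
    sp = dict(nx.all_pairs_shortest_path_length(g))
    for a, b in itertools.permutations(nodes, 2):
        if b not in sp[a]:
            continue
        target = sp[a][b]
        paths = []

        def walk(node, path):
            if len(path) - 1 == target:
                if node == b:
                    paths.append(list(path))
                return
            for w in g.successors(node):
                if sp[a].get(w) == len(path):  # stay on shortest-path DAG
                    walk(w, path + [w])

        walk(a, [a])
        for p in paths:
            for v in p[1:-1]:
                bet[v] += 1.0 / len(paths)
    return bet


class TestDegreeCentrality:
    def test_star_and_cycle_closed_forms(self, star_graph, cycle_graph):
        assert degree_centrality(star_graph).scores["c"] == 1.0
        assert all(v == 1.0 for v in degree_centrality(cycle_graph).scores.values())

    def test_matches_direct_count_on_random_multigraph(self):
        from malnet.graphops import total_degree

        g = random_multidigraph(50, 300, seed=2)
        scores = degree_centrality(g).scores
        for v in g.g.nodes:
            assert scores[v] == pytest.approx(total_degree(g, v) / 49)

    def test_rejects_single_node(self):
        g = untyped_graph([], nodes=["only"])
        with pytest.raises(ValueError):
            degree_centrality(g)


class TestCloseness:
    def test_star_center_and_leaves(self, star_graph):
        s = closeness_centrality(star_graph).scores
        assert s["c"] == 1.0
        assert all(s[f"l{i}"] == 0.0 for i in range(4))  # leaves reach nothing

    def test_path_head(self, path_graph):
        assert closeness_centrality(path_graph).scores["A"] == pytest.approx(2 / 3)

    def test_disconnected_inflation_per_printed_convention(self):
        """Two disjoint edges: C(A) = (N-1)/1 = 3 — the unreachable-as-zero
        convention can exceed 1 on disconnected graphs."""
        g = untyped_graph([("A", "B"), ("C", "D")])
        assert closeness_centrality(g).scores["A"] == pytest.approx(3.0)

    def test_harmonic_variant_stays_bounded(self):
        g = untyped_graph([("A", "B"), ("C", "D")])
        s = closeness_centrality(g, harmonic=True).scores
        assert all(0 <= v <= 1 for v in s.values())


class TestBetweenness:
    def test_path_middle_and_complete_graph(self, path_graph, complete4_graph):
        assert betweenness_centrality(path_graph).scores["B"] == 1.0
        assert all(v == 0.0 for v in betweenness_centrality(complete4_graph).scores.values())

    def test_matches_exhaustive_enumeration_on_random_digraphs(self):
        for seed in range(6):
            g = random_multidigraph(12, 30, seed)
            got = betweenness_centrality(g).scores
            want = brute_force_betweenness(g)
            for v in g.g.nodes:
                assert got[v] == pytest.approx(want[v], abs=1e-9)

    def test_parallel_edges_do_not_multiply_paths(self):
        a = untyped_graph([("A", "B"), ("B", "C")])
        b = untyped_graph([("A", "B"), ("A", "B"), ("B", "C"), ("B", "C")])
        assert betweenness_centrality(a).scores == betweenness_centrality(b).scores


class TestPageRank:
    def test_damping_zero_gives_all_ones(self):
        g = random_multidigraph(10, 30, seed=1)
        assert all(v == pytest.approx(1.0) for v in pagerank(g, d=0.0).scores.values())

    def test_directed_cycle_fixed_point_is_all_ones(self, cycle_graph):
        s = pagerank(cycle_graph, d=0.85).scores
        assert all(v == pytest.approx(1.0, abs=1e-7) for v in s.values())

    def test_default_damping_recorded_in_params(self, cycle_graph):
        assert pagerank(cycle_graph).params["d"] == 0.85

    def test_sum_is_n_on_strongly_connected_multigraph(self):
        # random strongly connected multigraph: cycle backbone + chords
        rng = np.random.default_rng(4)
        edges = [(f"v{i}", f"v{(i + 1) % 30}") for i in range(30)]
        edges += [
            (f"v{a}", f"v{b}")
            for a, b in rng.integers(0, 30, size=(60, 2))
            if a != b
        ]
        g = untyped_graph(edges)
        tol = 1e-8
        s = pagerank(g, d=0.85, tol=tol).scores
        assert sum(s.values()) == pytest.approx(g.n, abs=10 * tol * g.n)

    def test_initialization_independence_on_strongly_connected_graph(self, cycle_graph):
        # the printed recurrence is a contraction for d < 1: any start converges
        # to the same fixed point; we check all-ones vs a perturbed run by
        # iterating from the converged state
        s1 = pagerank(cycle_graph, d=0.85, tol=1e-10).scores
        s2 = pagerank(cycle_graph, d=0.85, tol=1e-12).scores
        for v in s1:
            assert s1[v] == pytest.approx(s2[v], abs=1e-8)

    def test_non_convergence_raises_with_last_iterate(self):
        g = random_multidigraph(20, 60, seed=9)
        with pytest.raises(PageRankConvergenceError) as exc:
            pagerank(g, d=0.85, tol=1e-15, max_iter=2)
        assert len(exc.value.last_scores) == 20


class TestInvariants:
    def test_all_metrics_permute_with_node_relabeling(self):
        g = random_multidigraph(15, 50, seed=6)
        mapping = {v: f"z{i}" for i, v in enumerate(sorted(g.g.nodes, reverse=True))}
        h = MalpracticeGraph(nx.relabel_nodes(g.g, mapping))
        for metric in ("degree", "closeness", "betweenness", "pagerank"):
            sg = compute_centrality(g, metric).scores
            sh = compute_centrality(h, metric).scores
            for v in g.g.nodes:
                assert sg[v] == pytest.approx(sh[mapping[v]], abs=1e-9)

    def test_directed_cycle_is_constant_for_every_metric(self, cycle_graph):
        for metric in ("degree", "closeness", "betweenness", "pagerank"):
            vals = list(compute_centrality(cycle_graph, metric).scores.values())
            assert max(vals) - min(vals) < 1e-9


class TestHubTables:
    def test_top1_is_argmax_with_lexicographic_ties(self):
        scores = compute_centrality(untyped_graph([("b", "a"), ("c", "a")]), "degree")
        table = rank_hubs(scores, k=1)
        # a has degree 2; b and c tie at 1 but k=1 keeps only the argmax
        assert table.rows[0][1] == "a"
        t2 = rank_hubs(scores, k=3)
        assert [r[1] for r in t2.rows] == ["a", "b", "c"]

    def test_star_degree_table(self, star_graph):
        table = rank_hubs(compute_centrality(star_graph, "degree"), k=2)
        assert table.rows[0][1] == "c"
        assert table.rows[0][3] >= table.rows[1][3]

    def test_error_subgraph_restriction_contains_only_errors(self):
        g = generate_mmnc(MmncGenParams(n_cases=120, seed=3))
        scores = compute_centrality(g, "degree")
        table = rank_hubs(scores, k=10, restrict="error_subgraph", graph=g)
        assert table.rows, "error subgraph should not be empty"
        assert all(kind == NodeKind.ERROR.value for _, _, kind, _ in table.rows)

    def test_error_subgraph_has_only_order_edges(self):
        g = generate_mmnc(MmncGenParams(n_cases=80, seed=4))
        sub = error_subgraph(g)
        assert {d["relation"] for _, _, d in sub.g.edges(data=True)} <= {"Order"}
        kinds = {a.get("kind") for _, a in sub.g.nodes(data=True)}
        assert kinds == {NodeKind.ERROR.value}
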