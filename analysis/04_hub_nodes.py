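#!/usr/bin/env python
"""Hub nodes of the claims network.

Computes the four centrality metrics (degree, closeness, betweenness,
PageRank at damping 0.85) on the overall graph and on the error subgraph
(error nodes + chronological Order links), and writes the top-10 hub tables
in the style of the published results.
"""

import sys
from pathlib import Path

from malnet.centrality import METRICS, compute_centrality, rank_hubs
from malnet.io import read_csv_pair

HERE = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    ndir = HERE / "network"
    if not (ndir / "nodes.csv").exists():
        print("run 01_build_network.py first", file=sys.stderr)
        return 1
    graph = read_csv_pair(ndir / "nodes.csv", ndir / "edges.csv")
    print(f"loaded {graph.n} nodes, {graph.n_relationships} relationships")

    for restrict, label in ((None, "overall"), ("error_subgraph", "errors")):
        print(f"\n== top 10 by each metric ({label}) ==")
        for metric in METRICS:
            params = {"d": 0.85} if metric == "pagerank" else {}
            scores = compute_centrality(graph, metric, **params)
            table = rank_hubs(scores, 10, restrict=restrict, graph=graph)
            out = HERE / f"hubs_{label}_{metric}.csv"
            with open(out, "w", encoding="utf-8") as fh:
                fh.write("rank,node,kind,score\n")
                for rank, node, kind, score in table.rows:
                    fh.write(f'{rank},"{node}",{kind},{score:.6f}\n')
            top3 = ", ".join(node for _, node, _, _ in table.rows[:3])
            print(f"{metric:12s}: {top3}")
    print(f"\nwrote hub tables under {HERE}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
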