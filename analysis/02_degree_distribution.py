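#!/usr/bin/env python
"""Degree distribution of the claims network.

Reads the degree sequence produced by 01_build_network.py, tabulates the
distribution, and plots the log-log degree histogram (the visual scale-free
diagnostic: a straight-line tail on log-log axes).
"""

import sys
from collections import Counter
from pathlib import Path

import numpy as np

from malnet.io import read_degree_sequence

HERE = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    seq_path = HERE / "network" / "degree_sequence.txt"
    if not seq_path.exists():
        print("run 01_build_network.py first", file=sys.stderr)
        return 1
    deg = read_degree_sequence(seq_path)
    counts = Counter(deg.tolist())

    out = HERE / "degree_distribution.csv"
    with open(out, "w", encoding="utf-8") as fh:
        fh.write("degree,n_nodes\n")
        for k in sorted(counts):
            fh.write(f"{k},{counts[k]}\n")
    print(f"{deg.size} nodes; median degree {np.median(deg):.0f}; "
          f"max degree {deg.max()}; degree-1 share {(deg == 1).mean() * 100:.2f}%")
    print(f"wrote {out}")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ks = np.array(sorted(counts))
    ns = np.array([counts[k] for k in ks], dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(ks, ns / deg.size, "o", ms=3, alpha=0.7)
    ax.set_xlabel("degree $k$")
    ax.set_ylabel("$P(k)$")
    ax.set_title("Degree distribution of the claims network")
    fig.tight_layout()
    fig.savefig(HERE / "degree_distribution.png", dpi=150)
    print(f"wrote {HERE / 'degree_distribution.png'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
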