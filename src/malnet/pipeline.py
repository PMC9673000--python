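"""End-to-end analysis pipeline: load or generate a claims network,
validate it, summarize its degree structure, classify scale-free vs
alternatives, compute the four centralities, and rank hubs on the overall
graph and on the error subgraph.

The report is fully deterministic for a fixed config and seed: every number
in it is recomputable from the input, and serialization rounds only at the
end (2 decimals for percentages, 6 for fit parameters).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from .centrality import METRICS, HubTable, compute_centrality, rank_hubs
from .generate import MmncGenParams, generate_mmnc, generate_pa_graph, generate_random_graph
from .graphops import degree_distribution, degree_sequence
from .io import (
    read_csv_pair,
    read_cases_jsonl,
    cases_to_graph,
    read_graphml,
    write_degree_sequence,
)
from .scalefree import Verdict, classify_network
from .schema import MalpracticeGraph, case_cardinality_checks, validate_graph

logger = logging.getLogger("malnet")

__all__ = ["PipelineConfig", "run_pipeline", "summarize_graph", "write_report", "read_graph"]

_CONFIG_KEYS = {
    "input",
    "generator",
    "direction",
    "damping",
    "reps",
    "top_k",
    "seed",
    "output_dir",
    "discrete",
}


@dataclass
class PipelineConfig:
    """Pipeline configuration.

    ``input`` is a path to a graph file (GraphML, JSON-lines cases, or a
    directory holding ``nodes.csv``/``edges.csv``); alternatively
    ``generator`` is a spec such as ``{"kind": "mmnc", "n_cases": 500}`` or
    ``{"kind": "pa", "n": 5000, "m": 3}`` (the pipeline seed is used unless
    the spec carries its own).
    """

    input: Optional[str] = None
    generator: Optional[dict] = None
    direction: str = "directed"
    damping: float = 0.85
    reps: int = 2500
    top_k: int = 10
    seed: int = 0
    output_dir: Optional[str] = None
    discrete: bool = True

    def __post_init__(self) -> None:
        if (self.input is None) == (self.generator is None):
            raise ValueError("exactly one of input / generator must be given")
        if not 0.0 <= self.damping <= 1.0:
            raise ValueError("damping must be in [0, 1]")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.direction not in ("directed", "undirected"):
            raise ValueError("direction must be 'directed' or 'undirected'")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides: Any) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def read_graph(path: str | os.PathLike) -> MalpracticeGraph:
    """Read a claims network from GraphML, JSON-lines cases, or a
    nodes.csv/edges.csv directory; schema codes are checked strictly."""
    p = Path(path)
    if p.is_dir():
        nodes, edges = p / "nodes.csv", p / "edges.csv"
        if not nodes.exists() or not edges.exists():
            raise ValueError(f"{path}: directory must contain nodes.csv and edges.csv")
        return read_csv_pair(nodes, edges)
    suffix = p.suffix.lower()
    if suffix == ".graphml":
        return read_graphml(p)
    if suffix in (".jsonl", ".ndjson"):
        return cases_to_graph(read_cases_jsonl(p))
    raise ValueError(f"{path}: unknown graph format {suffix!r}")


def _build_graph(config: PipelineConfig) -> MalpracticeGraph:
    if config.input is not None:
        return read_graph(config.input)
    spec = dict(config.generator or {})
    kind = spec.pop("kind", None)
    spec.setdefault("seed", config.seed)
    if kind == "mmnc":
        return generate_mmnc(MmncGenParams(**spec))
    if kind == "pa":
        return generate_pa_graph(**spec)
    if kind == "random":
        return generate_random_graph(**spec)
    raise ValueError(f"unknown generator kind {kind!r}")


def summarize_graph(graph: MalpracticeGraph) -> dict:
    """Degree-structure summary of a claims network.

    Reports N, the relationship count, the median total degree, the share
    of single-relationship nodes, and the minimal top fraction of nodes
    (sorted by degree descending, id ascending) whose summed degrees reach
    half of all relationship endpoints — the "top x% of nodes hold 50% of
    relationships" statistic.  An edge-count variant is impossible to assign
    per node, so endpoints (degree sum = 2 x edges) are the convention.
    """
    n = graph.n
    if n == 0:
        return {"n_nodes": 0, "n_relationships": 0}
    nodes = list(graph.g.nodes)
    deg = degree_sequence(graph, nodes)
    total = int(deg.sum())
    order = sorted(range(n), key=lambda i: (-deg[i], nodes[i]))
    half = total / 2.0
    cum = 0
    top_count = 0
    for i in order:
        if cum >= half or total == 0:
            break
        cum += int(deg[i])
        top_count += 1
    top_degree_sum = int(deg[[order[i] for i in range(top_count)]].sum()) if top_count else 0
    return {
        "n_nodes": n,
        "n_relationships": graph.n_relationships,
        "median_degree": float(np.median(deg)),
        "degree1_nodes": int((deg == 1).sum()),
        "degree1_share_pct": float((deg == 1).sum() / n * 100.0),
        "top_nodes_for_half_relationships": top_count,
        "top_share_pct": float(top_count / n * 100.0),
        "top_degree_sum": top_degree_sum,
        "total_degree_sum": total,
    }


def _fit_dict(fit) -> dict:
    d = {
        "family": fit.family,
        "xmin": fit.xmin,
        "n_tail": fit.n_tail,
        "n": fit.n,
        "loglik": fit.loglik,
        "ks": fit.ks,
        "discrete": fit.discrete,
    }
    d.update(fit.params)
    return d


def _verdict_dict(v: Verdict) -> dict:
    return {
        "verdict": v.verdict,
        "power_law": _fit_dict(v.power_law),
        "gof": {
            "n_reps": v.gof.n_reps,
            "p_value": v.gof.p_value,
            "n_fail_to_reject": v.gof.n_fail_to_reject,
            "ks_observed": v.gof.ks_observed,
            "seed": v.gof.seed,
        },
        "alternatives": {
            name: {
                "fit": _fit_dict(fit),
                "lrt": {
                    "log_ratio": lrt.log_ratio,
                    "normalized": lrt.normalized,
                    "p_value": lrt.p_value,
                },
            }
            for name, (fit, lrt) in v.alternatives.items()
        },
    }


def _hub_dict(t: HubTable) -> dict:
    return {
        "metric": t.metric,
        "k": t.k,
        "rows": [
            {"rank": r, "node": node, "kind": kind, "score": score}
            for r, node, kind, score in t.rows
        ],
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return the report as a plain dict.

    Stages run in order: validate -> summarize -> fit/classify ->
    centralities -> rank.  A stage failure aborts with an error naming the
    stage; no stage mutates the loaded graph.
    """
    graph = _build_graph(config)
    logger.info("loaded graph: %d nodes, %d relationships", graph.n, graph.n_relationships)

    # validate (only meaningful for typed graphs: generated pa/random are untyped)
    typed = any(a.get("kind") is not None for _, a in graph.g.nodes(data=True))
    violations = validate_graph(graph) if typed else []
    if typed and violations:
        raise ValueError(
            "stage 'validate' failed: " + "; ".join(str(v) for v in violations[:20])
        )
    cardinality = case_cardinality_checks(graph) if typed else {}
    logger.info("stage validate: ok (typed=%s)", typed)

    summary = summarize_graph(graph)
    logger.info("stage summarize: %s", summary)

    seq = degree_sequence(graph)
    seq_fit = seq[seq >= 1]  # isolated nodes carry no tail information
    verdict = classify_network(seq_fit, n_reps=config.reps, seed=config.seed,
                               discrete=config.discrete)
    logger.info("stage fit: verdict=%s", verdict.verdict)

    undirected = config.direction == "undirected"
    hub_overall: dict[str, dict] = {}
    hub_errors: dict[str, dict] = {}
    for metric in METRICS:
        params: dict[str, Any] = {}
        if metric == "pagerank":
            params["d"] = config.damping
        if metric == "closeness" and undirected:
            params["undirected"] = True
        scores = compute_centrality(graph, metric, **params)
        hub_overall[metric] = _hub_dict(rank_hubs(scores, config.top_k, graph=graph))
        hub_errors[metric] = _hub_dict(
            rank_hubs(scores, config.top_k, restrict="error_subgraph", graph=graph)
        )
    logger.info("stage centralities: done (%s)", ", ".join(METRICS))

    report = {
        "provenance": {
            "malnet_version": __version__,
            "seed": config.seed,
            "config": {
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "output_dir" and v is not None
            },
        },
        "summary": summary,
        "cardinality_checks": cardinality,
        "degree_distribution_head": {
            str(k): c for k, c in sorted(degree_distribution(graph).counts.items())[:20]
        },
        "scale_free": _verdict_dict(verdict),
        "hubs_overall": hub_overall,
        "hubs_error_subgraph": hub_errors,
    }
    if config.output_dir is not None:
        write_report(report, config.output_dir, graph=graph)
    return report


_PCT_KEYS = {"degree1_share_pct", "top_share_pct"}
_PARAM_KEYS = {"alpha", "lambda", "mu", "sigma", "alpha_se", "lambda_se", "mu_se",
               "sigma_se", "loglik", "ks", "log_ratio", "normalized", "p_value",
               "ks_observed", "score", "median_degree"}


def _round(obj: Any, key: Optional[str] = None) -> Any:
    if isinstance(obj, dict):
        return {k: _round(v, k) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round(v, key) for v in obj]
    if isinstance(obj, float):
        if key in _PCT_KEYS:
            return round(obj, 2)
        if key in _PARAM_KEYS:
            return round(obj, 6)
        return round(obj, 6)
    return obj


def write_report(report: dict, output_dir: str | os.PathLike,
                 graph: Optional[MalpracticeGraph] = None) -> list[Path]:
    """Write the report as JSON, markdown hub tables, CSV hub tables, and
    (when the graph is given) the degree-sequence text file."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    rounded = _round(report)
    jpath = out / "report.json"
    jpath.write_text(json.dumps(rounded, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
                     encoding="utf-8")
    written.append(jpath)

    md = ["# Claims-network analysis report", ""]
    s = report.get("summary", {})
    md += [
        f"- nodes: {s.get('n_nodes')}",
        f"- relationships: {s.get('n_relationships')}",
        f"- median degree: {s.get('median_degree')}",
        f"- degree-1 share: {round(s.get('degree1_share_pct', 0.0), 2)}%",
        f"- top {round(s.get('top_share_pct', 0.0), 2)}% of nodes "
        f"({s.get('top_nodes_for_half_relationships')}) hold half of all relationship endpoints",
        "",
        f"**Scale-free verdict:** {report['scale_free']['verdict']} "
        f"(bootstrap p = {round(report['scale_free']['gof']['p_value'], 4)})",
        "",
    ]
    for section, tables in (("overall graph", report["hubs_overall"]),
                            ("error subgraph", report["hubs_error_subgraph"])):
        md.append(f"## Top nodes — {section}")
        md.append("")
        md.append("| Rank | " + " | ".join(m.capitalize() for m in METRICS) + " |")
        md.append("|" + "---|" * (len(METRICS) + 1))
        depth = max((len(tables[m]["rows"]) for m in METRICS), default=0)
        for i in range(depth):
            cells = []
            for m in METRICS:
                rows = tables[m]["rows"]
                cells.append(rows[i]["node"] if i < len(rows) else "")
            md.append(f"| {i + 1} | " + " | ".join(cells) + " |")
        md.append("")
    mpath = out / "report.md"
    mpath.write_text("\n".join(md), encoding="utf-8")
    written.append(mpath)

    for section, tables in (("overall", report["hubs_overall"]),
                            ("errors", report["hubs_error_subgraph"])):
        for m in METRICS:
            cpath = out / f"hubs_{section}_{m}.csv"
            lines = ["rank,node,kind,score"]
            for row in tables[m]["rows"]:
                node = str(row["node"]).replace('"', '""')
                lines.append(f'{row["rank"]},"{node}",{row["kind"]},{row["score"]:.6f}')
            cpath.write_text("\n".join(lines) + "\n", encoding="utf-8")
            written.append(cpath)

    if graph is not None:
        dpath = out / "degree_sequence.txt"
        write_degree_sequence(degree_sequence(graph), dpath)
        written.append(dpath)
    return written
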