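"""Readers and writers for claims networks and degree sequences.

Formats:

* **GraphML** — node attribute ``kind``, edge attribute ``relation`` (plus
  ``case`` where present); delegated to :mod:`networkx`.
* **CSV pair** — ``nodes.csv`` (``id, kind, attrs`` with extra attributes as
  a JSON column) and ``edges.csv`` (``source, target, relation, case``).
* **JSON-lines case records** — one case per line with nested
  patient/hospital/specialty/disease/comorbidities/errors/outcome fields;
  the case-record form is what the synthetic generator produces internally.
* **Plain degree sequences** — one integer per line, the input format of the
  tail-fitting stage.

All writers emit UTF-8.  Readers reject unknown node-kind and relation codes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .schema import MalpracticeGraph, NodeKind, RelationKind

__all__ = [
    "CaseRecord",
    "cases_to_graph",
    "read_graphml",
    "write_graphml",
    "read_csv_pair",
    "write_csv_pair",
    "read_cases_jsonl",
    "write_cases_jsonl",
    "read_degree_sequence",
    "write_degree_sequence",
]

_VALID_KINDS = {k.value for k in NodeKind}
_VALID_RELATIONS = {r.value for r in RelationKind}


# ---------------------------------------------------------------------------
# case records


@dataclass
class CaseRecord:
    """One litigation case in nested record form."""

    case_id: str
    patient: str
    hospital: str
    specialty: str
    disease_group: str
    outcome: str
    comorbidities: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)  # chronological order

    def to_json(self) -> str:
        return json.dumps(
            {
                "case_id": self.case_id,
                "patient": self.patient,
                "hospital": self.hospital,
                "specialty": self.specialty,
                "disease_group": self.disease_group,
                "outcome": self.outcome,
                "comorbidities": self.comorbidities,
                "errors": self.errors,
            },
            ensure_ascii=False,
            sort_keys=True,
        )


def cases_to_graph(cases: Iterable[CaseRecord]) -> MalpracticeGraph:
    """Assemble the typed multigraph from case records.

    Per case: one With link per comorbidity, one SufferFrom, one
    SeekMedicalAdvice, one Affiliated, one AcceptJudgment, two Sue links
    (O->C and P->H); for cases with errors, one Error link from the hospital
    to the first error, Order links chaining subsequent errors, and one Cause
    link (O->C).  All per-case edges carry the case id.
    """
    g = MalpracticeGraph()
    K, R = NodeKind, RelationKind
    for c in cases:
        g.add_node(c.patient, K.PATIENT)
        g.add_node(c.hospital, K.HOSPITAL)
        g.add_node(c.specialty, K.SPECIALTY)
        g.add_node(c.disease_group, K.DISEASE)
        g.add_node(c.outcome, K.OUTCOME, level=c.outcome)
        g.add_node(c.case_id, K.CLAIM)
        for cd in c.comorbidities:
            g.add_node(cd, K.COMORBIDITY)
            g.add_relationship(c.patient, cd, R.WITH, case=c.case_id)
        g.add_relationship(c.patient, c.disease_group, R.SUFFER_FROM, case=c.case_id)
        g.add_relationship(c.patient, c.specialty, R.SEEK_MEDICAL_ADVICE, case=c.case_id)
        g.add_relationship(c.specialty, c.hospital, R.AFFILIATED, case=c.case_id)
        if c.errors:
            for e in c.errors:
                g.add_node(e, K.ERROR, label=e)
            g.add_relationship(c.hospital, c.errors[0], R.ERROR, case=c.case_id)
            for a, b in zip(c.errors, c.errors[1:]):
                g.add_relationship(a, b, R.ORDER, case=c.case_id)
            g.add_relationship(c.outcome, c.case_id, R.CAUSE, case=c.case_id)
        g.add_relationship(c.outcome, c.case_id, R.SUE, case=c.case_id)
        g.add_relationship(c.patient, c.hospital, R.SUE, case=c.case_id)
        g.add_relationship(c.hospital, c.case_id, R.ACCEPT_JUDGMENT, case=c.case_id)
    return g


def write_cases_jsonl(cases: Sequence[CaseRecord], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in cases:
            fh.write(c.to_json() + "\n")


def read_cases_jsonl(path: str | os.PathLike) -> list[CaseRecord]:
    cases = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
                cases.append(
                    CaseRecord(
                        case_id=d["case_id"],
                        patient=d["patient"],
                        hospital=d["hospital"],
                        specialty=d["specialty"],
                        disease_group=d["disease_group"],
                        outcome=d["outcome"],
                        comorbidities=list(d.get("comorbidities", [])),
                        errors=list(d.get("errors", [])),
                    )
                )
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"{path}: malformed case record at line {lineno}: {exc}") from exc
    return cases


# ---------------------------------------------------------------------------
# GraphML


def write_graphml(graph: MalpracticeGraph, path: str | os.PathLike) -> None:
    nx.write_graphml(graph.g, path, encoding="utf-8")


def read_graphml(path: str | os.PathLike) -> MalpracticeGraph:
    g = nx.read_graphml(path, force_multigraph=True)
    if not g.is_directed():  # pragma: no cover - graphml preserves directedness
        raise ValueError(f"{path}: expected a directed graph")
    _check_codes(g, str(path))
    return MalpracticeGraph(g)


def _check_codes(g: nx.MultiDiGraph, source: str) -> None:
    for v, attrs in g.nodes(data=True):
        kind = attrs.get("kind")
        if kind is not None and kind not in _VALID_KINDS:
            raise ValueError(f"{source}: node {v!r} has unknown kind code {kind!r}")
    for u, v, data in g.edges(data=True):
        rel = data.get("relation")
        if rel is not None and rel not in _VALID_RELATIONS:
            raise ValueError(f"{source}: edge {u!r}->{v!r} has unknown relation {rel!r}")


# ---------------------------------------------------------------------------
# CSV pair


def write_csv_pair(graph: MalpracticeGraph, nodes_path, edges_path) -> None:
    nrows = []
    for v, attrs in graph.g.nodes(data=True):
        extra = {k: val for k, val in attrs.items() if k != "kind"}
        nrows.append(
            {
                "id": v,
                "kind": attrs.get("kind", ""),
                "attrs": json.dumps(extra, ensure_ascii=False, sort_keys=True),
            }
        )
    pd.DataFrame(nrows, columns=["id", "kind", "attrs"]).to_csv(
        nodes_path, index=False, encoding="utf-8"
    )
    erows = []
    for u, v, data in graph.g.edges(data=True):
        erows.append(
            {
                "source": u,
                "target": v,
                "relation": data.get("relation", ""),
                "case": data.get("case", ""),
            }
        )
    pd.DataFrame(erows, columns=["source", "target", "relation", "case"]).to_csv(
        edges_path, index=False, encoding="utf-8"
    )


def read_csv_pair(nodes_path, edges_path) -> MalpracticeGraph:
    nodes = pd.read_csv(nodes_path, dtype=str, keep_default_na=False)
    edges = pd.read_csv(edges_path, dtype=str, keep_default_na=False)
    for col in ("id", "kind"):
        if col not in nodes.columns:
            raise ValueError(f"{nodes_path}: missing column {col!r}")
    for col in ("source", "target", "relation"):
        if col not in edges.columns:
            raise ValueError(f"{edges_path}: missing column {col!r}")

    g = MalpracticeGraph()
    known = set()
    for rec_no, row in enumerate(nodes.itertuples(index=False), 2):  # header = line 1
        kind = row.kind or None
        if kind is not None and kind not in _VALID_KINDS:
            raise ValueError(f"{nodes_path}: line {rec_no}: unknown kind code {kind!r}")
        attrs = json.loads(row.attrs) if getattr(row, "attrs", "") else {}
        g.add_node(row.id, kind, **attrs)
        known.add(row.id)
    for rec_no, row in enumerate(edges.itertuples(index=False), 2):
        if row.relation not in _VALID_RELATIONS:
            raise ValueError(f"{edges_path}: line {rec_no}: unknown relation {row.relation!r}")
        if row.source not in known or row.target not in known:
            raise ValueError(
                f"{edges_path}: line {rec_no}: edge references undeclared node "
                f"({row.source!r} -> {row.target!r})"
            )
        case = getattr(row, "case", "") or None
        g.add_relationship(row.source, row.target, row.relation, case=case)
    return g


# ---------------------------------------------------------------------------
# degree sequences


def write_degree_sequence(values: Sequence[int] | np.ndarray, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for v in values:
            fh.write(f"{int(v)}\n")


def read_degree_sequence(path) -> np.ndarray:
    vals = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                vals.append(int(line))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: not an integer: {line!r}") from exc
    return np.asarray(vals, dtype=np.int64)
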