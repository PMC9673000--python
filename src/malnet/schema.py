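"""Typed data model of the malpractice claims knowledge graph.

The graph records, per litigation case, the chain of events leading from a
patient's illness to a legal judgment: a patient (P) with comorbidities (CD)
and a disease group (D) seeks medical advice from a specialty (S) affiliated
with a hospital (H); the hospital may commit one or more medical errors (E,
chained chronologically), wholly or partly causing a patient outcome (O); the
patient sues, and a malpractice claim (C) concludes with a judgment.

Eight node kinds and nine directed relationship kinds exist.  Relationships
are directed in chronological order and the graph is a multigraph: the same
pair of entities (e.g. a specialty and its hospital) is linked once per case.

Outcome levels follow the WHO International Classification for Patient Safety
(ICPS) harm scale, localized to five degrees.  Error labels follow an
ICPS-derived taxonomy split into *technical* errors (diagnosis/treatment
skill) and *nontechnical* errors (consent, records, communication,
management).  Disease groups follow ICD-10 chapter-level categories (at most
23); comorbidities follow the Charlson Comorbidity Index (CCI, at most 20
conditions).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any, Iterator, Optional

import networkx as nx

__all__ = [
    "NodeKind",
    "RelationKind",
    "ErrorCategory",
    "ERROR_TAXONOMY",
    "register_error",
    "OUTCOME_LEVELS",
    "MAX_COMORBIDITY_KINDS",
    "MAX_DISEASE_GROUPS",
    "MalpracticeGraph",
    "Violation",
    "validate_graph",
    "case_cardinality_checks",
    "REPORTED_NODE_COUNTS",
    "REPORTED_RELATIONSHIP_COUNTS",
    "REPORTED_TOTAL_NODES",
    "REPORTED_TOTAL_RELATIONSHIPS",
    "REPORTED_SINGLE_RELATIONSHIP_NODES",
    "REPORTED_TOP_NODES",
    "REPORTED_TOP_NODE_RELATIONSHIP_ENDPOINTS",
]


class NodeKind(str, enum.Enum):
    """The eight entity kinds of the claims network."""

    PATIENT = "P"
    HOSPITAL = "H"
    SPECIALTY = "S"
    OUTCOME = "O"
    CLAIM = "C"
    COMORBIDITY = "CD"
    ERROR = "E"
    DISEASE = "D"


#: The five WHO-ICPS-derived outcome degrees.
OUTCOME_LEVELS = (
    "none",
    "minor injury",
    "severe injury",
    "death",
    "mental injury only",
)

#: CCI has at most 20 comorbid conditions; ICD-10 grouping has at most 23 groups.
MAX_COMORBIDITY_KINDS = 20
MAX_DISEASE_GROUPS = 23


@dataclass(frozen=True)
class ErrorCategory:
    """A medical-error label with its technical/nontechnical classification.

    ``technical`` errors relate to diagnosis, treatment or drugs used;
    ``nontechnical`` errors relate to informed consent, medical records,
    communication or management.
    """

    label: str
    technical: bool


def _taxonomy(entries: list[tuple[str, bool]]) -> dict[str, ErrorCategory]:
    return {label: ErrorCategory(label, tech) for label, tech in entries}


#: Extensible registry of error labels -> :class:`ErrorCategory`.
#: Seeded with the labels appearing in the published hub tables of the
#: reference litigation corpus; extend with :func:`register_error`.
ERROR_TAXONOMY: dict[str, ErrorCategory] = _taxonomy(
    [
        # nontechnical (consent / records / communication / management)
        ("inadequate informed consent", False),
        ("lack of informed consent", False),
        ("unsigned consent documentation", False),
        ("unclear, ambiguous, illegible, or incomplete medical records", False),
        ("failure to communicate with or instruct the patient or family", False),
        ("supervision or patient safety management", False),
        ("emergency management", False),
        ("administrative management", False),
        ("risk management", False),
        ("other management-related errors", False),
        # technical (diagnosis / treatment / surgery / drugs)
        ("missed diagnosis", True),
        ("delay in diagnosis", True),
        ("delay in treatment", True),
        ("delay in surgery", True),
        ("failure to perform preoperative evaluation", True),
        ("failure to perform pretreatment evaluation", True),
        ("failure to recognize complications", True),
        ("failure to identify postoperative complications", True),
        ("untimely patient rounds", True),
        ("other medicine-related errors", True),
        ("other surgery-related errors", True),
        ("other treatment-related errors", True),
    ]
)


def register_error(label: str, technical: bool) -> ErrorCategory:
    """Add an error label to the taxonomy registry (idempotent).

    Raises ``ValueError`` if the label exists with the opposite flag: every
    label carries exactly one technical/nontechnical classification.
    """
    existing = ERROR_TAXONOMY.get(label)
    if existing is not None:
        if existing.technical != technical:
            raise ValueError(
                f"error label {label!r} already registered as "
                f"{'technical' if existing.technical else 'nontechnical'}"
            )
        return existing
    cat = ErrorCategory(label, technical)
    ERROR_TAXONOMY[label] = cat
    return cat


class RelationKind(str, enum.Enum):
    """The nine directed relationship kinds, oriented chronologically."""

    WITH = "With"
    SUFFER_FROM = "SufferFrom"
    SEEK_MEDICAL_ADVICE = "SeekMedicalAdvice"
    AFFILIATED = "Affiliated"
    ERROR = "Error"
    ACCEPT_JUDGMENT = "AcceptJudgment"
    CAUSE = "Cause"
    SUE = "Sue"
    ORDER = "Order"


#: Allowed (source kind, target kind) pairs per relationship kind.  ``Sue``
#: admits two endpoint typings: the outcome sues the claim into being
#: (O -> C) and the patient sues the hospital (P -> H) — two links per case.
RELATION_ENDPOINTS: dict[RelationKind, frozenset[tuple[NodeKind, NodeKind]]] = {
    RelationKind.WITH: frozenset({(NodeKind.PATIENT, NodeKind.COMORBIDITY)}),
    RelationKind.SUFFER_FROM: frozenset({(NodeKind.PATIENT, NodeKind.DISEASE)}),
    RelationKind.SEEK_MEDICAL_ADVICE: frozenset({(NodeKind.PATIENT, NodeKind.SPECIALTY)}),
    RelationKind.AFFILIATED: frozenset({(NodeKind.SPECIALTY, NodeKind.HOSPITAL)}),
    RelationKind.ERROR: frozenset({(NodeKind.HOSPITAL, NodeKind.ERROR)}),
    RelationKind.ACCEPT_JUDGMENT: frozenset({(NodeKind.HOSPITAL, NodeKind.CLAIM)}),
    RelationKind.CAUSE: frozenset({(NodeKind.OUTCOME, NodeKind.CLAIM)}),
    RelationKind.SUE: frozenset(
        {(NodeKind.OUTCOME, NodeKind.CLAIM), (NodeKind.PATIENT, NodeKind.HOSPITAL)}
    ),
    RelationKind.ORDER: frozenset({(NodeKind.ERROR, NodeKind.ERROR)}),
}


class MalpracticeGraph:
    """A typed directed multigraph of claims-network entities.

    Thin wrapper over :class:`networkx.MultiDiGraph`.  Node kind lives in the
    node attribute ``kind`` (never encoded in the identifier, which is an
    opaque string); relationship kind lives in the edge attribute
    ``relation``; per-case edges additionally carry the claim identifier in
    the edge attribute ``case``.
    """

    def __init__(self, g: Optional[nx.MultiDiGraph] = None):
        self.g: nx.MultiDiGraph = g if g is not None else nx.MultiDiGraph()

    # -- construction -------------------------------------------------------

    def add_node(self, node_id: str, kind: NodeKind | str | None = None, **attrs: Any) -> None:
        if kind is not None:
            attrs["kind"] = NodeKind(kind).value
        self.g.add_node(node_id, **attrs)

    def add_relationship(
        self,
        source: str,
        target: str,
        relation: RelationKind | str,
        case: Optional[str] = None,
        **attrs: Any,
    ) -> None:
        attrs["relation"] = RelationKind(relation).value
        if case is not None:
            attrs["case"] = case
        self.g.add_edge(source, target, **attrs)

    # -- inspection ---------------------------------------------------------

    @property
    def n(self) -> int:
        """Number of nodes, the symbol N of the centrality formulas."""
        return self.g.number_of_nodes()

    @property
    def n_relationships(self) -> int:
        return self.g.number_of_edges()

    def node_kind(self, node_id: str) -> Optional[NodeKind]:
        code = self.g.nodes[node_id].get("kind")
        return None if code is None else NodeKind(code)

    def nodes(self, kind: Optional[NodeKind] = None) -> list[str]:
        if kind is None:
            return list(self.g.nodes)
        return [v for v, a in self.g.nodes(data=True) if a.get("kind") == kind.value]

    def relationships(self) -> Iterator[tuple[str, str, str, dict]]:
        """Yield (source, target, relation code, edge data) for every edge."""
        for u, v, data in self.g.edges(data=True):
            yield u, v, data.get("relation", ""), data

    def copy(self) -> "MalpracticeGraph":
        return MalpracticeGraph(self.g.copy())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MalpracticeGraph(n={self.n}, relationships={self.n_relationships})"


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    """One schema violation found by :func:`validate_graph`."""

    code: str
    message: str

    def __str__(self) -> str:
        return f"[{self.code}] {self.message}"


_VALID_KINDS = {k.value for k in NodeKind}
_VALID_RELATIONS = {r.value for r in RelationKind}


def validate_graph(graph: MalpracticeGraph) -> list[Violation]:
    """Check a graph against the claims-network schema.

    Returns the list of violations (empty when valid).  Checks performed:

    * every node carries a recognized ``kind`` attribute;
    * every relationship carries a recognized ``relation`` and its endpoint
      kinds match the schema table;
    * outcome nodes carry one of the five outcome levels;
    * error nodes carry a label present in the taxonomy registry;
    * at most 20 comorbidity nodes and 23 disease-group nodes exist;
    * ``Order`` edges have no self-loops and, where edges are attributed to a
      case, each case's Order edges form a simple chain (every error at most
      one predecessor and one successor, no cycle).

    The check is a pure read: it is idempotent and independent of the order
    in which relationships were inserted.
    """
    g = graph.g
    out: list[Violation] = []

    kinds: dict[str, Optional[str]] = {}
    for v, attrs in g.nodes(data=True):
        code = attrs.get("kind")
        kinds[v] = code
        if code is None:
            out.append(Violation("missing-kind", f"node {v!r} has no kind attribute"))
        elif code not in _VALID_KINDS:
            out.append(Violation("unknown-kind", f"node {v!r} has unknown kind {code!r}"))
        elif code == NodeKind.OUTCOME.value:
            level = attrs.get("level", v)
            if level not in OUTCOME_LEVELS:
                out.append(
                    Violation("unknown-outcome", f"outcome node {v!r} has level {level!r}")
                )
        elif code == NodeKind.ERROR.value:
            label = attrs.get("label", v)
            if label not in ERROR_TAXONOMY:
                out.append(
                    Violation("unknown-error", f"error node {v!r} label {label!r} not in taxonomy")
                )

    n_cd = sum(1 for c in kinds.values() if c == NodeKind.COMORBIDITY.value)
    if n_cd > MAX_COMORBIDITY_KINDS:
        out.append(Violation("too-many-comorbidities", f"{n_cd} CD nodes > {MAX_COMORBIDITY_KINDS}"))
    n_d = sum(1 for c in kinds.values() if c == NodeKind.DISEASE.value)
    if n_d > MAX_DISEASE_GROUPS:
        out.append(Violation("too-many-disease-groups", f"{n_d} D nodes > {MAX_DISEASE_GROUPS}"))

    order_by_case: dict[str, list[tuple[str, str]]] = {}
    for u, v, data in g.edges(data=True):
        rel = data.get("relation")
        if rel is None:
            out.append(Violation("missing-relation", f"edge {u!r}->{v!r} has no relation"))
            continue
        if rel not in _VALID_RELATIONS:
            out.append(Violation("unknown-relation", f"edge {u!r}->{v!r} relation {rel!r}"))
            continue
        rk = RelationKind(rel)
        ku, kv = kinds.get(u), kinds.get(v)
        if ku in _VALID_KINDS and kv in _VALID_KINDS:
            pair = (NodeKind(ku), NodeKind(kv))
            if pair not in RELATION_ENDPOINTS[rk]:
                allowed = " or ".join(
                    f"{a.value}->{b.value}" for a, b in sorted(RELATION_ENDPOINTS[rk])
                )
                out.append(
                    Violation(
                        "endpoint-kind",
                        f"{rel} edge {u!r}->{v!r} links {ku}->{kv}, expected {allowed}",
                    )
                )
        if rk is RelationKind.ORDER:
            if u == v:
                out.append(Violation("order-self-loop", f"Order self-loop on {u!r}"))
            case = data.get("case")
            if case is not None:
                order_by_case.setdefault(case, []).append((u, v))

    for case, edges in sorted(order_by_case.items()):
        srcs = [u for u, _ in edges]
        dsts = [v for _, v in edges]
        if len(set(srcs)) < len(srcs) or len(set(dsts)) < len(dsts):
            out.append(
                Violation("order-branch", f"case {case!r}: Order edges branch (not a chain)")
            )
            continue
        chain = nx.DiGraph(edges)
        if not nx.is_directed_acyclic_graph(chain):
            out.append(Violation("order-cycle", f"case {case!r}: Order edges contain a cycle"))

    return out


# ---------------------------------------------------------------------------
# cardinality checks


def case_cardinality_checks(graph: MalpracticeGraph) -> dict[str, bool]:
    """Check the per-case relationship cardinalities of the schema.

    Constraints (keyed by name in the returned map):

    * ``two_sue_per_case`` — every case has exactly two Sue links, one typed
      O->C and one typed P->H;
    * ``cause_matches_errorful_cases`` — the number of Cause links equals the
      number of cases with at least one Error link;
    * ``one_suffer_from_per_case``, ``one_seek_medical_advice_per_case``,
      ``one_affiliated_per_case``, ``one_accept_judgment_per_case`` — exactly
      one such link per case.

    Cases are identified by the edge attribute ``case`` when present.  When no
    edge carries a case attribute the constraints are checked in aggregate
    against the number of claim (C) nodes: 2 Sue links and one of each
    single-per-case relation per claim, and #Cause == #Error.
    """
    g = graph.g
    per_case: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {r.value: 0 for r in RelationKind}
    sue_typed: dict[str, dict[str, int]] = {}
    any_case_attr = False

    kinds = {v: a.get("kind") for v, a in g.nodes(data=True)}
    for u, v, data in g.edges(data=True):
        rel = data.get("relation")
        if rel not in _VALID_RELATIONS:
            continue
        totals[rel] += 1
        case = data.get("case")
        if case is not None:
            any_case_attr = True
            c = per_case.setdefault(case, {})
            c[rel] = c.get(rel, 0) + 1
            if rel == RelationKind.SUE.value:
                t = sue_typed.setdefault(case, {"OC": 0, "PH": 0, "other": 0})
                pair = (kinds.get(u), kinds.get(v))
                if pair == ("O", "C"):
                    t["OC"] += 1
                elif pair == ("P", "H"):
                    t["PH"] += 1
                else:
                    t["other"] += 1

    if not any_case_attr:
        n_claims = sum(1 for k in kinds.values() if k == NodeKind.CLAIM.value)
        return {
            "two_sue_per_case": totals["Sue"] == 2 * n_claims,
            "cause_matches_errorful_cases": totals["Cause"] == totals["Error"],
            "one_suffer_from_per_case": totals["SufferFrom"] == n_claims,
            "one_seek_medical_advice_per_case": totals["SeekMedicalAdvice"] == n_claims,
            "one_affiliated_per_case": totals["Affiliated"] == n_claims,
            "one_accept_judgment_per_case": totals["AcceptJudgment"] == n_claims,
        }

    cases = sorted(per_case)
    n_errorful = sum(1 for c in cases if per_case[c].get("Error", 0) >= 1)

    def _each(rel: str, count: int) -> bool:
        return all(per_case[c].get(rel, 0) == count for c in cases)

    two_sue = _each("Sue", 2) and all(
        sue_typed.get(c, {}).get("OC") == 1
        and sue_typed.get(c, {}).get("PH") == 1
        for c in cases
    )
    return {
        "two_sue_per_case": two_sue,
        "cause_matches_errorful_cases": totals["Cause"] == n_errorful,
        "one_suffer_from_per_case": _each("SufferFrom", 1),
        "one_seek_medical_advice_per_case": _each("SeekMedicalAdvice", 1),
        "one_affiliated_per_case": _each("Affiliated", 1),
        "one_accept_judgment_per_case": _each("AcceptJudgment", 1),
    }


# ---------------------------------------------------------------------------
# Reference corpus report (published counts for the national litigation
# corpus of 6,610 tertiary-hospital malpractice claims, 2008-2018).  These are
# inputs for arithmetic-identity checks and report-schema references only;
# the corpus itself is not redistributable.  Note the published D count is the
# 5,368 individual diseases, which this package's schema compresses to their
# <=23 ICD-10 groups.

REPORTED_NODE_COUNTS: dict[str, int] = {
    "P": 6582,
    "H": 351,
    "S": 38,
    "O": 5,
    "C": 6610,
    "CD": 20,
    "E": 125,
    "D": 5368,
}

REPORTED_RELATIONSHIP_COUNTS: dict[str, int] = {
    "With": 2097,
    "SufferFrom": 6610,
    "SeekMedicalAdvice": 6610,
    "Affiliated": 6610,
    "Error": 4821,
    "AcceptJudgment": 6610,
    "Cause": 4821,
    "Sue": 13320,
    "Order": 6201,
}

REPORTED_TOTAL_NODES = 19099
REPORTED_TOTAL_RELATIONSHIPS = 57700
#: nodes with exactly one relationship, and the published share 34.45%
REPORTED_SINGLE_RELATIONSHIP_NODES = 6580
#: the 149 highest-degree nodes (0.78% of nodes) carry 28,850 of the 57,700
#: relationship endpoints' worth — half of all relationships
REPORTED_TOP_NODES = 149
REPORTED_TOP_NODE_RELATIONSHIP_ENDPOINTS = 28850
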