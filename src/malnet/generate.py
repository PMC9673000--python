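"""Seeded synthetic-data generators.

This module makes every downstream stage testable without the (non
redistributable) litigation corpus.  It provides:

* :func:`generate_mmnc` — a schema-conforming synthetic claims network.  The
  generator is an *emulator*: its contract is schema conformity, the printed
  per-case cardinalities, and a tunable rich-get-richer heavy tail — not
  statistical realism of any real corpus.
* :func:`generate_pa_graph` — a preferential-attachment (growth) reference
  graph whose degree tail is power-law.
* :func:`generate_random_graph` — a directed Erdős–Rényi reference graph
  whose degree distribution is binomial (Poisson-like), the null model in
  which all connections are equally probable.
* exact samplers for power-law, left-truncated exponential and left-truncated
  log-normal tails, used as ground-truth draws in parameter-recovery tests
  and by the bootstrap.

Every generator is a pure function of its parameters and seed.  A single
global seed is expanded into per-component child seeds by fixed offsets, so
different generators called with the same seed are statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import optimize

from . import _sampling
from .io import CaseRecord, cases_to_graph
from .schema import (
    ERROR_TAXONOMY,
    MAX_COMORBIDITY_KINDS,
    MAX_DISEASE_GROUPS,
    OUTCOME_LEVELS,
    MalpracticeGraph,
)

__all__ = [
    "MmncGenParams",
    "generate_mmnc",
    "generate_mmnc_cases",
    "generate_pa_graph",
    "generate_random_graph",
    "sample_power_law",
    "sample_exponential_tail",
    "sample_lognormal_tail",
]

# fixed per-component seed offsets (seed expansion: default_rng([offset, seed]))
_OFF_MMNC = 1
_OFF_PA = 2
_OFF_RANDOM = 3
_OFF_POWER_LAW = 4
_OFF_EXPONENTIAL = 5
_OFF_LOGNORMAL = 6

#: 38 hospital specialties; the first six are the high-litigation specialties
#: of the reference corpus hub tables.
SPECIALTIES = (
    "orthopedics",
    "obstetrics and gynecology",
    "emergency medicine",
    "gastroenterology",
    "general surgery",
    "cancer",
    "cardiology",
    "neurology",
    "neurosurgery",
    "urology",
    "ophthalmology",
    "otolaryngology",
    "dermatology",
    "pediatrics",
    "neonatology",
    "respiratory medicine",
    "nephrology",
    "endocrinology",
    "hematology",
    "rheumatology",
    "infectious diseases",
    "thoracic surgery",
    "cardiac surgery",
    "vascular surgery",
    "plastic surgery",
    "anesthesiology",
    "intensive care",
    "radiology",
    "radiotherapy",
    "rehabilitation medicine",
    "traditional medicine",
    "stomatology",
    "psychiatry",
    "geriatrics",
    "burn surgery",
    "hepatobiliary surgery",
    "spine surgery",
    "interventional medicine",
)


@dataclass
class MmncGenParams:
    """Parameters of the synthetic claims-network generator.

    Defaults emulate the scale of the reference corpus: 6,610 cases against
    351 tertiary hospitals and 38 specialties, 72.93% of cases with at least
    one error (4,821/6,610) and a mean of 2.286 error occurrences per
    errorful case (11,022/4,821), with on average 0.317 recorded
    comorbidities per case (2,097/6,610).

    ``attachment_strength`` tunes the rich-get-richer choice of hospitals,
    specialties, disease groups, comorbidities and error labels: candidates
    are drawn with probability proportional to ``(degree + 1) ** strength``
    (0 = uniform; 1 = linear preferential attachment).

    ``outcome_probs`` gives the probabilities of the five outcome levels
    (none, minor injury, severe injury, death, mental injury only) in that
    order.  The default skews toward harm — claims are filed over bad
    outcomes — with death, minor and severe injury the three dominant levels.
    """

    n_cases: int = 6610
    n_hospitals: int = 351
    n_specialties: int = 38
    n_disease_groups: int = 23
    n_comorbidity_kinds: int = 20
    error_rate: float = 4821 / 6610
    mean_errors_per_errorful_case: float = 11022 / 4821
    attachment_strength: float = 1.0
    comorbidity_rate: float = 2097 / 6610
    outcome_probs: tuple[float, ...] = (0.10, 0.35, 0.25, 0.25, 0.05)
    seed: int = 0
    max_errors_per_case: int = 8

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_hospitals", "n_specialties", "n_disease_groups",
                     "n_comorbidity_kinds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_disease_groups > MAX_DISEASE_GROUPS:
            raise ValueError(f"n_disease_groups > {MAX_DISEASE_GROUPS}")
        if self.n_comorbidity_kinds > MAX_COMORBIDITY_KINDS:
            raise ValueError(f"n_comorbidity_kinds > {MAX_COMORBIDITY_KINDS}")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.mean_errors_per_errorful_case < 1.0:
            raise ValueError("mean_errors_per_errorful_case must be >= 1")
        if self.attachment_strength < 0.0:
            raise ValueError("attachment_strength must be nonnegative")
        if len(self.outcome_probs) != len(OUTCOME_LEVELS):
            raise ValueError(f"outcome_probs must have {len(OUTCOME_LEVELS)} entries")
        if abs(sum(self.outcome_probs) - 1.0) > 1e-12:
            raise ValueError("outcome_probs must sum to 1 (within 1e-12)")
        if not 1 <= self.max_errors_per_case <= len(ERROR_TAXONOMY):
            raise ValueError("max_errors_per_case out of range")


class _AttachmentPool:
    """Candidate pool with rich-get-richer weights (deg + 1) ** strength."""

    def __init__(self, labels: list[str], strength: float):
        self.labels = labels
        self.strength = strength
        self.deg = np.zeros(len(labels), dtype=np.int64)

    def draw(self, rng: np.random.Generator, k: int = 1, distinct: bool = False) -> list[str]:
        w = (self.deg + 1.0) ** self.strength
        p = w / w.sum()
        idx = rng.choice(len(self.labels), size=k, replace=not distinct, p=p)
        return [self.labels[i] for i in np.atleast_1d(idx)]

    def touch(self, label: str, by: int = 1) -> None:
        self.deg[self.labels.index(label)] += by


def _trunc_geometric_q(mean: float, kmax: int) -> float:
    """Continuation probability of a geometric on {1..kmax} with given mean."""
    if mean <= 1.0:
        return 0.0
    ks = np.arange(1, kmax + 1)

    def m(q: float) -> float:
        w = q ** (ks - 1)
        return float((ks * w).sum() / w.sum())

    hi_mean = m(1 - 1e-12)
    if mean >= hi_mean:
        raise ValueError(f"mean {mean} not attainable on support 1..{kmax}")
    return optimize.brentq(lambda q: m(q) - mean, 1e-12, 1 - 1e-12)


def generate_mmnc_cases(params: MmncGenParams) -> list[CaseRecord]:
    """Draw the synthetic case records underlying :func:`generate_mmnc`."""
    rng = np.random.default_rng([_OFF_MMNC, params.seed])
    s = params.attachment_strength

    hospitals = _AttachmentPool([f"Hospital {i + 1:03d}" for i in range(params.n_hospitals)], s)
    specialties = _AttachmentPool(list(SPECIALTIES[: params.n_specialties])
                                  if params.n_specialties <= len(SPECIALTIES)
                                  else [f"specialty {i + 1}" for i in range(params.n_specialties)], s)
    diseases = _AttachmentPool(
        [f"ICD-10 group {i + 1:02d}" for i in range(params.n_disease_groups)], s
    )
    comorbidities = _AttachmentPool(
        [f"CCI condition {i + 1:02d}" for i in range(params.n_comorbidity_kinds)], s
    )
    errors = _AttachmentPool(sorted(ERROR_TAXONOMY), s)

    q = _trunc_geometric_q(params.mean_errors_per_errorful_case, params.max_errors_per_case)
    ks = np.arange(1, params.max_errors_per_case + 1)
    kw = q ** (ks - 1)
    k_probs = kw / kw.sum()

    cases: list[CaseRecord] = []
    for i in range(params.n_cases):
        case_id = f"case {i + 1:06d}"
        patient = f"patient {i + 1:06d}"
        hospital = hospitals.draw(rng)[0]
        hospitals.touch(hospital)
        specialty = specialties.draw(rng)[0]
        specialties.touch(specialty)
        disease = diseases.draw(rng)[0]
        diseases.touch(disease)
        n_cd = min(rng.poisson(params.comorbidity_rate), params.n_comorbidity_kinds)
        cds = comorbidities.draw(rng, n_cd, distinct=True) if n_cd else []
        for cd in cds:
            comorbidities.touch(cd)
        outcome = OUTCOME_LEVELS[rng.choice(len(OUTCOME_LEVELS), p=params.outcome_probs)]
        errs: list[str] = []
        if rng.random() < params.error_rate:
            k = int(rng.choice(ks, p=k_probs))
            errs = errors.draw(rng, k, distinct=True)
            for e in errs:
                errors.touch(e)
        cases.append(
            CaseRecord(
                case_id=case_id,
                patient=patient,
                hospital=hospital,
                specialty=specialty,
                disease_group=disease,
                outcome=outcome,
                comorbidities=cds,
                errors=errs,
            )
        )
    return cases


def generate_mmnc(params: MmncGenParams) -> MalpracticeGraph:
    """Generate a schema-conforming synthetic claims network.

    The output always passes :func:`malnet.schema.validate_graph` and all
    :func:`malnet.schema.case_cardinality_checks`; with
    ``attachment_strength >= 1`` the degree profile is heavy-tailed (a few
    hub hospitals/specialties/errors carry a large share of relationships).
    """
    return cases_to_graph(generate_mmnc_cases(params))


def generate_pa_graph(n: int, m: int, seed: int = 0) -> MalpracticeGraph:
    """Growth with preferential attachment (Barabási–Albert process).

    Starts from ``m`` unconnected core nodes; each new node attaches ``m``
    edges to existing nodes with probability proportional to their degree,
    giving ``m * (n - m)`` edges.  Edges are directed from the newer node to
    the older (chronological orientation); nodes are untyped.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if n <= m:
        raise ValueError("n must exceed m")
    ug = nx.barabasi_albert_graph(n, m, seed=int(np.random.default_rng([_OFF_PA, seed]).integers(2**31)))
    g = nx.MultiDiGraph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for u, v in ug.edges():
        new, old = (u, v) if u > v else (v, u)
        g.add_edge(f"n{new}", f"n{old}")
    return MalpracticeGraph(g)


def generate_random_graph(n: int, p: float, seed: int = 0) -> MalpracticeGraph:
    """Directed Erdős–Rényi graph: every ordered pair linked independently
    with probability ``p`` (the all-connections-equally-probable null)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    ug = nx.gnp_random_graph(
        n, p, seed=int(np.random.default_rng([_OFF_RANDOM, seed]).integers(2**31)), directed=True
    )
    g = nx.MultiDiGraph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for u, v in ug.edges():
        g.add_edge(f"n{u}", f"n{v}")
    return MalpracticeGraph(g)


def sample_power_law(
    n: int, alpha: float, xmin: float = 1, discrete: bool = False, seed: int = 0
) -> np.ndarray:
    """Sample from a power-law tail P(x) ∝ x^(-alpha), x >= xmin.

    Continuous: exact inverse-CDF draw.  Discrete: exact cumulative search on
    the Hurwitz-zeta CCDF.
    """
    if alpha <= 1.0:
        raise ValueError("alpha must exceed 1 (non-normalizable otherwise)")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([_OFF_POWER_LAW, seed])
    if discrete:
        if xmin < 1:
            raise ValueError("discrete power law requires xmin >= 1")
        return _sampling.draw_power_law_discrete(rng, n, alpha, int(xmin))
    return _sampling.draw_power_law_continuous(rng, n, alpha, float(xmin))


def sample_exponential_tail(n: int, lam: float, xmin: float = 0.0, seed: int = 0) -> np.ndarray:
    """Sample from an exponential left-truncated at ``xmin``."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    rng = np.random.default_rng([_OFF_EXPONENTIAL, seed])
    return _sampling.draw_exponential_tail(rng, n, lam, xmin)


def sample_lognormal_tail(
    n: int, mu: float, sigma: float, xmin: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Sample from a log-normal left-truncated at ``xmin``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng([_OFF_LOGNORMAL, seed])
    return _sampling.draw_lognormal_tail(rng, n, mu, sigma, xmin)
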