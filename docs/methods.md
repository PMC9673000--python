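# Methods

## The problem

Medical-malpractice litigation records can be read as a network: patients,
hospitals, specialties, diseases, comorbidities, medical errors, outcomes and
claims are entities, and the events of a case (seeking care, committing an
error, suing, judgment) are directed, chronologically oriented relationships
among them.  Two structural hypotheses compete.  If claims were random
accidents, the degree distribution of this network would be binomial/Poisson
(bell-shaped).  If claims cluster — hospitals or specialties with past claims
attracting new ones — the network grows by preferential attachment and its
degree distribution develops a power-law tail, P(k) ∝ k^(−α): a *scale-free*
network with a few dominant hubs.  Which regime holds decides whether
hub-targeted interventions (consent training in a handful of specialties,
record-keeping audits at a few hospitals) can pay off disproportionately.

This package implements the full decision pipeline — typed claims graph,
degree analysis, maximum-likelihood tail classification, and centrality-based
hub ranking — together with the synthetic generators needed to exercise it,
since the underlying litigation corpus (6,610 Chinese tertiary-hospital
cases, 2008–2018) is not redistributable.  Its published count tables are
shipped as constants for arithmetic-identity checks and report-schema
references only.

## Graph model

Eight node kinds (patient P, hospital H, specialty S, outcome O, claim C,
comorbidity CD, error E, disease group D) and nine directed relationship
kinds (With, SufferFrom, SeekMedicalAdvice, Affiliated, Error,
AcceptJudgment, Cause, Sue, Order) with fixed endpoint typings.  The graph
is a multigraph: each case contributes its own parallel edges, and a node's
degree (in + out, counting multiplicity) is its caseload.  Per case the
schema demands exactly one SufferFrom / SeekMedicalAdvice / Affiliated /
AcceptJudgment link, exactly two Sue links (O→C and P→H), and — for cases
with at least one error — one Error link from the hospital to the first
error, Order links chaining later errors chronologically, and one Cause
link.  This reading makes the published corpus totals self-consistent
(4,821 Error = 4,821 Cause = errorful cases; 6,201 Order = error occurrences
minus errorful cases).  The published Sue total, 13,320 for 6,610 cases, is
*about* two per case; the ~100 extra links (multi-plaintiff cases,
presumably) are why the printed-table checks assert the ratio rather than
the exact identity, while the generator enforces exactly two.

Error labels carry a technical (diagnosis/treatment skill) vs nontechnical
(consent, records, communication, management) flag in an extensible
registry; outcomes use a five-level ICPS-derived harm scale.  Disease nodes
are the ≤23 ICD-10 chapter-level groups; the corpus counted the 5,368
individual diseases instead, which is why its median degree is 1 (most
individual diseases occur once) while synthetic graphs built on groups have
a higher median — the summary *structure*, not that value, is the contract.

## Synthetic data

`generate_mmnc` is an emulator, not a calibrated model of the corpus: its
contract is schema conformity, the per-case cardinalities, and a tunable
heavy tail.  Case counts, hospital/specialty/disease/comorbidity pool sizes,
the error rate (4,821/6,610), the mean error occurrences per errorful case
(11,022/4,821 ≈ 2.29, drawn from a geometric truncated to 1..8 — published
chains are short) and the comorbidity rate (2,097/6,610) default to the
corpus scale.  Outcome probabilities are not published; the default
(none .10, minor .35, severe .25, death .25, mental .05) encodes that claims
follow harm, with death/minor/severe dominant as in the published hub
tables.  Categorical choices are rich-get-richer: a candidate with current
degree g is drawn with probability ∝ (g+1)^s, where s = 0 is uniform and
s = 1 (default) linear preferential attachment; at s = 1 the top 1% of
nodes carry ≈48% of relationship endpoints, mirroring the corpus's
0.78% → 50%.  What the generator does *not* emulate: judgment amounts,
regions, time trends, multi-case patients, per-disease nodes, and any
fitted realism — passing tests show the pipeline is correct, not that the
corpus looks like this.

Reference models: `generate_pa_graph` (Barabási–Albert growth, edges
directed new→old) and `generate_random_graph` (directed Erdős–Rényi) give
known scale-free and non-scale-free degree profiles.  Exact tail samplers
(continuous/discrete power law via inverse CDF / Hurwitz-zeta cumulative
search, left-truncated exponential via memorylessness, left-truncated
log-normal via inverse CDF) provide ground truth for recovery tests and
drive the bootstrap.  Every generator is a pure function of (parameters,
seed); a global seed expands to per-component child seeds by fixed offsets.

## Tail classification

Power-law fitting follows the standard maximum-likelihood recipe with
KS-minimizing threshold selection: every unique sample value leaving at
least 10 tail observations is tried as x_min (fewer tail points make the
exponent estimate unstable); α is the tail MLE; the (x_min, α) pair with
the smallest Kolmogorov–Smirnov distance wins, smallest x_min on ties.
Degrees are counts, so discrete estimators are the default: α̂ = 1 +
n/Σln(x_i/(x_min−½)) for speed, with exact Hurwitz-zeta likelihood
maximization available (`method="exact"`).  The approximation is biased low
at x_min ≤ ~5 (α̂ ≈ 2.0 for a true 2.5 at x_min = 1), which inflates the KS
there and pushes the selected threshold up a few units; the exact mode keeps
x_min = 1 on clean data.  Recovery checks therefore use the exact mode.

Goodness of fit is a semi-parametric bootstrap (default 2,500 replicates):
each replicate draws n values — from the fitted tail model with probability
n_tail/n, else uniformly from the empirical body below x_min — and is
refitted from scratch the same way the observed fit was obtained (searched
thresholds are re-searched; fixed thresholds stay).  The p-value is the
fraction of replicate KS distances reaching the observed one; small p
rejects the family.  Alongside, the count of replicates whose KS statistic
is below the asymptotic 5% critical value 1.358/√n_tail is reported (the
"failed to reject" count of the corpus report, printed there as
2,489/2,500).  Replicate seeds derive from the test seed by counter, so
p-values are bit-reproducible.

Alternatives — left-truncated exponential (closed-form MLE; shifted
geometric for integer data) and left-truncated log-normal (Nelder–Mead MLE
with finite-difference observed-information SEs) — are fitted at the power
law's threshold and compared by Vuong's normalized log-likelihood-ratio
test with two-sided normal p-value; positive R favors the power law.  For
integer data all likelihoods are proper probability masses (zeta pmf,
shifted geometric, CDF-difference discretization), so the ratio compares
like with like.

Verdict logic: `scale_free` requires bootstrap p ≥ 0.1 *and* no alternative
significantly favored (R < 0, p < 0.1); `not_scale_free` when the bootstrap
rejects (p < 0.1) or an alternative wins outright (R < 0, p < 0.05);
`inconclusive` in the remaining band (an alternative weakly favored at
0.05 ≤ p < 0.1).

### Known power limitations

Two documented failure modes, both properties of the procedure rather than
of this implementation (an independent C implementation of the same recipe,
igraph's plfit, behaves identically on the same data):

* **Threshold escape.**  For data that are not power laws (e.g. Poisson
  degrees of a random graph), the KS-minimizing search often lands on a
  small, steep far tail (n_tail 20–150, α 8–12) where a discrete power law
  is numerically a geometric distribution.  There the bootstrap has
  *structurally* no power — replicates are the empirical body plus a
  near-identical tail — and the likelihood-ratio test cannot separate the
  families either.  At n = 3,000, mean degree 6, the random graph is
  correctly rejected in ~70% of seeds (those where the search keeps
  n_tail ≳ 250 and the exponential wins at p < 0.01), not in the rest.
* **Log-normal mimicry.**  A heavy log-normal is classified scale-free with
  high confidence on many seeds: its observed range *is* power-law-like and
  the search can always truncate to a conforming tail.  What does hold, and
  is tested, is that the power law is never significantly favored *over*
  the log-normal truth.  This is the classic power-law/log-normal
  indistinguishability; a confident scale-free verdict should always be
  read jointly with the log-normal comparison it ships with.

## Centrality and hubs

The four metrics are implemented exactly as their printed formulas define
them, on the directed multigraph:

* degree D(i) = d_i/(N−1) with d_i = in+out degree counting multiplicity
  (so D can reach 2 on a complete digraph);
* closeness C(i) = (N−1)/Σ_j D_ij with unreachable j contributing 0 to the
  sum — implemented literally although it inflates scores on disconnected
  graphs (two disjoint edges give C = N−1); a harmonic variant
  (`harmonic=True`) is available for sanity comparisons;
* betweenness B(i) = Σ_{a≠b≠i} g_ab(i)/g_ab over ordered pairs,
  unnormalized, by Brandes' accumulation; paths are node sequences, so
  parallel edges neither shorten nor multiply them;
* PageRank PR(i) = (1−d) + d Σ PR(T)/C(T), the classic unnormalized
  recurrence, damping d = 0.85 by default, C(T) counting parallel edges and
  each parallel edge contributing its own term; dangling nodes spread their
  rank uniformly, preserving Σ PR = N on strongly connected graphs.
  Iteration stops when the largest score change drops below tol = 1e−8
  (max 200 sweeps) — the printed formula has no stopping rule, so one was
  chosen.

Hub tables take the top k (default 10) by score, ties broken by
lexicographic node id for deterministic reports.  The error subgraph —
error nodes plus their chronological Order links — is where hub *errors*
are ranked, recomputing scores on the subgraph rather than filtering
overall scores.

## Pipeline and numerical conventions

`run_pipeline` stages: validate → summarize → classify → centralities →
rank; any failure aborts naming its stage, and no stage mutates the graph.
Reports are plain dicts, rounded only at serialization (2 decimals for
percentages, 6 for fit parameters), making fixed config + seed runs
byte-identical.  The "top x% of nodes hold 50% of relationships" summary
sorts by degree descending then id ascending and takes the minimal prefix
whose degree sum reaches half the endpoint total (endpoints, not edges: a
per-node edge share is not well defined).

Problem sizes in the shipped analysis and acceptance script are scaled to
desk hardware: the acceptance pipeline uses 1,500-case networks (the
all-pairs BFS behind closeness/betweenness is O(N·E)), 200 bootstrap
replicates, and 50-run calibration batches; the corpus-scale defaults
(6,610 cases, 2,500 replicates) remain the package defaults and run in a
few minutes where needed.

## Limitations

Beyond the statistical power limits above: the generator's attachment
mechanism acts on marginal pools, not joint hospital-specialty structure;
edge weights are multiplicities only (the corpus also weighted by
relationship counts, which coincides here); distances ignore direction only
when asked (`direction: undirected` sensitivity switch); and closeness
follows the printed unreachable-as-zero convention, which product graph
databases may not share — rankings, not raw closeness values, are the
comparable output.
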