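"""Synthetic generators: schema conformity, determinism, distributional oracles."""

import numpy as np
import pytest
from scipy import special, stats

from malnet.generate import (
    MmncGenParams,
    generate_mmnc,
    generate_pa_graph,
    generate_random_graph,
    sample_exponential_tail,
    sample_lognormal_tail,
    sample_power_law,
)
from malnet.graphops import degree_sequence
from malnet.schema import RelationKind, case_cardinality_checks, validate_graph


def relation_counts(graph):
    out = {}
    for _, _, rel, _ in graph.relationships():
        out[rel] = out.get(rel, 0) + 1
    return out


class TestMmnc:
    def test_single_errorful_case_cardinalities(self):
        g = generate_mmnc(MmncGenParams(n_cases=1, error_rate=1.0, seed=0))
        counts = relation_counts(g)
        assert counts["Sue"] == 2
        assert counts["Cause"] == 1
        assert counts["Error"] == 1  # one Error link per errorful case
        assert validate_graph(g) == []

    def test_default_generator_satisfies_its_own_schema(self):
        g = generate_mmnc(MmncGenParams(n_cases=200, seed=1))
        assert validate_graph(g) == []
        assert all(case_cardinality_checks(g).values())

    def test_order_links_count_error_occurrences_minus_cases(self):
        # k errors in a case contribute 1 Error link and k-1 Order links
        params = MmncGenParams(n_cases=150, error_rate=1.0, seed=5)
        g = generate_mmnc(params)
        counts = relation_counts(g)
        assert counts["Error"] == 150
        assert counts["Order"] >= 1
        assert counts["Cause"] == counts["Error"]

    def test_determinism_under_fixed_seed(self):
        a = generate_mmnc(MmncGenParams(n_cases=60, seed=7))
        b = generate_mmnc(MmncGenParams(n_cases=60, seed=7))
        ea = sorted((u, v, tuple(sorted(d.items()))) for u, v, d in a.g.edges(data=True))
        eb = sorted((u, v, tuple(sorted(d.items()))) for u, v, d in b.g.edges(data=True))
        assert ea == eb

    def test_heavy_tail_under_preferential_attachment(self):
        """Top 1% of nodes carry at least a quarter of relationship endpoints."""
        g = generate_mmnc(MmncGenParams(n_cases=5000, attachment_strength=1.0, seed=1))
        deg = np.sort(degree_sequence(g))[::-1]
        top = int(np.ceil(0.01 * deg.size))
        assert deg[:top].sum() / deg.sum() >= 0.25

    def test_infeasible_params_rejected(self):
        with pytest.raises(ValueError):
            MmncGenParams(n_cases=10, n_hospitals=0)
        with pytest.raises(ValueError):
            MmncGenParams(outcome_probs=(0.5, 0.5, 0.1, 0.0, 0.0))
        with pytest.raises(ValueError):
            MmncGenParams(error_rate=1.5)


class TestReferenceGraphs:
    def test_pa_tree_edge_count(self):
        g = generate_pa_graph(10, 1, seed=0)
        assert g.n == 10
        assert g.n_relationships == 9

    def test_pa_seeds_differ_but_node_count_fixed(self):
        a, b = generate_pa_graph(50, 2, seed=1), generate_pa_graph(50, 2, seed=2)
        assert a.n == b.n == 50
        assert sorted(a.g.edges()) != sorted(b.g.edges())

    def test_pa_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            generate_pa_graph(3, 3)

    def test_random_graph_edge_extremes(self):
        assert generate_random_graph(20, 0.0, seed=1).n_relationships == 0
        assert generate_random_graph(4, 1.0, seed=1).n_relationships == 12  # n(n-1)

    def test_random_graph_mean_degree_matches_binomial_expectation(self):
        n, p = 3000, 0.002
        g = generate_random_graph(n, p, seed=5)
        deg = degree_sequence(g)
        expect = 2 * p * (n - 1)
        se = np.sqrt(2 * p * (1 - p) * (n - 1) / n)
        assert abs(deg.mean() - expect) <= 3 * se


class TestTailSamplers:
    def test_continuous_power_law_median_closed_form(self):
        # median = xmin * 2^(1/(alpha-1)) = 2 for alpha=2, xmin=1
        x = sample_power_law(100_000, 2.0, 1.0, discrete=False, seed=3)
        assert np.median(x) == pytest.approx(2.0, rel=0.05)

    def test_continuous_power_law_ccdf_within_ks_band(self):
        """Empirical CCDF matches (x/xmin)^(1-alpha) within 1.63/sqrt(n)."""
        n, alpha, xmin = 100_000, 2.5, 1.0
        x = np.sort(sample_power_law(n, alpha, xmin, discrete=False, seed=9))
        model = 1.0 - (x / xmin) ** (1.0 - alpha)
        i = np.arange(1, n + 1)
        ks = max((i / n - model).max(), (model - (i - 1) / n).max())
        assert ks <= 1.63 / np.sqrt(n)  # 1% critical value

    def test_discrete_power_law_mass_at_one_matches_zeta(self):
        x = sample_power_law(50_000, 2.5, 1, discrete=True, seed=3)
        assert (x == 1).mean() == pytest.approx(1.0 / special.zeta(2.5, 1), abs=0.01)

    def test_discrete_sampler_respects_threshold(self):
        x = sample_power_law(5000, 2.2, 4, discrete=True, seed=2)
        assert x.min() >= 4

    def test_power_law_rejects_non_normalizable_exponent(self):
        with pytest.raises(ValueError):
            sample_power_law(10, 1.0, 1.0)

    def test_exponential_tail_mean(self):
        lam, n = 0.5, 50_000
        x = sample_exponential_tail(n, lam, xmin=0.0, seed=1)
        assert abs(x.mean() - 1 / lam) <= 3 * (1 / lam) / np.sqrt(n)

    def test_exponential_truncation_respected(self):
        assert sample_exponential_tail(1000, 2.0, xmin=3.0, seed=4).min() >= 3.0

    def test_lognormal_degenerate_sigma_limit(self):
        x = sample_lognormal_tail(100, mu=1.0, sigma=1e-8, seed=0)
        assert np.allclose(x, np.e, rtol=1e-5)

    def test_lognormal_truncation_and_shape(self):
        mu, sigma, xmin = 0.5, 1.0, 2.0
        x = sample_lognormal_tail(50_000, mu, sigma, xmin=xmin, seed=6)
        assert x.min() >= xmin
        # conditional median: quantile of the truncated distribution
        phi0 = stats.norm.cdf((np.log(xmin) - mu) / sigma)
        med = np.exp(mu + sigma * stats.norm.ppf(0.5 * (1 + phi0)))
        assert np.median(x) == pytest.approx(med, rel=0.03)

    def test_samplers_are_pure_functions_of_seed(self):
        for fn, kw in [
            (sample_power_law, dict(alpha=2.5, xmin=1, discrete=True)),
            (sample_exponential_tail, dict(lam=0.3, xmin=1.0)),
            (sample_lognormal_tail, dict(mu=0.5, sigma=1.0, xmin=1.0)),
        ]:
            a, b = fn(500, seed=12, **kw), fn(500, seed=12, **kw)
            assert (np.asarray(a) == np.asarray(b)).all()
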