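"""Tail fitting, bootstrap goodness of fit, and likelihood-ratio comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from malnet._sampling import draw_exponential_discrete
from malnet.generate import (
    sample_exponential_tail,
    sample_lognormal_tail,
    sample_power_law,
)
from malnet.scalefree import (
    bootstrap_gof,
    classify_network,
    fit_exponential,
    fit_lognormal,
    fit_power_law,
    ks_distance,
    likelihood_ratio,
    mle_alpha,
    TailFit,
)


class TestMleAlpha:
    def test_continuous_closed_form_at_e_times_xmin(self):
        # all x = e * xmin gives sum(ln(x/xmin)) = n, hence alpha = 2
        x = np.full(100, np.e * 3.0)
        assert mle_alpha(x, 3.0, discrete=False) == pytest.approx(2.0)

    def test_continuous_recovery_within_asymptotic_se(self):
        n, alpha = 50_000, 2.5
        x = sample_power_law(n, alpha, 1.0, discrete=False, seed=3)
        se = (alpha - 1) / np.sqrt(n)
        assert abs(mle_alpha(x, 1.0, discrete=False) - alpha) <= 4 * se

    def test_discrete_exact_recovery_at_threshold_one(self):
        x = sample_power_law(50_000, 2.5, 1, discrete=True, seed=3)
        assert mle_alpha(x, 1, discrete=True, method="exact") == pytest.approx(2.5, abs=0.02)

    def test_exact_mode_diverges_on_degenerate_tail(self):
        with pytest.raises(ValueError, match="diverges"):
            mle_alpha(np.full(50, 5.0), 5, discrete=True, method="exact")

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.floats(0.1, 100.0), st.integers(0, 10_000))
    def test_continuous_estimator_is_scale_equivariant(self, c, seed):
        x = sample_power_law(200, 2.2, 1.0, discrete=False, seed=seed)
        a1 = mle_alpha(x, 1.0, discrete=False)
        a2 = mle_alpha(c * x, c * 1.0, discrete=False)
        assert a1 == pytest.approx(a2, rel=1e-9)


class TestKsDistance:
    def _fit(self, alpha=2.0, xmin=1.0, discrete=False):
        return TailFit("power_law", xmin, {"alpha": alpha}, 0, 0, 0.0, 0.0, discrete)

    def test_sample_at_model_quantiles_has_tiny_distance(self):
        # quantiles at p = (i - 0.5)/n leave at most 0.5/n of ECDF mismatch
        n, alpha, xmin = 1000, 2.0, 1.0
        p = (np.arange(1, n + 1) - 0.5) / n
        x = xmin * (1 - p) ** (-1 / (alpha - 1))
        assert ks_distance(x, self._fit(alpha, xmin)) <= 0.5 / n + 1e-12
    def test_constant_sample_against_continuous_model(self):
        x = np.full(100, 2.0)
        fit = self._fit(2.0, 1.0)
        gap = 1.0 - (1.0 - (2.0 / 1.0) ** (1.0 - 2.0))  # 1 - F(2) = 0.5
        assert ks_distance(x, fit) >= gap - 1e-12

    def test_empty_tail_is_an_error(self):
        with pytest.raises(ValueError):
            ks_distance(np.array([1.0, 2.0]), self._fit(2.0, xmin=10.0))


class TestFitPowerLaw:
    def test_clean_sample_keeps_low_threshold_with_exact_mle(self):
        x = sample_power_law(50_000, 2.5, 1, discrete=True, seed=4)
        fit = fit_power_law(x, discrete=True, method="exact")
        assert fit.xmin <= 3
        assert fit.params["alpha"] == pytest.approx(2.5, abs=0.05)

    def test_spliced_sample_detects_transition_near_twenty(self):
        """Exponential body below 20 + power-law tail above: the KS search
        should place x_min near the splice point."""
        for seed in [0, 1]:
            rng = np.random.default_rng(seed)
            body = draw_exponential_discrete(rng, 8000, 0.15, 1)
            body = body[body < 20]
            tail = sample_power_law(2000, 2.5, 20, discrete=True, seed=seed)
            fit = fit_power_law(np.concatenate([body, tail]), discrete=True)
            assert 10 <= fit.xmin <= 30

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law(np.array([2.0]))

    def test_few_distinct_values_warns(self):
        with pytest.warns(UserWarning, match="distinct"):
            fit_power_law(np.array([1, 1, 2, 2, 3, 3] * 10, dtype=float), discrete=True)


class TestAlternativeFits:
    def test_exponential_closed_form_recovery(self):
        # tail mean xmin + 2 gives lambda = 0.5
        x = sample_exponential_tail(50_000, 0.5, xmin=2.0, seed=1)
        fit = fit_exponential(x, 2.0)
        assert fit.params["lambda"] == pytest.approx(0.5, abs=3 * fit.params["lambda_se"])

    def test_lognormal_recovery_untruncated(self):
        x = sample_lognormal_tail(50_000, 1.0, 0.8, xmin=0.0, seed=1)
        fit = fit_lognormal(x, 0.0)
        assert fit.params["mu"] == pytest.approx(1.0, abs=0.03)
        assert fit.params["sigma"] == pytest.approx(0.8, abs=0.03)

    def test_lognormal_truncated_recovery(self):
        x = sample_lognormal_tail(30_000, 1.0, 0.8, xmin=2.5, seed=2)
        fit = fit_lognormal(x, 2.5)
        assert fit.params["mu"] == pytest.approx(1.0, abs=4 * fit.params["mu_se"])
        assert fit.params["sigma"] == pytest.approx(0.8, abs=4 * fit.params["sigma_se"])

    def test_degenerate_tails_raise(self):
        with pytest.raises(ValueError):
            fit_exponential(np.full(20, 3.0), 3.0)
        with pytest.raises(ValueError):
            fit_lognormal(np.full(20, 3.0), 1.0)


class TestBootstrapGof:
    def test_correctly_specified_model_rarely_rejects(self):
        ok = 0
        for seed in range(10):
            x = sample_power_law(400, 2.5, 1, discrete=True, seed=100 + seed)
            fit = fit_power_law(x, discrete=True)
            ok += bootstrap_gof(x, fit, n_reps=100, seed=seed).p_value > 0.05
        assert ok >= 9

    def test_gross_misspecification_is_rejected(self):
        # exponential family fitted to heavy power-law data: KS is extreme
        x = sample_power_law(2000, 2.5, 1, discrete=True, seed=0)
        fit = fit_exponential(x, 1.0, discrete=True)
        res = bootstrap_gof(x, fit, n_reps=100, seed=0)
        assert res.p_value < 0.05
        assert res.n_fail_to_reject <= res.n_reps

    def test_result_is_reproducible_and_counts_consistent(self):
        x = sample_power_law(300, 2.5, 1, discrete=True, seed=5)
        fit = fit_power_law(x, discrete=True)
        a = bootstrap_gof(x, fit, n_reps=50, seed=11)
        b = bootstrap_gof(x, fit, n_reps=50, seed=11)
        assert a.p_value == b.p_value
        assert a.n_fail_to_reject == b.n_fail_to_reject
        assert 0 <= a.p_value <= 1 and a.n_fail_to_reject <= a.n_reps

    def test_rejects_bad_rep_count(self):
        x = sample_power_law(100, 2.5, 1, discrete=True, seed=1)
        fit = fit_power_law(x, discrete=True)
        with pytest.raises(ValueError):
            bootstrap_gof(x, fit, n_reps=0)


class TestLikelihoodRatio:
    def test_identical_fits_give_zero_ratio_unit_p(self):
        x = sample_power_law(500, 2.5, 1, discrete=True, seed=2)
        fit = fit_power_law(x, discrete=True)
        res = likelihood_ratio(x, fit, fit)
        assert res.log_ratio == 0.0 and res.p_value == 1.0

    def test_power_law_data_favor_power_law_over_exponential(self):
        x = sample_power_law(50_000, 2.5, 1, discrete=True, seed=7)
        pl = fit_power_law(x, discrete=True)
        ex = fit_exponential(x, pl.xmin, discrete=True)
        res = likelihood_ratio(x, pl, ex)
        assert res.log_ratio > 0 and res.p_value < 0.01

    def test_exponential_data_favor_exponential_symmetrically(self):
        # compared over the full support, where the exponential body is visible
        rng = np.random.default_rng(8)
        x = draw_exponential_discrete(rng, 50_000, 0.19, 1)
        pl = fit_power_law(x, discrete=True, xmin=1)
        ex = fit_exponential(x, 1, discrete=True)
        res = likelihood_ratio(x, pl, ex)
        assert res.log_ratio < 0 and res.p_value < 0.01

    def test_mismatched_thresholds_rejected(self):
        x = sample_power_law(500, 2.5, 1, discrete=True, seed=3)
        pl = fit_power_law(x, discrete=True)
        ex = fit_exponential(x, pl.xmin + 1, discrete=True)
        with pytest.raises(ValueError, match="xmin"):
            likelihood_ratio(x, pl, ex)


class TestClassify:
    def test_lognormal_data_never_significantly_certify_power_law(self):
        """Log-normal degree data may locally mimic a power law, but the
        likelihood-ratio test must never significantly favor the power law
        over the log-normal truth."""
        from malnet._sampling import draw_lognormal_discrete

        for seed in range(3):
            rng = np.random.default_rng([9, seed])
            x = draw_lognormal_discrete(rng, 10_000, 0.57, 1.85, 1)
            v = classify_network(x, n_reps=50, seed=seed)
            fit, lrt = v.alternatives["lognormal"]
            assert not (lrt.log_ratio > 0 and lrt.p_value < 0.05)

    def test_verdict_attaches_all_fits_and_tests(self):
        x = sample_power_law(1000, 2.5, 1, discrete=True, seed=4)
        v = classify_network(x, n_reps=50, seed=1)
        assert v.verdict in ("scale_free", "not_scale_free", "inconclusive")
        assert v.power_law.family == "power_law"
        assert set(v.alternatives) == {"exponential", "lognormal"}
        assert 0 <= v.gof.p_value <= 1
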