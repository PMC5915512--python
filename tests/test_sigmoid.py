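"""Supra-threshold curves, sigmoid/linear fits, AICc selection, thresholds."""

import math

import numpy as np
import pytest

from predecline.sigmoid import (
    NonIdentifiedError,
    ThresholdCurve,
    build_threshold_curve,
    compare_models_aicc,
    estimate_threshold,
    evaluate_sigmoid,
    fit_linear,
    fit_sigmoid,
)


def brute_force_curve(b, q, min_tail):
    """Independent oracle: direct loop over candidate thresholds."""
    out = []
    for t in sorted(set(b)):
        tail = [qi for bi, qi in zip(b, q) if bi >= t]
        if len(tail) >= min_tail:
            out.append((t, float(np.mean(tail)), len(tail)))
    return out


class TestThresholdCurve:
    def test_matches_brute_force_oracle(self, rng):
        b = rng.uniform(0.9, 1.6, 40)
        q = rng.normal(-1.0, 1.0, 40)
        curve = build_threshold_curve(b, q, min_tail=4)
        expected = brute_force_curve(b, q, 4)
        assert len(curve) == len(expected)
        for (t, m, k), ct, cm, ck in zip(
            expected, curve.thresholds, curve.mean_response, curve.tail_count
        ):
            assert ct == t
            assert cm == pytest.approx(m)
            assert ck == k

    def test_step_function_response(self):
        """Change dropping to -3 exactly at c*: supra-threshold means equal
        -3 for every candidate at or beyond c*."""
        b = np.linspace(1.0, 2.0, 21)
        c_star = 1.5
        q = np.where(b >= c_star, -3.0, 0.0)
        curve = build_threshold_curve(b, q, min_tail=1)
        at_or_above = curve.thresholds >= c_star
        np.testing.assert_allclose(curve.mean_response[at_or_above], -3.0)

    def test_counting_and_min_tail_extremes(self, rng):
        b = rng.permutation(np.linspace(0, 1, 15))
        q = rng.normal(size=15)
        assert len(build_threshold_curve(b, q, min_tail=1)) == 15
        single = build_threshold_curve(b, q, min_tail=15)
        assert len(single) == 1
        assert single.thresholds[0] == b.min()
        with pytest.raises(ValueError, match="min_tail"):
            build_threshold_curve(b[:3], q[:3], min_tail=5)

    def test_tail_counts_non_increasing(self, default_cohort, cluster_change):
        curve = build_threshold_curve(
            default_cohort["florbetapir_suvr"].to_numpy(), cluster_change
        )
        assert (np.diff(curve.tail_count) <= 0).all()


class TestEvaluateSigmoid:
    def test_midpoint_and_asymptote_identities(self):
        assert evaluate_sigmoid((-3, 3, 1.228, 0.02), 1.228) == pytest.approx(-1.5)
        assert evaluate_sigmoid((2.0, -4.0, 0.0, 1.0), 0.0) == pytest.approx(0.0)
        assert evaluate_sigmoid((2.0, -4.0, 0.0, 1.0), -50.0) == pytest.approx(2.0)
        assert evaluate_sigmoid((2.0, -4.0, 0.0, 1.0), 50.0) == pytest.approx(-2.0)

    def test_rejects_nonpositive_steepness(self):
        with pytest.raises(ValueError, match="d"):
            evaluate_sigmoid((0, 1, 0, 0.0), 1.0)


def _noiseless_curve(a, b, c, d, lo, hi, n=200):
    x = np.linspace(lo, hi, n)
    y = evaluate_sigmoid((a, b, c, d), x)
    return ThresholdCurve("x", x, y, np.arange(n, 0, -1))


class TestFitSigmoid:
    @pytest.mark.parametrize(
        "params,lo,hi",
        [((-3, 3, 1.228, 0.02), 0.9, 1.6), ((0, -3.4, 45.0, 3.0), 10, 100)],
    )
    def test_noiseless_parameter_recovery(self, params, lo, hi):
        curve = _noiseless_curve(*params, lo, hi)
        fit = fit_sigmoid(curve)
        assert fit.converged
        assert abs(fit.c - params[2]) <= 1e-6
        assert fit.d == pytest.approx(params[3], rel=1e-4)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response_not_identified(self):
        curve = ThresholdCurve("x", np.linspace(0, 1, 10), np.zeros(10), np.arange(10, 0, -1))
        with pytest.raises(NonIdentifiedError):
            fit_sigmoid(curve)

    def test_too_few_points_rejected(self):
        curve = _noiseless_curve(-3, 3, 1.2, 0.02, 0.9, 1.6, n=5)
        with pytest.raises(ValueError, match="6"):
            fit_sigmoid(curve)

    def test_sigmoid_rss_never_exceeds_linear(self, rng):
        """The multi-start includes a near-linear configuration, so the
        sigmoid fit is at least as good as the straight line."""
        for _ in range(5):
            x = np.sort(rng.uniform(0, 1, 30))
            y = rng.normal(2 * x - 1, 0.3)
            curve = ThresholdCurve("x", x, y, np.arange(30, 0, -1))
            assert fit_sigmoid(curve).rss <= fit_linear(curve).rss * (1 + 1e-8)


class TestFitLinear:
    def test_perfect_line(self):
        x = np.linspace(0, 1, 12)
        curve = ThresholdCurve("x", x, 2 * x + 1, np.arange(12, 0, -1))
        fit = fit_linear(curve)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)
        assert fit.r_squared == pytest.approx(1.0)

    def test_aicc_matches_hand_formula(self, rng):
        x = np.linspace(0, 1, 10)
        y = 2 * x + rng.normal(0, 0.2, 10)
        curve = ThresholdCurve("x", x, y, np.arange(10, 0, -1))
        fit = fit_linear(curve)
        n, k = 10, 3
        expected = n * math.log(fit.rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert fit.aicc == pytest.approx(expected)


class TestModelComparison:
    def test_equal_aicc_gives_even_odds(self):
        lin = fit_linear(_noiseless_curve(0, 1, 0.5, 5.0, 0, 1, n=20))
        sig = fit_sigmoid(_noiseless_curve(0, 1, 0.5, 5.0, 0, 1, n=20))
        sig.aicc = lin.aicc  # force a tie
        cmp_ = compare_models_aicc(lin, sig)
        assert cmp_.prob_correct == pytest.approx(0.5)
        assert cmp_.prob_linear + cmp_.prob_sigmoid == pytest.approx(1.0)

    def test_sigmoid_generated_data_prefers_sigmoid(self, rng):
        x = np.linspace(0.9, 1.6, 100)
        y = evaluate_sigmoid((-3, 3, 1.2, 0.05), x) + rng.normal(0, 0.05, 100)
        curve = ThresholdCurve("x", x, y, np.arange(100, 0, -1))
        cmp_ = compare_models_aicc(fit_linear(curve), fit_sigmoid(curve))
        assert cmp_.preferred == "sigmoid"
        assert cmp_.prob_correct > 0.95

    def test_linear_generated_data_prefers_linear(self, rng):
        x = np.linspace(0, 1, 50)
        y = 1.5 * x - 1 + rng.normal(0, 0.05, 50)
        curve = ThresholdCurve("x", x, y, np.arange(50, 0, -1))
        cmp_ = compare_models_aicc(fit_linear(curve), fit_sigmoid(curve))
        assert cmp_.preferred == "linear"

    def test_mismatched_lengths_rejected(self):
        lin = fit_linear(_noiseless_curve(0, 1, 0.5, 0.1, 0, 1, n=20))
        sig = fit_sigmoid(_noiseless_curve(0, 1, 0.5, 0.1, 0, 1, n=30))
        with pytest.raises(ValueError, match="different data"):
            compare_models_aicc(lin, sig)


class TestThresholdEstimate:
    def test_noiseless_ci_width_vanishes(self):
        fit = fit_sigmoid(_noiseless_curve(-3, 3, 1.228, 0.02, 0.9, 1.6))
        est = estimate_threshold(fit)
        assert est.ci95[1] - est.ci95[0] == pytest.approx(0.0, abs=1e-8)
        assert not est.extrapolated

    def test_extrapolation_flagged(self, rng):
        # data covering only the left asymptote and the rise; inflection
        # beyond the observed range
        x = np.linspace(0, 1, 30)
        y = evaluate_sigmoid((0, -3, 1.4, 0.3), x) + rng.normal(0, 0.001, 30)
        fit = fit_sigmoid(ThresholdCurve("x", x, y, np.arange(30, 0, -1)))
        if fit.c > 1.0:  # fit lands beyond the data, as constructed
            assert estimate_threshold(fit).extrapolated

    def test_nonconverged_fit_rejected(self):
        fit = fit_sigmoid(_noiseless_curve(-3, 3, 1.228, 0.02, 0.9, 1.6))
        fit.converged = False
        with pytest.raises(ValueError, match="non-converged"):
            estimate_threshold(fit)

    def test_ci_coverage_near_nominal(self):
        """Monte-Carlo: the asymptotic 95% CI for c covers the generative
        inflection in at least 89/100 seeded replicates."""
        gen_c = 45.0
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            x = np.linspace(10, 100, 60)
            y = evaluate_sigmoid((0, -3.4, gen_c, 3.0), x) + rng.normal(0, 0.08, 60)
            fit = fit_sigmoid(ThresholdCurve("x", x, y, np.arange(60, 0, -1)))
            lo, hi = fit.c_ci95
            hits += lo <= gen_c <= hi
        assert hits >= 89
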