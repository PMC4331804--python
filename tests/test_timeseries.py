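"""Unit and property tests for the AR-vs-constant time-dependence test."""

import math

import numpy as np
import pytest
from scipy import stats

from nfapin.timeseries import (ARFit, ConstantFit, InvalidOrderError,
                               RankDeficientDesignError, build_design,
                               call_dependence, dependence_table,
                               f_statistic, fit_ar, fit_constant,
                               likelihood_ratio, max_test_order)
from nfapin.synthetic import gen_ar_series, gen_null_series

from oracles import ols_gauss


class TestDesign:
    def test_lag_one_layout(self):
        y, design = build_design([1, 2, 3, 4], 1)
        np.testing.assert_array_equal(y, [2, 3, 4])
        np.testing.assert_array_equal(design, [[1, 1], [1, 2], [1, 3]])

    @pytest.mark.parametrize("m, p, shape", [
        (5, 2, (3, 3)),
        (36, 17, (19, 18)),  # largest admissible order at M = 36
        (36, 1, (35, 2)),
    ])
    def test_dimensions(self, m, p, shape, rng):
        y, design = build_design(rng.normal(size=m), p)
        assert design.shape == shape
        assert y.shape == (shape[0],)

    @pytest.mark.parametrize("m, p", [(4, 2), (36, 18), (10, 0), (10, -1)])
    def test_inadmissible_order_rejected(self, m, p, rng):
        with pytest.raises(InvalidOrderError):
            build_design(rng.normal(size=m), p)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            build_design([1.0, np.nan, 2.0, 3.0], 1)


class TestFits:
    def test_perfect_linear_recursion(self):
        fit = fit_ar([1, 2, 3, 4], 1)
        np.testing.assert_allclose(fit.coefficients, [1.0, 1.0], atol=1e-10)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-20)

    def test_constant_series_is_rank_deficient(self):
        with pytest.raises(RankDeficientDesignError):
            fit_ar([3.0] * 6, 1)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            m = int(rng.integers(8, 40))
            p = int(rng.integers(1, (m - 1) // 2 + 1))
            x = rng.normal(size=m)
            fit = fit_ar(x, p)
            _, design = build_design(x, p)
            beta, rss = ols_gauss(design, x[p:])
            np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)
            assert fit.residual_variance == pytest.approx(
                rss / (m - p), abs=1e-8)

    def test_constant_fit_arithmetic(self):
        fit = fit_constant([1, 2, 3, 4], 1)
        assert fit.mean == pytest.approx(3.0)
        assert fit.residual_variance == pytest.approx(2 / 3)

    def test_constant_fit_alternating(self):
        # span m = 2..6 holds (10, 0, 10, 0, 10): mean 6, variance
        # ((10-6)^2 * 3 + 6^2 * 2) / 5 = 24
        fit = fit_constant([0, 10, 0, 10, 0, 10], 1)
        assert fit.mean == pytest.approx(6.0)
        assert fit.residual_variance == pytest.approx(24.0)

    def test_constant_fit_flat(self):
        fit = fit_constant([7.5] * 9, 3)
        assert fit.mean == pytest.approx(7.5)
        assert fit.residual_variance == 0.0


class TestLikelihoodRatio:
    def test_equal_fits_give_one(self):
        ar = ARFit(order=1, coefficients=np.array([0.0, 0.0]),
                   residual_variance=2.0)
        const = ConstantFit(mean=0.0, residual_variance=2.0, order_context=1)
        assert likelihood_ratio(ar, const, m=10) == pytest.approx(1.0)

    def test_perfect_ar_fit_gives_zero(self):
        ar = ARFit(order=1, coefficients=np.array([1.0, 1.0]),
                   residual_variance=0.0)
        const = ConstantFit(mean=0.0, residual_variance=2.0, order_context=1)
        assert likelihood_ratio(ar, const, m=10) == 0.0

    def test_arithmetic(self):
        # (0.5 / 2) ** ((m - p)/2) with m - p = 4
        ar = ARFit(order=1, coefficients=np.array([0.0, 0.0]),
                   residual_variance=0.5)
        const = ConstantFit(mean=0.0, residual_variance=2.0, order_context=1)
        assert likelihood_ratio(ar, const, m=5) == pytest.approx(0.0625)

    def test_degenerate_constant_series_raises(self):
        ar = ARFit(order=1, coefficients=np.array([0.0, 0.0]),
                   residual_variance=0.0)
        const = ConstantFit(mean=1.0, residual_variance=0.0, order_context=1)
        with pytest.raises(RankDeficientDesignError):
            likelihood_ratio(ar, const, m=10)


class TestFStatistic:
    def test_arithmetic_against_variance_ratio(self, rng):
        # F = (M - 2p - 1)/p * (s2c/s2 - 1), checked via the fits
        x = rng.normal(size=8)
        f_val, _ = f_statistic(x, 1)
        s2 = fit_ar(x, 1).residual_variance
        s2c = fit_constant(x, 1).residual_variance
        assert f_val == pytest.approx(5.0 * (s2c / s2 - 1.0))

    def test_perfect_fit_rejects_outright(self):
        f_val, pval = f_statistic(np.arange(1.0, 9.0), 1)
        assert math.isinf(f_val)
        assert pval == 0.0

    def test_flat_series_never_rejects(self):
        # tail constant: both models fit exactly, no time information
        f_val, pval = f_statistic([9.0, 1.0, 1.0, 1.0, 1.0, 1.0], 1)
        assert (f_val, pval) == (0.0, 1.0)

    def test_null_size_at_short_series_matches_monte_carlo_truth(self, rng):
        # the F(p, M-2p-1) reference is asymptotic for autoregressive
        # designs: at M=20, alpha=0.05 the exact size is ~0.0384
        # (frozen from a 200,000-replicate simulation oracle)
        n_series, m, truth = 2000, 20, 0.0384
        rate = np.mean([
            f_statistic(gen_null_series(0.0, 1.0, m, rng), 1)[1] < 0.05
            for _ in range(n_series)])
        se = math.sqrt(truth * (1 - truth) / n_series)
        assert abs(rate - truth) < 3 * se

    def test_null_calibration_at_long_series(self, rng):
        # at M=200 the asymptotic F null is accurate and p-values are
        # close to uniform
        n_series, alpha, m = 1000, 0.05, 200
        pvals = np.array([f_statistic(gen_null_series(0.0, 1.0, m, rng), 1)[1]
                          for _ in range(n_series)])
        se = math.sqrt(alpha * (1 - alpha) / n_series)
        assert abs((pvals < alpha).mean() - alpha) < 3 * se
        assert stats.kstest(pvals, "uniform").pvalue > 0.001

    def test_two_forms_of_the_statistic_agree(self, rng):
        # F from the variance ratio equals the Lambda form
        for _ in range(200):
            m = int(rng.integers(8, 40))
            p = int(rng.integers(1, max_test_order(m) + 1))
            x = rng.normal(size=m)
            f_val, _ = f_statistic(x, p)
            lam = likelihood_ratio(fit_ar(x, p), fit_constant(x, p), m)
            via_lambda = (m - 2 * p - 1) / p * (lam ** (-2 / (m - p)) - 1)
            assert f_val == pytest.approx(via_lambda, abs=1e-10, rel=1e-10)

    def test_nesting_makes_f_nonnegative(self, rng):
        for _ in range(200):
            m = int(rng.integers(8, 30))
            p = int(rng.integers(1, max_test_order(m) + 1))
            x = rng.normal(size=m)
            s2 = fit_ar(x, p).residual_variance
            s2c = fit_constant(x, p).residual_variance
            assert s2c >= s2 - 1e-12
            assert f_statistic(x, p)[0] >= 0.0

    def test_shift_scale_invariance(self, rng):
        x = rng.normal(size=24)
        f_ref = f_statistic(x, 2)[0]
        for a, b in [(2.0, 0.0), (-1.0, 5.0), (0.001, -3.0), (100.0, 7.0)]:
            assert f_statistic(a * x + b, 2)[0] == pytest.approx(
                f_ref, abs=1e-8, rel=1e-8)


class TestCallDependence:
    def test_constant_series_called_independent(self):
        call = call_dependence([2.0] * 12, alpha=0.01)
        assert not call.time_dependent
        assert call.min_pvalue == 1.0
        assert call.best_order is None

    def test_perfect_trend_called_dependent(self):
        call = call_dependence(np.arange(1.0, 37.0), alpha=0.01)
        assert call.time_dependent
        assert call.min_pvalue == 0.0
        assert call.best_order == 1

    def test_scans_all_admissible_orders(self, rng):
        call = call_dependence(rng.normal(size=36), alpha=0.01)
        assert set(call.per_order) == set(range(1, 18))

    def test_min_pvalue_is_the_minimum(self, rng):
        call = call_dependence(rng.normal(size=20), alpha=0.05)
        assert call.min_pvalue == min(p for _, p in call.per_order.values())

    def test_bonferroni_is_more_conservative(self, rng):
        flips = 0
        for _ in range(50):
            x = rng.normal(size=16)
            plain = call_dependence(x, alpha=0.2)
            bonf = call_dependence(x, alpha=0.2, bonferroni=True)
            assert plain.time_dependent or not bonf.time_dependent
            flips += plain.time_dependent and not bonf.time_dependent
        assert flips > 0  # the flag actually bites somewhere

    def test_power_against_ar1_signal(self, rng):
        # observed power 0.99 over these 200 seeded replicates
        n_rep = 200
        hits = sum(
            call_dependence(
                gen_ar_series([0.0, 0.9], 1.0, 36, rng), alpha=0.05
            ).time_dependent
            for _ in range(n_rep))
        assert hits / n_rep > 0.9

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            call_dependence([1.0, 2.0, 1.0, 2.0], alpha=1.5)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            call_dependence([1.0, 2.0, 3.0])


def test_dependence_table_shape_and_calls(rng):
    import pandas as pd

    frame = pd.DataFrame(
        {f"t{t}": v for t, v in enumerate(np.vstack(
            [np.arange(36.0), np.full(36, 3.0), rng.normal(size=36)]).T)},
        index=["trend", "flat", "noise"])
    table = dependence_table(frame, alpha=0.01)
    assert list(table.index) == ["trend", "flat", "noise"]
    assert bool(table.loc["trend", "time_dependent"])
    assert not bool(table.loc["flat", "time_dependent"])
    assert table.loc["flat", "min_pvalue"] == 1.0
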