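"""Solver tests: check loss, objective, oracle agreement, inference."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linprog

from adherence_qreg import (
    QuantReg,
    RankDeficientError,
    check_loss,
    exact_small_fit,
    objective_value,
)

from conftest import small_instance


class TestCheckLoss:
    @pytest.mark.parametrize("tau", [0.1, 0.25, 0.5, 0.9])
    def test_zero_residual(self, tau):
        assert check_loss(0.0, tau) == 0.0

    @pytest.mark.parametrize("r", [-3.0, 2.0])
    def test_median_is_half_absolute(self, r):
        assert check_loss(r, 0.5) == pytest.approx(abs(r) / 2)

    def test_asymmetric_slopes(self):
        assert check_loss(-1.0, 0.25) == pytest.approx(0.75)
        assert check_loss(1.0, 0.25) == pytest.approx(0.25)

    @pytest.mark.parametrize("tau", [0.0, 1.0, -0.2, 1.5])
    def test_tau_domain(self, tau):
        with pytest.raises(ValueError):
            check_loss(1.0, tau)

    @given(r=st.floats(-1e6, 1e6), tau=st.floats(0.01, 0.99))
    @settings(max_examples=50, derandomize=True)
    def test_piecewise_linear_form(self, r, tau):
        expected = tau * r if r >= 0 else (tau - 1.0) * r
        assert check_loss(r, tau) == pytest.approx(expected)
        assert check_loss(r, tau) >= 0.0


class TestObjective:
    def test_perfect_fit_zero(self, rng):
        x, _ = small_instance(rng, n=8, p=2)
        beta = np.array([1.0, -2.0])
        assert objective_value(beta, x, x @ beta, 0.3) == 0.0

    def test_intercept_only_hand_sum(self):
        y = np.array([1.0, 2.0, 3.0])
        assert objective_value([2.0], np.ones((3, 1)), y, 0.5) == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            x, y = small_instance(rng)
            beta = rng.normal(size=x.shape[1])
            tau = float(rng.uniform(0.05, 0.95))
            naive = sum(check_loss(yi - xi @ beta, tau) for xi, yi in zip(x, y))
            assert objective_value(beta, x, y, tau) == pytest.approx(naive, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            objective_value([1.0, 2.0], np.ones((3, 1)), np.zeros(3), 0.5)


class TestFit:
    def test_intercept_only_is_sample_quantile(self, rng):
        y = rng.normal(size=41)
        for tau in (0.25, 0.5, 0.8):
            fit = QuantReg(y, np.ones((41, 1))).fit(tau)
            target = objective_value([np.quantile(y, tau)], np.ones((41, 1)), y, tau)
            assert fit.objective == pytest.approx(target, rel=1e-9)

    def test_exact_line_recovered(self, rng):
        x, _ = small_instance(rng, n=10, p=2)
        y = x @ np.array([1.5, -0.7])
        fit = QuantReg(y, x).fit(0.4)
        assert fit.objective == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(fit.params, [1.5, -0.7], atol=1e-8)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            x, y = small_instance(rng)
            tau = float(rng.choice([0.1, 0.25, 0.5, 0.75, 0.9]))
            model = QuantReg(y, x)
            assert model.fit(tau).objective == pytest.approx(
                model.fit_exact(tau).objective, abs=1e-8
            )

    def test_median_equals_half_l1_linprog(self, rng):
        """tau = 0.5 objective equals half the LAD optimum (independent LP)."""
        for _ in range(5):
            x, y = small_instance(rng, n=10, p=2)
            n, p = x.shape
            # min 1'(u+v) s.t. X b + u - v = y
            c = np.r_[np.zeros(p), np.ones(2 * n)]
            a_eq = np.hstack([x, np.eye(n), -np.eye(n)])
            lp = linprog(c, A_eq=a_eq, b_eq=y,
                         bounds=[(None, None)] * p + [(0, None)] * (2 * n))
            assert lp.status == 0
            fit = QuantReg(y, x).fit(0.5)
            assert fit.objective == pytest.approx(0.5 * lp.fun, abs=1e-8)

    def test_subgradient_condition(self, rng):
        for _ in range(20):
            x, y = small_instance(rng)
            n, p = x.shape
            tau = float(rng.uniform(0.1, 0.9))
            fit = QuantReg(y, x).fit(tau)
            r = y - x @ fit.params
            assert np.sum(r < -1e-8) <= n * tau + 1e-9
            assert n * tau <= np.sum(r <= 1e-8) + p + 1e-9

    def test_scale_and_shift_equivariance(self, rng):
        x, y = small_instance(rng, n=12, p=2)
        fit = QuantReg(y, x).fit(0.3)
        scaled = QuantReg(5.0 * y, x).fit(0.3)
        np.testing.assert_allclose(scaled.params, 5.0 * fit.params, atol=1e-8)
        shifted_x = x.copy()
        shifted_x[:, 1] += 10.0
        shifted = QuantReg(y, shifted_x).fit(0.3)
        np.testing.assert_allclose(shifted.params[1], fit.params[1], atol=1e-8)
        np.testing.assert_allclose(
            shifted.params[0], fit.params[0] - 10.0 * fit.params[1], atol=1e-7
        )

    def test_response_outlier_robustness(self, rng):
        x = np.column_stack([np.ones(60), rng.normal(size=60)])
        y = x @ np.array([1.0, 0.5]) + rng.normal(scale=0.2, size=60)
        fit = QuantReg(y, x).fit(0.5)
        k = int(np.argmax(y - x @ fit.params))  # already above the fit
        y2 = y.copy()
        y2[k] += 1e6
        fit2 = QuantReg(y2, x).fit(0.5)
        np.testing.assert_allclose(fit2.params, fit.params, atol=1e-7)

    def test_intercept_monotone_in_tau(self, rng):
        y = rng.normal(size=30)
        model = QuantReg(y, np.ones((30, 1)))
        betas = [model.fit(t).params[0] for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert np.all(np.diff(betas) >= -1e-10)

    def test_objective_recomputation_invariant(self, rng):
        x, y = small_instance(rng, n=11, p=3)
        fit = QuantReg(y, x).fit(0.35)
        assert fit.objective == pytest.approx(
            objective_value(fit.params, x, y, 0.35), abs=1e-10
        )

    def test_rank_deficiency_names_columns(self, rng):
        x = np.column_stack([np.ones(20), rng.normal(size=20)])
        x = np.column_stack([x, x[:, 1]])  # duplicate column
        with pytest.raises(RankDeficientError, match="x2|x1"):
            QuantReg(rng.normal(size=20), x)

    def test_extreme_tau_clipped_with_warning(self, rng):
        y = rng.normal(size=20)
        model = QuantReg(y, np.ones((20, 1)))
        with pytest.warns(UserWarning, match="clipped"):
            fit = model.fit(0.001)
        assert fit.tau == pytest.approx(0.5 / 20)


class TestExactSmallFit:
    def test_refuses_large_instances(self, rng):
        x, y = small_instance(rng, n=20, p=2)
        with pytest.raises(ValueError, match="refused"):
            exact_small_fit(x, y, 0.5)

    def test_hand_median_instance(self):
        fit = exact_small_fit(np.ones((3, 1)), np.array([1.0, 2.0, 3.0]), 0.5)
        assert fit.objective == pytest.approx(1.0)


class TestBootstrap:
    def test_b2_interval_is_min_max(self, rng):
        x, y = small_instance(rng, n=15, p=2)
        fit = QuantReg(y, x).fit(0.5)
        ci = fit.bootstrap_ci(n_boot=2, seed=3)
        est = fit._boot_estimates
        np.testing.assert_allclose(ci["ci_low"], est.min(axis=0))
        np.testing.assert_allclose(ci["ci_high"], est.max(axis=0))

    def test_seed_determinism(self, rng):
        x, y = small_instance(rng, n=15, p=2)
        fit = QuantReg(y, x).fit(0.5)
        ci1 = fit.bootstrap_ci(n_boot=25, seed=11)
        ci2 = QuantReg(y, x).fit(0.5).bootstrap_ci(n_boot=25, seed=11)
        np.testing.assert_array_equal(ci1.to_numpy(), ci2.to_numpy())

    def test_rejects_single_replicate(self, rng):
        x, y = small_instance(rng, n=15, p=2)
        with pytest.raises(ValueError):
            QuantReg(y, x).fit(0.5).bootstrap_ci(n_boot=1)


class TestPredict:
    def test_reference_row_gives_intercept(self, rng):
        x, y = small_instance(rng, n=15, p=3)
        fit = QuantReg(y, x).fit(0.4)
        row = np.zeros(3)
        row[0] = 1.0
        assert fit.predict(row)[0] == pytest.approx(fit.params[0])

    def test_observed_row_equals_fitted_value(self, rng):
        x, y = small_instance(rng, n=15, p=2)
        fit = QuantReg(y, x).fit(0.4)
        assert fit.predict(x[3])[0] == pytest.approx((x @ fit.params)[3])

    def test_clamp_flag(self, rng):
        x, y = small_instance(rng, n=15, p=2)
        fit = QuantReg(y, x).fit(0.4)
        assert fit.predict(np.array([1.0, 1e6]), clamp=True)[0] in (0.0, 1.0)

    def test_column_mismatch(self, rng):
        x, y = small_instance(rng, n=15, p=2)
        fit = QuantReg(y, x).fit(0.4)
        with pytest.raises(ValueError):
            fit.predict(np.ones(5))


def test_agrees_with_statsmodels_objective(rng):
    """Independent implementation cross-check on a moderate instance."""
    from statsmodels.regression.quantile_regression import QuantReg as SMQuantReg

    x = np.column_stack([np.ones(300), rng.normal(size=(300, 2))])
    y = x @ np.array([0.5, 0.1, -0.2]) + rng.normal(scale=0.3, size=300)
    for tau in (0.2, 0.5, 0.8):
        mine = QuantReg(y, x).fit(tau)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = SMQuantReg(y, x).fit(q=tau)
        ref_obj = objective_value(ref.params, x, y, tau)
        assert mine.objective <= ref_obj + 1e-6
        np.testing.assert_allclose(mine.params, ref.params, atol=5e-3)
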