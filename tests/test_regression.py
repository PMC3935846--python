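"""Quantile regression engine: losses, fits, oracles, AIC selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from conftest import exhaustive_quantile_fit, pinball
from qsdm import (
    GridQuantileRegressor,
    SyntheticTruth,
    aic_quantile_model,
    check_loss,
    coefficient_paths,
    default_tau_grid,
    fit_quantile_grid,
    fit_single_quantile,
    generate_observations,
    predict_quantiles,
    rearrange_quantiles,
    sample_quantile,
    select_model,
)
from qsdm.regression import QuantileFitGrid, design_matrix


class TestCheckLoss:
    @pytest.mark.parametrize(
        "residuals, tau, expected",
        [
            ([0.0, 0.0, 0.0], 0.3, 0.0),
            ([1.0, -1.0], 0.5, 1.0),
            ([2.0, -3.0], 0.25, 0.25 * 2 + 0.75 * 3),
            ([], 0.5, 0.0),
        ],
    )
    def test_direct_evaluation(self, residuals, tau, expected):
        assert check_loss(residuals, tau) == pytest.approx(expected)

    def test_rejects_boundary_tau(self):
        with pytest.raises(ValueError, match="tau"):
            check_loss([1.0], 0.0)
        with pytest.raises(ValueError, match="tau"):
            check_loss([1.0], 1.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        r=hnp.arrays(
            float,
            st.integers(1, 20),
            # keep residual magnitudes away from the underflow range
            elements=st.floats(-1e6, 1e6).map(lambda v: 0.0 if abs(v) < 1e-9 else v),
        ),
        tau=st.floats(0.01, 0.99),
    )
    def test_nonnegative_and_zero_iff_zero_residuals(self, r, tau):
        loss = check_loss(r, tau)
        assert loss >= 0.0
        assert (loss == 0.0) == bool((r == 0).all())


class TestSampleQuantile:
    @pytest.mark.parametrize(
        "y, tau, expected",
        [
            ([1, 2, 3, 4, 5], 0.5, 3.0),  # odd-n median
            ([0, 10], 0.25, 0.0),  # loss minimized at the lower point
            ([0, 10], 0.5, 0.0),  # interval minimizer: lower endpoint
            ([5.0], 0.9, 5.0),
        ],
    )
    def test_known_values(self, y, tau, expected):
        assert sample_quantile(y, tau) == expected

    def test_rejects_empty(self):
        with pytest.raises(ValueError, match="empty"):
            sample_quantile([], 0.5)

    def test_matches_brute_force_argmin(self):
        rng = np.random.default_rng(7)
        y = rng.normal(10, 4, size=30)
        tau = 0.7
        losses = [pinball(y - q, tau) for q in y]
        best = y[int(np.argmin(losses))]
        assert sample_quantile(y, tau) == pytest.approx(best)

    @settings(max_examples=60, derandomize=True)
    @given(
        y=hnp.arrays(float, st.integers(2, 40), elements=st.floats(-100, 100)),
        tau=st.floats(0.05, 0.95),
    )
    def test_is_a_check_loss_minimizer_over_candidates(self, y, tau):
        q = sample_quantile(y, tau)
        loss_q = pinball(y - q, tau)
        best = min(pinball(y - c, tau) for c in y)
        assert loss_q <= best + 1e-9 * max(1.0, best)


class TestFitSingleQuantile:
    def test_constant_response_intercept_only(self):
        data = pd.DataFrame(
            {"sample_id": range(5), "velocity": [0.1] * 5, "inundation": [1.0] * 5,
             "biomass": [5.0] * 5}
        )
        beta, loss = fit_single_quantile(data, terms=(), tau=0.3)
        assert beta[0] == pytest.approx(5.0)
        assert loss == pytest.approx(0.0, abs=1e-10)

    def test_intercept_only_median_equals_sample_quantile(self, small_observations):
        data = small_observations.iloc[:201]  # odd n: unique median
        beta, _ = fit_single_quantile(data, terms=(), tau=0.5)
        assert beta[0] == pytest.approx(sample_quantile(data.biomass, 0.5), abs=1e-8)

    def test_toy_table_matches_vertex_oracle(self, toy_table):
        tau = 0.75
        D = design_matrix(
            toy_table[["velocity", "inundation"]].to_numpy()
        )
        y = toy_table.biomass.to_numpy()
        _, oracle_loss = exhaustive_quantile_fit(D, y, tau)
        beta, loss = fit_single_quantile(toy_table, tau=tau)
        assert loss <= oracle_loss * (1 + 1e-6) + 1e-12
        assert loss == pytest.approx(oracle_loss, rel=1e-6)

    def test_subgradient_optimality_intercept_only(self, small_observations):
        for tau in (0.25, 0.5, 0.9):
            beta, _ = fit_single_quantile(small_observations, terms=(), tau=tau)
            r = small_observations.biomass.to_numpy() - beta[0]
            n = r.size
            assert (r < 0).sum() <= n * tau + 1e-9
            assert (r <= 0).sum() >= n * tau - 1e-9

    def test_rank_deficient_design_rejected(self):
        data = pd.DataFrame(
            {"sample_id": range(6), "velocity": np.linspace(0, 1, 6),
             "inundation": np.zeros(6), "biomass": np.arange(6.0)}
        )
        with pytest.raises(ValueError, match="rank deficient"):
            fit_single_quantile(data, terms=("velocity", "inundation", "interaction"))

    def test_matches_statsmodels_on_random_data(self, small_observations):
        """Independent cross-check: IRLS solution cannot beat the LP loss."""
        statsmodels = pytest.importorskip("statsmodels.api")
        data = small_observations
        D = design_matrix(data[["velocity", "inundation"]].to_numpy())
        y = data.biomass.to_numpy()
        for tau in (0.3, 0.5, 0.8):
            beta, loss = fit_single_quantile(data, tau=tau)
            sm_fit = statsmodels.QuantReg(y, D).fit(q=tau)
            sm_loss = pinball(y - D @ sm_fit.params, tau)
            assert loss <= sm_loss * (1 + 1e-6)
            assert loss == pytest.approx(sm_loss, rel=1e-3)

    def test_random_instances_match_exhaustive_minimum(self):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            n = int(rng.integers(8, 31))
            x = rng.uniform(0, 1, (n, 2)) * [1.5, 100.0]
            y = rng.uniform(0, 20, n)
            data = pd.DataFrame(
                {"sample_id": range(n), "velocity": x[:, 0],
                 "inundation": x[:, 1], "biomass": y}
            )
            terms = ("velocity", "inundation")
            D = design_matrix(x, terms)
            tau = float(rng.choice([0.1, 0.5, 0.9]))
            _, oracle = exhaustive_quantile_fit(D, y, tau)
            _, loss = fit_single_quantile(data, terms=terms, tau=tau)
            assert loss <= oracle * (1 + 1e-9) + 1e-12


class TestGridFitting:
    def test_default_grid_has_fifty_levels(self):
        taus = default_tau_grid()
        assert taus.size == 50
        assert taus[0] == pytest.approx(0.01)
        assert taus[-1] == pytest.approx(0.99)
        assert np.allclose(np.diff(taus), 0.02)

    def test_singleton_grid_reduces_to_single_fit(self, small_observations):
        grid = fit_quantile_grid(small_observations, taus=[0.5])
        beta, loss = fit_single_quantile(small_observations, tau=0.5)
        np.testing.assert_allclose(grid.coefficients[0], beta, atol=1e-8)
        assert grid.check_loss[0] == pytest.approx(loss)

    def test_estimator_sklearn_interface(self, small_observations):
        X = small_observations[["velocity", "inundation"]].to_numpy()
        y = small_observations.biomass.to_numpy()
        est = GridQuantileRegressor(taus=[0.25, 0.5, 0.75])
        assert est.get_params()["taus"] == [0.25, 0.5, 0.75]
        est.fit(X, y)
        assert est.coef_.shape == (3, 3)
        assert est.intercept_.shape == (3,)
        q = est.predict_quantiles(X[:5])
        assert q.shape == (5, 3)
        np.testing.assert_allclose(est.predict(X[:5]), q[:, 1])

    def test_fit_grid_json_roundtrip(self, small_observations, tmp_path):
        fit = fit_quantile_grid(small_observations, taus=[0.3, 0.7])
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = QuantileFitGrid.from_json(path)
        np.testing.assert_allclose(back.coefficients, fit.coefficients)
        np.testing.assert_allclose(back.taus, fit.taus)
        assert back.terms == fit.terms

    def test_recovers_conditional_median_surface(self, no_suppression_truth):
        """With p0=0, Q(0.5|x) = 0.5·B(x): the fitted surface tracks it closely.

        Individual coefficients are noisy at this n (the raw interaction
        design is collinear), so the check targets the predicted surface,
        which is the statistically stable quantity.
        """
        obs = generate_observations(5000, no_suppression_truth, seed=31)
        fit = fit_quantile_grid(obs, taus=[0.5])
        v, i = np.meshgrid(np.linspace(0, 1.5, 16), np.linspace(0, 100, 21))
        pred = predict_quantiles(fit, v, i)[..., 0]
        truth_surface = 0.5 * no_suppression_truth.bound(v, i)
        rel = np.abs(pred - truth_surface) / truth_surface
        assert np.median(rel) < 0.05
        # coefficients are unbiased but noisy: loose componentwise sanity band
        expected = 0.5 * np.asarray(no_suppression_truth.beta)
        np.testing.assert_allclose(fit.coefficients[0], expected, rtol=0.5)


class TestPredictAndRearrange:
    def test_zero_coefficients_predict_zero(self):
        fit = QuantileFitGrid(
            taus=np.array([0.25, 0.75]), terms=("velocity", "inundation", "interaction"),
            coefficients=np.zeros((2, 4)), check_loss=np.zeros(2), n_obs=10,
        )
        np.testing.assert_array_equal(predict_quantiles(fit, 0.7, 55.0), [0.0, 0.0])

    def test_intercept_only_predicts_constants(self):
        fit = QuantileFitGrid(
            taus=np.array([0.2, 0.8]), terms=(),
            coefficients=np.array([[1.5], [4.0]]), check_loss=np.zeros(2), n_obs=10,
        )
        np.testing.assert_allclose(predict_quantiles(fit, 0.0, 0.0), [1.5, 4.0])

    def test_identity_construction_returns_tau_grid(self):
        taus = default_tau_grid()
        coef = np.column_stack([taus, np.zeros((50, 3))])
        fit = QuantileFitGrid(
            taus=taus, terms=("velocity", "inundation", "interaction"),
            coefficients=coef, check_loss=np.zeros(50), n_obs=100,
        )
        np.testing.assert_allclose(predict_quantiles(fit, 1.0, 50.0), taus)

    def test_rearrange_examples(self):
        np.testing.assert_allclose(
            rearrange_quantiles([1.0, 0.8, 1.2]), [0.8, 1.0, 1.2]
        )
        np.testing.assert_allclose(
            rearrange_quantiles([0.1, 0.2, 0.3]), [0.1, 0.2, 0.3]
        )

    @settings(max_examples=60, derandomize=True)
    @given(q=hnp.arrays(float, st.integers(1, 30), elements=st.floats(-50, 50)))
    def test_rearrange_idempotent_and_multiset_preserving(self, q):
        once = rearrange_quantiles(q)
        assert (np.diff(once) >= 0).all()
        np.testing.assert_array_equal(rearrange_quantiles(once), once)
        np.testing.assert_allclose(np.sort(q), once)


class TestCoefficientPaths:
    def test_cardinality(self, small_observations):
        fit = fit_quantile_grid(small_observations, taus=default_tau_grid())
        paths = coefficient_paths(fit)
        assert len(paths) == 200  # 50 levels × 4 terms
        assert set(paths.columns) == {"tau", "term", "estimate"}

    def test_single_level_four_rows(self, small_observations):
        fit = fit_quantile_grid(small_observations, taus=[0.5])
        assert len(coefficient_paths(fit)) == 4

    def test_velocity_path_linear_in_tau(self, no_suppression_truth):
        """Q(τ|x) = τ·B(x) ⇒ the velocity coefficient path has slope β_vel."""
        obs = generate_observations(5000, no_suppression_truth, seed=13)
        taus = np.array([0.2, 0.4, 0.6, 0.8])
        fit = fit_quantile_grid(obs, taus=taus)
        paths = coefficient_paths(fit)
        vel = paths[paths.term == "velocity"].sort_values("tau")
        slope = np.polyfit(vel.tau, vel.estimate, 1)[0]
        assert slope == pytest.approx(no_suppression_truth.beta[1], rel=0.1)


class TestAicSelection:
    def test_asymmetric_laplace_formula(self, toy_table):
        tau = 0.5
        beta, loss = fit_single_quantile(toy_table, tau=tau)
        n, k = len(toy_table), beta.size
        sigma = loss / n
        expected = 2 * k - 2 * n * (math.log(tau * (1 - tau)) - math.log(sigma) - 1)
        assert aic_quantile_model(toy_table, tau=tau) == pytest.approx(expected)

    def test_perfect_fit_reports_minus_inf_with_warning(self):
        data = pd.DataFrame(
            {"sample_id": range(5), "velocity": np.linspace(0.1, 1, 5),
             "inundation": np.linspace(5, 95, 5), "biomass": [3.0] * 5}
        )
        with pytest.warns(RuntimeWarning, match="perfect fit"):
            assert aic_quantile_model(data, terms=(), tau=0.5) == -np.inf

    def test_identical_formulas_identical_mean_aic(self, small_observations):
        full = ("velocity", "inundation", "interaction")
        ranked = select_model(
            small_observations, formulas=[full, full], taus=[0.4, 0.6]
        )
        assert ranked.mean_aic.iloc[0] == pytest.approx(ranked.mean_aic.iloc[1])

    def test_interaction_detected_when_present(self, no_suppression_truth):
        obs = generate_observations(1500, no_suppression_truth, seed=77)
        ranked = select_model(
            obs,
            formulas=[("velocity", "inundation"), ("velocity", "inundation", "interaction")],
            taus=[0.3, 0.5, 0.7],
        )
        assert ranked.formula.iloc[0] == ("velocity", "inundation", "interaction")
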