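import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import linprob as lp
from linprob.exceptions import (
    CovariateTypeError,
    InfeasibleBetaError,
    InvalidOutcomeError,
    MissingDataError,
    SingularDesignError,
)
from linprob.model import BINARY_PM1, CONSTANT, CONTINUOUS

from conftest import draw_outcomes, make_data, scaled_spec


# ---------------------------------------------------------------- make_dataset


class TestMakeDataset:
    def test_zero_one_recode(self):
        table = pd.DataFrame({"y": [0, 1, 1], "x": [1.0, 2.0, 3.0]})
        data = lp.make_dataset(table, "y", ["x"], coding="zero_one")
        np.testing.assert_array_equal(data.y, [-1.0, 1.0, 1.0])

    def test_pm1_identity(self):
        table = pd.DataFrame({"y": [-1, 1, -1], "x": [0.0, 1.0, 2.0]})
        data = lp.make_dataset(table, "y", ["x"], coding="pm1")
        np.testing.assert_array_equal(data.y, [-1.0, 1.0, -1.0])

    def test_three_levels_rejected(self):
        table = pd.DataFrame({"y": [1, 2, 3], "x": [0.0, 1.0, 2.0]})
        with pytest.raises(InvalidOutcomeError):
            lp.make_dataset(table, "y", ["x"])

    def test_wrong_levels_for_coding(self):
        table = pd.DataFrame({"y": [1, 2, 1], "x": [0.0, 1.0, 2.0]})
        with pytest.raises(InvalidOutcomeError):
            lp.make_dataset(table, "y", ["x"], coding="zero_one")

    def test_non_numeric_covariate(self):
        table = pd.DataFrame({"y": [0, 1], "x": ["a", "b"]})
        with pytest.raises(CovariateTypeError):
            lp.make_dataset(table, "y", ["x"])

    def test_missing_outcome_dropped_and_counted(self):
        table = pd.DataFrame({"y": [0, 1, None, 1], "x": [1.0, 2.0, 3.0, 4.0]})
        data = lp.make_dataset(table, "y", ["x"])
        assert data.n == 3
        assert data.n_dropped_outcome == 1

    def test_missing_covariate_masked_not_dropped(self):
        table = pd.DataFrame({"y": [0, 1, 1], "x": [1.0, None, 3.0]})
        data = lp.make_dataset(table, "y", ["x"])
        assert data.n == 3
        assert data.missing_mask[1, 1]  # column 0 is the intercept
        assert data.missing_mask.sum() == 1

    def test_intercept_and_kind_detection(self):
        table = pd.DataFrame(
            {"y": [0, 1, 0, 1], "b": [-1, 1, 1, -1], "c": [0.1, 0.2, 0.3, 0.4]}
        )
        data = lp.make_dataset(table, "y", ["b", "c"])
        assert data.column_names[0] == "(intercept)"
        assert data.column_meta == (CONSTANT, BINARY_PM1, CONTINUOUS)
        np.testing.assert_array_equal(data.X[:, 0], 1.0)

    def test_no_intercept(self):
        table = pd.DataFrame({"y": [0, 1], "x": [1.0, 2.0]})
        data = lp.make_dataset(table, "y", ["x"], add_intercept=False)
        assert data.p == 1

    @given(st.lists(st.sampled_from([0, 1]), min_size=2, max_size=30))
    def test_recode_is_affine(self, raw):
        if len(set(raw)) < 2:
            raw = raw + [0, 1]
        table = pd.DataFrame({"y": raw, "x": np.arange(len(raw), dtype=float)})
        data = lp.make_dataset(table, "y", ["x"])
        np.testing.assert_array_equal(data.y, 2.0 * np.array(raw, float) - 1.0)


# --------------------------------------------------------------------- fit_ols


class TestFitOls:
    def test_intercept_only_mean(self):
        data = make_data(np.ones((5, 1)), [1, 1, 1, -1, -1])
        fit = lp.fit_ols(data)
        assert fit.beta_hat[0] == pytest.approx(0.2)

    def test_exact_interpolation(self):
        data = make_data([[1, 1], [1, -1]], [1, -1])
        fit = lp.fit_ols(data)
        np.testing.assert_allclose(fit.beta_hat, [0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(fit.delta_hat, [1.0, -1.0], atol=1e-12)

    def test_matches_independent_normal_equations(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        y = np.where(rng.random(20) < 0.5, 1.0, -1.0)
        fit = lp.fit_ols(make_data(X, y))
        # independent route: assemble and solve the normal equations by QR
        q, r = np.linalg.qr(X)
        oracle = np.linalg.solve(r, q.T @ y)
        np.testing.assert_allclose(fit.beta_hat, oracle, atol=1e-10)

    def test_rank_deficient_names_columns(self, rng):
        x = rng.normal(size=10)
        X = np.column_stack([np.ones(10), x, 2 * x])
        data = make_data(X, np.where(rng.random(10) < 0.5, 1.0, -1.0),
                         names=("const", "x", "x_twice"))
        with pytest.raises(SingularDesignError) as err:
            lp.fit_ols(data)
        assert "x_twice" in str(err.value)

    def test_missing_cells_rejected(self):
        data = make_data(np.ones((4, 1)), [1, -1, 1, -1])
        bad = lp.BinaryDataset(
            y=data.y,
            X=data.X,
            missing_mask=np.array([[True], [False], [False], [False]]),
            column_meta=data.column_meta,
            column_names=data.column_names,
        )
        with pytest.raises(MissingDataError):
            lp.fit_ols(bad)

    def test_delta_hat_reconstructible(self, rng):
        X = np.column_stack([np.ones(30), rng.uniform(-1, 1, 30)])
        y = np.where(rng.random(30) < 0.5, 1.0, -1.0)
        fit = lp.fit_ols(make_data(X, y))
        np.testing.assert_allclose(fit.delta_hat, X @ fit.beta_hat, atol=1e-12)


# ---------------------------------------------------------- estimate_covariance


class TestEstimateCovariance:
    def test_zero_beta_gives_plain_inverse(self, rng):
        X = np.column_stack([np.ones(15), rng.normal(size=15)])
        data = make_data(X, np.where(rng.random(15) < 0.5, 1.0, -1.0))
        cov, n_clip = lp.estimate_covariance(data, np.zeros(2))
        np.testing.assert_allclose(cov, np.linalg.inv(X.T @ X), atol=1e-12)
        assert n_clip == 0

    def test_constant_delta_collapses_sandwich(self):
        # delta_i^2 = c for all i makes the sandwich (1-c)(x'x)^-1
        X = np.array([[1.0, 1.0], [1.0, -1.0], [1.0, 1.0], [1.0, -1.0]])
        data = make_data(X, [1, -1, 1, -1])
        beta = np.array([0.0, 0.5])  # delta = +/-0.5, delta^2 = 0.25
        cov, _ = lp.estimate_covariance(data, beta)
        np.testing.assert_allclose(cov, 0.75 * np.linalg.inv(X.T @ X), atol=1e-12)

    def test_clipping_counted(self):
        X = np.array([[1.0, 2.0], [1.0, 0.0], [1.0, -2.0]])
        data = make_data(X, [1, -1, 1])
        cov, n_clip = lp.estimate_covariance(data, np.array([0.0, 0.6]))
        assert n_clip == 2  # rows with |delta| = 1.2
        assert np.all(np.linalg.eigvalsh(cov) > -1e-12)

    def test_symmetric_psd(self, rng):
        spec = scaled_spec(80, 5, 0.8)
        data, truth = lp.simulate(spec)
        cov, _ = lp.estimate_covariance(data, truth["beta"])
        np.testing.assert_allclose(cov, cov.T, atol=1e-14)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-10)

    def test_monte_carlo_oracle(self):
        # empirical covariance of the OLS estimate over 1e5 replicates
        spec = scaled_spec(200, 42, 0.7)
        data, truth = lp.simulate(spec)
        X, delta = data.X, truth["delta"]
        rng = np.random.default_rng(2042)
        Y = draw_outcomes(delta, 100_000, rng)
        betas = np.linalg.inv(X.T @ X) @ X.T @ Y
        empirical = np.cov(betas)
        cov, _ = lp.estimate_covariance(data, truth["beta"])
        np.testing.assert_allclose(np.diag(empirical), np.diag(cov), rtol=0.05)

    def test_shrinkage_ordering(self):
        # corrected variances are strictly below (x'x)^-1 on the diagonal
        spec = scaled_spec(300, 7, 0.8)
        data, truth = lp.simulate(spec)
        cov, _ = lp.estimate_covariance(data, truth["beta"])
        plain = np.linalg.inv(data.X.T @ data.X)
        assert np.all(np.diag(cov) < np.diag(plain))


# --------------------------------------------------------------------- fit_wls


class TestFitWls:
    def test_uniform_weights_equal_ols(self):
        # balanced intercept-only outcomes give beta_ols = 0, all weights equal
        data = make_data(np.ones((6, 1)), [1, -1, 1, -1, 1, -1])
        wls = lp.fit_wls(data)
        ols = lp.fit_ols(data)
        np.testing.assert_allclose(wls.beta_hat, ols.beta_hat, atol=1e-12)
        assert not wls.weights_floored

    def test_floored_weight_flagged(self):
        # exact interpolation puts |delta_ols| = 1, flooring those weights
        data = make_data([[1, 1], [1, -1]], [1, -1])
        wls = lp.fit_wls(data)
        assert wls.weights_floored

    def test_matches_independent_weighted_solve(self, rng):
        spec = scaled_spec(120, 9, 0.5)
        data, _ = lp.simulate(spec)
        ols = lp.fit_ols(data)
        assert np.max(np.abs(ols.delta_hat)) < 1.0
        wls = lp.fit_wls(data, variance_floor=0.05)
        w = 1.0 / np.maximum(1.0 - ols.delta_hat**2, 0.05)
        Xw = data.X * np.sqrt(w)[:, None]
        yw = data.y * np.sqrt(w)
        oracle, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        np.testing.assert_allclose(wls.beta_hat, oracle, atol=1e-10)


# ---------------------------------------------------------------------- fit_ml


class TestFitMl:
    def test_balanced_data_zero_estimate(self):
        data = make_data(np.ones((4, 1)), [1, -1, 1, -1])
        fit = lp.fit_ml(data)
        np.testing.assert_allclose(fit.beta_hat, [0.0], atol=1e-10)
        assert fit.converged

    def test_monotone_likelihood_hits_boundary(self):
        data = make_data(np.ones((1, 1)), [1.0])
        fit = lp.fit_ml(data, boundary_margin=0.01)
        assert fit.beta_hat[0] == pytest.approx(0.99, abs=1e-12)
        assert fit.boundary_active
        assert fit.cov_hat is None

    def test_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, 50)
        delta = 0.7 * x
        y = np.where(rng.random(50) < (1 + delta) / 2, 1.0, -1.0)
        data = make_data(x, y)
        fit = lp.fit_ml(data)
        grid = np.arange(-0.99999, 1.0, 1e-5)
        ll = np.log(np.maximum(1.0 + grid[:, None] * (x * y)[None, :], 1e-300)).sum(
            axis=1
        )
        assert abs(fit.beta_hat[0] - grid[np.argmax(ll)]) < 1e-4

    def test_interior_fitted_values(self):
        spec = scaled_spec(200, 13, 0.9)
        data, _ = lp.simulate(spec)
        fit = lp.fit_ml(data)
        assert np.max(np.abs(fit.delta_hat)) <= 1.0 - lp.model.DEFAULT_BOUNDARY_MARGIN + 1e-12

    def test_small_signal_agreement_with_ols(self):
        # first-order expansion: ML and OLS agree to O(max|delta|^2)
        rng = np.random.default_rng(77)
        for rep in range(5):
            spec = scaled_spec(400, 100 + rep, 0.05)
            data, truth = lp.simulate(spec)
            ols = lp.fit_ols(data)
            ml = lp.fit_ml(data)
            dmax = np.max(np.abs(ols.delta_hat))
            gap = np.linalg.norm(ml.beta_hat - ols.beta_hat)
            assert gap <= 10.0 * dmax**2 * np.linalg.norm(ols.beta_hat)

    def test_ml_covariance_close_to_ols_at_zero_signal(self):
        data = make_data(np.ones((40, 1)), [1, -1] * 20)
        fit = lp.fit_ml(data)
        # at beta=0 the observed information is x'x
        np.testing.assert_allclose(fit.cov_hat, [[1.0 / 40]], rtol=1e-6)

    def test_fragility_single_out_of_range_row(self):
        # one contaminated row refutes beta_true for the likelihood while
        # barely moving least squares
        import dataclasses

        spec = scaled_spec(2000, 21, 0.8)
        clean, truth = lp.simulate(spec)
        spec_c = dataclasses.replace(spec, contamination=1)
        dirty, truth_c = lp.simulate(spec_c)
        assert lp.log_likelihood(clean, truth["beta"]) > -np.inf
        assert lp.log_likelihood(dirty, truth_c["beta"]) == -np.inf
        assert np.abs(truth_c["delta"][truth_c["contaminated_rows"]]).min() > 1.0
        assert np.all(np.isfinite(lp.fit_ols(dirty).beta_hat))

        # O(1/n) least-squares shift: append the SAME aberrant row at
        # growing n and watch the shift scale down proportionally
        shifts = {}
        for n in (1000, 4000):
            spec_n = scaled_spec(n, 22, 0.8)
            base, truth_n = lp.simulate(spec_n)
            row = np.array([1.0, 1.0, 1.5, 1.5])  # outside continuous support
            y_bad = -np.sign(row @ truth_n["beta"])
            contaminated = lp.BinaryDataset(
                y=np.append(base.y, y_bad),
                X=np.vstack([base.X, row]),
                missing_mask=np.zeros((base.n + 1, base.p), bool),
                column_meta=base.column_meta,
                column_names=base.column_names,
            )
            shifts[n] = np.linalg.norm(
                lp.fit_ols(contaminated).beta_hat - lp.fit_ols(base).beta_hat
            )
        assert shifts[4000] < shifts[1000]
        assert shifts[4000] * 4000 < 3.0 * shifts[1000] * 1000  # ~1/n scaling


# -------------------------------------------------------------- efficiency_gap


class TestEfficiencyGap:
    def test_zero_beta_zero_inflation(self, rng):
        X = np.column_stack([np.ones(25), rng.normal(size=25)])
        data = make_data(X, np.where(rng.random(25) < 0.5, 1.0, -1.0))
        rep = lp.efficiency_gap(data, np.zeros(2))
        np.testing.assert_allclose(rep.inflation, 0.0, atol=1e-14)
        assert rep.bound_scalar == 0.0

    def test_constant_delta_explicit_assembly(self):
        X = np.array([[1.0, 1.0], [1.0, -1.0], [1.0, 1.0], [1.0, -1.0]])
        data = make_data(X, [1, -1, 1, -1])
        beta = np.array([0.0, 0.5])
        rep = lp.efficiency_gap(data, beta)
        # explicit (I - Delta)^-1 route
        d2 = (X @ beta) ** 2
        oracle = np.linalg.inv(X.T @ np.diag(1.0 / (1.0 - d2)) @ X)
        np.testing.assert_allclose(rep.var_ml_approx, oracle, atol=1e-12)
        assert np.all(np.diag(rep.inflation) >= -1e-14)

    def test_geometric_series_diag_oracle(self):
        # Upsilon - Delta for delta = (0.3, -0.6) via partial geometric sums
        deltas = np.array([0.3, -0.6])
        d2 = deltas**2
        oracle = sum(d2 ** k for k in range(2, 400))  # sum_{k>=2} delta^{2k}
        closed = d2**2 / (1.0 - d2)
        np.testing.assert_allclose(closed, oracle, rtol=1e-12)
        np.testing.assert_allclose(closed, [0.0081 / 0.91, 0.1296 / 0.64], rtol=1e-12)
        # and the module's report respects the same scale
        data = make_data(np.eye(2), [1.0, -1.0], meta=("continuous", "continuous"))
        rep = lp.efficiency_gap(data, deltas)
        assert rep.bound_scalar == pytest.approx(max(closed) / 2.0)

    def test_infeasible_beta_rejected(self):
        data = make_data(np.ones((3, 1)), [1, -1, 1])
        with pytest.raises(InfeasibleBetaError):
            lp.efficiency_gap(data, np.array([1.0]))

    def test_inflation_vanishes_with_signal(self):
        sizes = []
        for target in (0.4, 0.2, 0.1):
            spec = scaled_spec(300, 3, target)
            data, truth = lp.simulate(spec)
            rep = lp.efficiency_gap(data, truth["beta"])
            sizes.append(np.max(np.diag(rep.inflation) / np.diag(rep.var_ml_approx)))
        assert sizes[0] > sizes[1] > sizes[2] >= 0.0


# ------------------------------------------------------------------ properties


class TestStatisticalProperties:
    def test_unbiasedness(self):
        spec = scaled_spec(250, 14, 0.7)
        data, truth = lp.simulate(spec)
        X, delta = data.X, truth["delta"]
        rng = np.random.default_rng(2718)
        Y = draw_outcomes(delta, 10_000, rng)
        betas = np.linalg.inv(X.T @ X) @ X.T @ Y
        mean = betas.mean(axis=1)
        mc_se = betas.std(axis=1, ddof=1) / np.sqrt(betas.shape[1])
        np.testing.assert_array_less(np.abs(mean - truth["beta"]), 3.0 * mc_se)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_cov_plugin_psd_for_any_fit(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        X = np.column_stack([np.ones(n), rng.uniform(-1, 1, n)])
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        fit = lp.fit_ols(make_data(X, y))
        assert np.all(np.linalg.eigvalsh(fit.cov_hat) > -1e-10)
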