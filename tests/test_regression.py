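"""OLS and NIPALS PLS1: oracle equivalences, diagnostics, LOO PRESS."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from varactivity.regression import (
    RankDeficientError,
    evaluate,
    fit_ols,
    fit_plsr,
    loo_cv_plsr,
)


def _random_problem(seed, n=20, p=3, noise=1.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = 2.0 + X @ beta + noise * rng.normal(size=n)
    return X, y


class TestOLS:
    def test_exact_line(self):
        x = np.arange(10.0)[:, None]
        y = 2.0 * x.ravel() + 1.0
        model = fit_ols(x, y)
        assert np.isclose(model.coefficients[0], 2.0)
        assert np.isclose(model.intercept, 1.0)
        assert model.r_squared > 1 - 1e-12
        assert np.max(np.abs(model.residuals)) < 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        X, y = _random_problem(seed)
        model = fit_ols(X, y)
        design = np.column_stack([np.ones(len(y)), X])
        oracle = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.max(np.abs(model.coefficients - oracle[1:])) < 1e-8
        assert abs(model.intercept - oracle[0]) < 1e-8

    def test_zero_residual_point_has_zero_cooks(self):
        # force an exact fit at one point by putting it on the fitted plane
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        y = 1.0 + X @ np.array([2.0, -1.0]) + rng.normal(size=30)
        model = fit_ols(X, y)
        x_new = np.array([[0.3, 0.4]])
        y_new = model.predict(x_new)  # approximately on the plane after refit
        X2 = np.vstack([X, x_new])
        y2 = np.append(y, y_new)
        model2 = fit_ols(X2, y2)
        # D = (e²/(p+1)s²)·h/(1−h)² → tiny residual gives D ≈ 0
        assert model2.cooks_distance[-1] < 1e-3
        assert np.all(model2.cooks_distance >= 0)

    def test_leverage_sums_to_p_plus_one(self):
        X, y = _random_problem(2, n=40, p=4)
        model = fit_ols(X, y)
        assert np.isclose(model.leverage.sum(), 5.0)
        assert np.all((model.leverage >= 0) & (model.leverage <= 1))

    def test_residuals_orthogonal_to_design(self):
        X, y = _random_problem(3, n=50, p=4)
        model = fit_ols(X, y)
        assert np.max(np.abs(X.T @ model.residuals)) < 1e-8
        assert abs(model.residuals.sum()) < 1e-8

    def test_nesting_never_decreases_r2(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 5))
            y = X[:, 0] * 3 + rng.normal(size=40)
            r2 = [fit_ols(X[:, : k + 1], y).r_squared for k in range(5)]
            assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_rank_deficiency_names_collinear_columns(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        X["c"] = X["a"] + X["b"]
        with pytest.raises(RankDeficientError) as err:
            fit_ols(X, rng.normal(size=30))
        assert set(err.value.collinear) & {"a", "b", "c"}

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="n_obs"):
            fit_ols(np.eye(3), np.ones(3))

    def test_missing_values_rejected(self):
        X = np.ones((10, 1)) * np.arange(10)[:, None]
        X[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_ols(X, np.arange(10.0))


class TestPLSR:
    @pytest.mark.parametrize("seed", range(4))
    def test_full_components_equal_ols_predictions(self, seed):
        X, y = _random_problem(seed, n=25, p=4)
        ols = fit_ols(X, y)
        pls = fit_plsr(X, y, n_components=4)
        assert np.max(np.abs(pls.predict(X) - ols.predict(X))) < 1e-8

    def test_univariate_single_component_is_simple_regression(self):
        X, y = _random_problem(5, n=30, p=1)
        pls = fit_plsr(X, y, 1)
        ols = fit_ols(X, y)
        assert np.max(np.abs(pls.predict(X) - ols.predict(X))) < 1e-8

    def test_deterministic(self):
        X, y = _random_problem(6, n=30, p=5)
        a = fit_plsr(X, y, 3)
        b = fit_plsr(X, y, 3)
        assert np.array_equal(a.x_weights, b.x_weights)
        assert np.array_equal(a.predict(X), b.predict(X))

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_sklearn_nipals(self, k):
        # independent oracle: sklearn's NIPALS with the same standardization
        X, y = _random_problem(7, n=40, p=6)
        ours = fit_plsr(X, y, k)
        ref = PLSRegression(n_components=k, scale=True).fit(X, y)
        assert np.max(np.abs(ours.predict(X) - ref.predict(X).ravel())) < 1e-8

    def test_scores_orthogonal(self):
        X, y = _random_problem(8, n=50, p=8)
        pls = fit_plsr(X, y, 5)
        gram = pls.x_scores.T @ pls.x_scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_per_component_predictions_nested(self):
        X, y = _random_problem(9, n=30, p=5)
        pls = fit_plsr(X, y, 4)
        per = pls.predict_per_component(X)
        for k in range(1, 5):
            assert np.allclose(per[:, k - 1], pls.predict(X, n_components=k))

    def test_zero_variance_column_dropped_with_warning(self):
        X, y = _random_problem(10, n=30, p=3)
        X = np.column_stack([X, np.full(30, 2.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            pls = fit_plsr(pd.DataFrame(X, columns=list("abcd")), y, 3)
        assert pls.dropped_columns == ["d"]
        assert "d" not in pls.feature_names

    def test_component_count_validation(self):
        X, y = _random_problem(11, n=10, p=3)
        with pytest.raises(ValueError):
            fit_plsr(X, y, 0)
        with pytest.raises(ValueError):
            fit_plsr(X, y, 4)


class TestLOOCV:
    def test_recovers_two_latent_directions(self):
        # noiseless y from 2 orthogonal latent directions in a 5-column X
        rng = np.random.default_rng(0)
        t = rng.normal(size=(60, 2))
        loadings = rng.normal(size=(2, 5))
        X = t @ loadings
        y = t @ np.array([3.0, -2.0])
        chosen, press = loo_cv_plsr(X, y, max_components=5)
        assert chosen == 2
        assert np.all(press >= 0)

    def test_chosen_within_bounds_and_press_nonnegative(self):
        X, y = _random_problem(12, n=25, p=6, noise=3.0)
        chosen, press = loo_cv_plsr(X, y, max_components=6)
        assert 1 <= chosen <= 6
        assert np.all(press >= 0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            loo_cv_plsr(np.ones((2, 1)), np.ones(2), 1)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = evaluate(y, y)
        assert m.r_squared == 1.0
        assert m.rmse == 0.0
        assert m.r_squared_ss == 1.0

    def test_constant_offset(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = evaluate(y + 5.0, y)
        assert np.isclose(m.r_squared, 1.0)
        assert np.isclose(m.rmse, 5.0)
        assert m.r_squared_ss < 1.0  # offset hurts variance-explained form

    def test_null_association_near_zero(self):
        # mean squared Pearson under independence ≈ 1/(n−1)
        values = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values.append(
                evaluate(rng.normal(size=1000), rng.normal(size=1000)).r_squared
            )
        assert np.mean(values) < 0.01

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            evaluate(np.array([1.0, 2.0]), np.array([3.0, 3.0]))
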