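"""Forward selection and iterative outlier removal."""

import numpy as np
import pandas as pd
import pytest

from varactivity.regression import fit_ols
from varactivity.selection import (
    SelectionConfig,
    detect_outliers,
    forward_select,
    iterate_selection,
)


def _noise_problem(seed, n=200, n_noise=20, beta=40.0, noise_sd=3.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.uniform(0, 1, size=(n, n_noise + 1)),
        columns=["inf"] + [f"noise_{i:02d}" for i in range(n_noise)],
    )
    y = pd.Series(50.0 + beta * X["inf"] + rng.normal(0, noise_sd, n))
    return X, y


class TestForwardSelect:
    def test_informative_feature_found_first(self):
        # simulation protocol: 20 seeds, expect ≥ 19 successes
        hits = sum(
            forward_select(*_noise_problem(seed)).selected[0] == "inf"
            for seed in range(20)
        )
        assert hits >= 19

    def test_plateau_rule_limits_selection(self):
        X, y = _noise_problem(0)
        trace = forward_select(X, y, delta_r2_min=1.0)
        assert len(trace.selected) <= 1
        assert trace.stop_reason in ("plateau", "no_candidate")

    def test_r2_path_nondecreasing_and_pvalues_below_threshold(self):
        X, y, _ = _multi_informative(3)
        trace = forward_select(X, y)
        assert all(
            b >= a - 1e-12 for a, b in zip(trace.r2_path, trace.r2_path[1:])
        )
        assert all(p < 1e-3 for p in trace.p_values)

    def test_step_pvalue_equals_full_ols_t_test(self):
        # the vectorized partial-correlation t test must equal the t test of
        # the added coefficient in the explicit augmented OLS fit
        X, y, _ = _multi_informative(1)
        trace = forward_select(X, y)
        for step in range(len(trace.selected)):
            cols = trace.selected[: step + 1]
            full = fit_ols(X[cols], y)
            assert np.isclose(
                full.p_values[cols.index(trace.selected[step])],
                trace.p_values[step],
                rtol=1e-8,
                atol=1e-300,
            )

    def test_column_order_invariance(self):
        X, y, _ = _multi_informative(5)
        shuffled = X[list(reversed(X.columns))]
        a = forward_select(X, y)
        b = forward_select(shuffled, y)
        assert a.selected == b.selected
        assert np.allclose(a.r2_path, b.r2_path)

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError):
            forward_select(pd.DataFrame(index=range(10)), np.ones(10))


def _multi_informative(seed, n=150):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.uniform(0, 1, size=(n, 10)),
        columns=[f"f{i:02d}" for i in range(10)],
    )
    beta = np.zeros(10)
    beta[:3] = [50.0, -35.0, 25.0]
    y = pd.Series(60.0 + X.to_numpy() @ beta + rng.normal(0, 4.0, n), index=X.index)
    return X, y, {f"f{i:02d}" for i in range(3)}


class TestDetectOutliers:
    def test_noiseless_data_has_no_flags(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.uniform(0, 1, (80, 3)), columns=list("abc"))
        y = 5.0 + X @ np.array([2.0, -3.0, 1.0])
        report = detect_outliers(fit_ols(X, y))
        assert report.flagged == []

    def test_gross_outlier_flagged(self):
        flagged = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.uniform(0, 1, (100, 3)), columns=list("abc"))
            y = 10.0 + X @ np.array([30.0, -20.0, 10.0]) + rng.normal(0, 2.0, 100)
            y.iloc[7] += 20.0  # 10 × noise SD
            flagged += 7 in detect_outliers(fit_ols(X, y)).flagged
        assert flagged >= 19

    def test_statistics_reported_for_everyone(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.uniform(0, 1, (50, 2)), columns=list("ab"))
        y = X["a"] * 10 + rng.normal(0, 1, 50)
        report = detect_outliers(fit_ols(X, y))
        assert len(report.cooks_distance) == 50
        assert (report.cooks_distance >= 0).all()
        every_flag_has_cause = all(
            report.cooks_distance[v] > report.cooks_threshold
            or abs(report.studentized_external[v]) > report.qq_threshold
            for v in report.flagged
        )
        assert every_flag_has_cause

    def test_flags_invariant_to_feature_rescaling(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.uniform(0, 1, (60, 3)), columns=list("abc"))
        y = 5 + X @ np.array([20.0, -10.0, 5.0]) + rng.normal(0, 2, 60)
        base = detect_outliers(fit_ols(X, y))
        X2 = X.copy()
        X2["b"] = X2["b"] * 1000.0 - 7.0
        rescaled = detect_outliers(fit_ols(X2, y))
        assert base.flagged == rescaled.flagged
        assert np.allclose(
            base.studentized_external, rescaled.studentized_external, atol=1e-8
        )

    def test_intersection_rule_is_stricter(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.uniform(0, 1, (80, 2)), columns=list("ab"))
        y = X["a"] * 30 + rng.normal(0, 3, 80)
        y.iloc[5] += 25
        model = fit_ols(X, y)
        union = set(detect_outliers(model, combine="union").flagged)
        both = set(detect_outliers(model, combine="intersection").flagged)
        assert both <= union

    def test_too_small_sample_rejected(self):
        # n = 5, p = 3: the fit is defined but n ≤ p + 2
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)))
        X.columns = list("abc")
        y = np.arange(5.0)
        model = fit_ols(X, y)
        with pytest.raises(ValueError, match="studentization"):
            detect_outliers(model)


class TestIterateSelection:
    def test_clean_data_converges_immediately(self):
        # noiseless generating model: first fit flags nothing
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.uniform(0, 1, (100, 6)),
                         columns=[f"f{i}" for i in range(6)])
        y = pd.Series(20.0 + X["f0"] * 50 - X["f1"] * 30, index=X.index)
        result = iterate_selection(X, y)
        assert result.converged
        assert result.n_iterations == 1
        assert result.removed == {}

    def test_planted_outliers_improve_final_fit(self):
        improved = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.uniform(0, 1, (120, 8)),
                             columns=[f"f{i}" for i in range(8)])
            y = pd.Series(
                30.0 + X["f0"] * 60 - X["f2"] * 40 + rng.normal(0, 5, 120),
                index=X.index,
            )
            shifted = rng.choice(120, size=5, replace=False)
            y.iloc[shifted] += rng.choice([-1, 1], 5) * 50.0
            result = iterate_selection(X, y)
            first_fit_r2 = _first_iteration_r2(X, y)
            improved += result.model.r_squared > first_fit_r2
        assert improved >= 19

    def test_removed_never_reinstated_and_logged_with_iteration(self, study_dataset):
        result = iterate_selection(
            study_dataset.features.values, study_dataset.activity
        )
        final_index = set(result.model.observation_index)
        assert set(result.removed) & final_index == set()
        assert all(
            1 <= it <= result.n_iterations for it in result.removed.values()
        )

    def test_exhausting_data_aborts_with_diagnostic(self):
        # an absurdly low Cook's threshold flags nearly every observation,
        # draining the sample below what studentization needs
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.uniform(0, 1, (12, 2)), columns=list("ab"))
        y = pd.Series(X["a"] * 40 + rng.normal(0, 0.5, 12), index=X.index)
        with pytest.raises(ValueError, match="exhausted"):
            iterate_selection(X, y, SelectionConfig(cooks_rule=1e-9))


def _first_iteration_r2(X, y):
    trace = forward_select(X, y)
    return fit_ols(X[trace.selected], y).r_squared
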