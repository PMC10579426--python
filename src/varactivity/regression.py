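"""Regression engines: multiple linear regression and NIPALS PLS1.

MLR is ordinary least squares with the classical influence diagnostics
used for outlier screening (leverage h_i, Cook's distance D_i, externally
studentized residuals); the fit itself is delegated to statsmodels.

PLSR is implemented here as univariate-response NIPALS with predictors
standardized to zero mean / unit variance.  NIPALS components are nested:
the score vectors t_1..t_k of a k-component model equal the first k score
vectors of any larger model, which lets leave-one-out PRESS for every
component count be computed from a single fit per held-out sample.

Test-set goodness of fit is reported two ways (they differ off the 45°
line): squared Pearson correlation between predicted and observed
(``r_squared``) and the variance-explained form 1 − SSres/SStot
(``r_squared_ss``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = [
    "LinearModel",
    "PLSModel",
    "FitMetrics",
    "RankDeficientError",
    "fit_ols",
    "fit_plsr",
    "loo_cv_plsr",
    "evaluate",
]


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names a candidate collinear set."""

    def __init__(self, collinear: list[str]):
        self.collinear = collinear
        super().__init__(
            f"design matrix is rank deficient; collinear column candidates: {collinear}"
        )


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] == 0:
        return
    # pivoted QR to name the dependent columns
    from scipy.linalg import qr as scipy_qr

    _, r, piv = scipy_qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        dependent = [names[j] for j in piv[rank:]]
        raise RankDeficientError(sorted(dependent))


@dataclass
class LinearModel:
    """Fitted OLS model with the diagnostics used for outlier screening."""

    feature_names: list[str]
    coefficients: np.ndarray  # activity % per score unit
    intercept: float
    p_values: np.ndarray  # two-sided t, per coefficient (no intercept)
    intercept_p_value: float
    residuals: np.ndarray
    fitted: np.ndarray
    leverage: np.ndarray
    cooks_distance: np.ndarray
    studentized_external: np.ndarray
    r_squared: float
    rmse: float
    n_obs: int
    observation_index: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def predict(self, X) -> np.ndarray:
        arr, names = _as_matrix(X)
        if isinstance(X, pd.DataFrame):
            arr = X[self.feature_names].to_numpy(dtype=float)
        elif arr.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {arr.shape[1]}"
            )
        return self.intercept + arr @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "kind": "mlr",
            "feature_names": list(self.feature_names),
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "r_squared": float(self.r_squared),
            "rmse": float(self.rmse),
            "n_obs": int(self.n_obs),
        }


def fit_ols(X, y, observation_index=None) -> LinearModel:
    """Ordinary least squares with leverage, Cook's D and studentized residuals.

    Requires a complete (no-NaN), full-column-rank design with
    n_obs > n_features + 1; rank deficiency raises
    :class:`RankDeficientError` naming a candidate collinear set.
    """
    arr, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = arr.shape
    if yv.shape[0] != n:
        raise ValueError("X and y length mismatch")
    if np.isnan(arr).any() or np.isnan(yv).any():
        raise ValueError("missing values in design or response; filter first")
    if n <= p + 1:
        raise ValueError(f"need n_obs > n_features + 1 (n={n}, p={p})")
    _check_full_rank(np.column_stack([np.ones(n), arr]), ["intercept"] + names)

    design = sm.add_constant(arr, has_constant="add")
    fit = sm.OLS(yv, design).fit()
    infl = OLSInfluence(fit)
    residuals = fit.resid
    return LinearModel(
        feature_names=names,
        coefficients=np.asarray(fit.params[1:]),
        intercept=float(fit.params[0]),
        p_values=np.asarray(fit.pvalues[1:]),
        intercept_p_value=float(fit.pvalues[0]),
        residuals=np.asarray(residuals),
        fitted=np.asarray(fit.fittedvalues),
        leverage=np.asarray(infl.hat_matrix_diag),
        cooks_distance=np.asarray(infl.cooks_distance[0]),
        studentized_external=np.asarray(infl.resid_studentized_external),
        r_squared=float(fit.rsquared),
        rmse=float(np.sqrt(np.mean(residuals**2))),
        n_obs=n,
        observation_index=(
            list(observation_index)
            if observation_index is not None
            else (list(X.index) if isinstance(X, pd.DataFrame) else list(range(n)))
        ),
    )


# ---------------------------------------------------------------------------
# NIPALS PLS1
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    """NIPALS PLS1 model on standardized predictors.

    ``x_weights`` (W), ``x_loadings`` (P) and ``x_scores`` (T) follow the
    usual NIPALS conventions; ``y_loadings`` (q) are the per-component
    regression weights of the centered response on the scores.  The
    regression-coefficient expansion B_k = W_k (P_kᵀ W_k)⁻¹ q_k gives the
    coefficients (on the standardized scale) of the k-component model.
    """

    feature_names: list[str]
    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    x_weights: np.ndarray  # p × k
    x_loadings: np.ndarray  # p × k
    x_scores: np.ndarray  # n × k
    y_loadings: np.ndarray  # k
    dropped_columns: list[str] = field(default_factory=list)

    def _standardize(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            arr = X[self.feature_names].to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim == 1:
                arr = arr[:, None]
        return (arr - self.x_mean) / self.x_scale

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Standardized-scale coefficient vector of the k-component model."""
        k = self.n_components if n_components is None else n_components
        w, p, q = self.x_weights[:, :k], self.x_loadings[:, :k], self.y_loadings[:k]
        return w @ np.linalg.solve(p.T @ w, q)

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        return self.y_mean + self._standardize(X) @ self.coefficients(n_components)

    def predict_per_component(self, X) -> np.ndarray:
        """n × k matrix of predictions using 1..k components (nested NIPALS)."""
        xs = self._standardize(X)
        w, p, q = self.x_weights, self.x_loadings, self.y_loadings
        rotations = w @ np.linalg.inv(p.T @ w)  # PᵀW is upper triangular
        contributions = (xs @ rotations) * q
        return self.y_mean + np.cumsum(contributions, axis=1)

    def to_dict(self) -> dict:
        return {
            "kind": "plsr",
            "feature_names": list(self.feature_names),
            "n_components": int(self.n_components),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": float(self.y_mean),
            "coefficients_std_scale": self.coefficients().tolist(),
            "dropped_columns": list(self.dropped_columns),
        }


def fit_plsr(X, y, n_components: int) -> PLSModel:
    """Fit a PLS1 model by NIPALS on standardized predictors.

    Zero-variance columns are dropped with a warning (recorded on the
    model).  If the X/y covariance is exhausted before ``n_components``
    deflation steps, the component count is capped at what the data
    supports and recorded as such.
    """
    arr, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = arr.shape
    if yv.shape[0] != n:
        raise ValueError("X and y length mismatch")
    if np.isnan(arr).any() or np.isnan(yv).any():
        raise ValueError("missing values in design or response; filter first")
    if n_components < 1:
        raise ValueError("n_components must be ≥ 1")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}"
        )

    scale = arr.std(axis=0, ddof=1)
    keep = scale > 0
    dropped = [names[j] for j in np.flatnonzero(~keep)]
    if dropped:
        warnings.warn(
            f"dropping zero-variance columns: {dropped}", stacklevel=2
        )
        arr = arr[:, keep]
        names = [nm for nm, k in zip(names, keep) if k]
        scale = scale[keep]
        if arr.shape[1] == 0:
            raise ValueError("all columns have zero variance")
        n_components = min(n_components, arr.shape[1])

    x_mean = arr.mean(axis=0)
    xs = (arr - x_mean) / scale
    y_mean = float(yv.mean())
    yc = yv - y_mean

    p_eff = xs.shape[1]
    W = np.zeros((p_eff, n_components))
    P = np.zeros((p_eff, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    Xa, ya = xs.copy(), yc.copy()
    k_done = 0
    x_norm0 = max(np.linalg.norm(xs), 1.0)
    for a in range(n_components):
        cov = Xa.T @ ya
        cov_norm = np.linalg.norm(cov)
        if cov_norm < 1e-12 * max(np.linalg.norm(ya), 1.0) * x_norm0 or cov_norm == 0:
            break  # covariance exhausted; fewer components than requested
        w = cov / cov_norm
        t = Xa @ w
        tt = t @ t
        if tt < 1e-24:
            break
        pa = Xa.T @ t / tt
        qa = ya @ t / tt
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
        Xa = Xa - np.outer(t, pa)
        ya = ya - qa * t
        k_done += 1
    if k_done == 0:
        raise ValueError("no PLS component could be extracted (X ⟂ y)")
    return PLSModel(
        feature_names=names,
        n_components=k_done,
        x_mean=x_mean,
        x_scale=scale,
        y_mean=y_mean,
        x_weights=W[:, :k_done],
        x_loadings=P[:, :k_done],
        x_scores=T[:, :k_done],
        y_loadings=q[:k_done],
        dropped_columns=dropped,
    )


def loo_cv_plsr(X, y, max_components: int) -> tuple[int, np.ndarray]:
    """Leave-one-out PRESS curve over 1..max_components; pick the minimum.

    PRESS(k) = Σ_i (y_i − ŷ_{−i,k})²; ties resolved toward the smaller
    component count.  Each held-out fit supports all component counts at
    once via the nested-score property of NIPALS.
    """
    arr, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n = arr.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 observations")
    kmax = min(max_components, n - 2, arr.shape[1])
    if kmax < 1:
        raise ValueError("max_components leaves no admissible component count")
    press = np.zeros(kmax)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_plsr(arr[mask], yv[mask], kmax)
        preds = model.predict_per_component(arr[i : i + 1])[0]
        if model.n_components < kmax:  # fold supported fewer components
            preds = np.concatenate(
                [preds, np.full(kmax - model.n_components, preds[-1])]
            )
        press += (yv[i] - preds) ** 2
    chosen = int(np.argmin(press)) + 1
    return chosen, press


# ---------------------------------------------------------------------------
# fit metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitMetrics:
    """Prediction-quality summary on an evaluation set."""

    r_squared: float  # squared Pearson(predicted, observed)
    rmse: float  # % activity
    pearson_r: float
    r_squared_ss: float  # 1 − SSres/SStot

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


def evaluate(predictions, observed) -> FitMetrics:
    """Pearson-based R², RMSE and variance-explained R² of predictions."""
    pred = np.asarray(predictions, dtype=float).ravel()
    obs = np.asarray(observed, dtype=float).ravel()
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("predictions/observed must be equal-length, size ≥ 2")
    if np.ptp(obs) == 0:
        raise ValueError("observed vector is constant; Pearson r undefined")
    if np.ptp(pred) == 0:
        r = 0.0  # constant predictor carries no linear association
    else:
        r = float(stats.pearsonr(pred, obs).statistic)
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    return FitMetrics(
        r_squared=r * r,
        rmse=float(np.sqrt(np.mean((obs - pred) ** 2))),
        pearson_r=r,
        r_squared_ss=1.0 - ss_res / ss_tot,
    )
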