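"""Forward variable selection and iterative outlier removal.

The model-building loop alternates two stages until it converges:

1. *Forward selection.*  Starting from the intercept-only model, each
   round fits every remaining candidate alongside the already-selected
   scores and adds the candidate giving the best R², provided its
   coefficient is significant (two-sided t, p < 1e-3 by default).  The
   loop stops when the best improvement falls below ``delta_r2_min``
   (the R² plateau), when no candidate reaches significance, or at
   ``max_features``.

2. *Outlier screening.*  The selected-variable OLS fit is screened with
   Cook's distance (D_i > 4/n by default) and the numeric surrogate of a
   Q-Q plot inspection, the externally studentized residual
   (|t_i| > 3 by default).  Flagged variants are removed and the whole
   procedure repeats on the reduced data, up to ``max_iterations`` times
   or until no new outlier appears.  Removed variants are never
   reinstated.

The candidate scan is vectorized: with Q an orthonormal basis of the
current design (intercept + selected columns), each candidate's gain is
its squared partial correlation with the residual of y, and the t test of
that partial correlation is algebraically the t test of the candidate's
coefficient in the augmented OLS fit — so one matrix product scores all
candidates per round.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regression import LinearModel, fit_ols

__all__ = [
    "SelectionConfig",
    "SelectionTrace",
    "OutlierReport",
    "IterationResult",
    "forward_select",
    "detect_outliers",
    "iterate_selection",
]

DEFAULT_P_THRESHOLD = 1e-3
DEFAULT_DELTA_R2_MIN = 0.005
DEFAULT_QQ_RULE = 3.0


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the select / fit / de-outlier loop."""

    p_threshold: float = DEFAULT_P_THRESHOLD
    delta_r2_min: float = DEFAULT_DELTA_R2_MIN
    max_features: int | None = None  # None → min(p, n − 3)
    cooks_rule: float | None = None  # None → 4/n at each fit
    qq_rule: float = DEFAULT_QQ_RULE
    combine: str = "union"  # union | intersection of the two criteria
    max_iterations: int = 10

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.delta_r2_min < 0:
            raise ValueError("delta_r2_min must be ≥ 0")
        if self.combine not in ("union", "intersection"):
            raise ValueError("combine must be 'union' or 'intersection'")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be ≥ 1")


@dataclass
class SelectionTrace:
    """Audit trail of one forward-selection run."""

    selected: list[str]
    r2_path: list[float]
    p_values: list[float]  # added-coefficient p-value per step
    stop_reason: str  # plateau | no_candidate | max_features

    def __post_init__(self):
        if self.stop_reason not in ("plateau", "no_candidate", "max_features"):
            raise ValueError(f"invalid stop_reason {self.stop_reason!r}")


@dataclass
class OutlierReport:
    """Per-fit outlier diagnostics and the flags they imply."""

    flagged: list
    cooks_distance: pd.Series
    studentized_external: pd.Series
    cooks_threshold: float
    qq_threshold: float
    combine: str
    iteration: int = 0


@dataclass
class IterationResult:
    """Outcome of the alternating selection / outlier-removal loop."""

    model: LinearModel
    trace: SelectionTrace
    reports: list[OutlierReport]
    removed: dict  # variant id → iteration index at removal
    n_iterations: int
    converged: bool

    @property
    def outlier_ids(self) -> list:
        return list(self.removed)


def forward_select(
    X: pd.DataFrame,
    y,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    delta_r2_min: float = DEFAULT_DELTA_R2_MIN,
    max_features: int | None = None,
) -> SelectionTrace:
    """Greedy forward selection by best-R² with a significance gate.

    Deterministic: exact R² ties between candidates resolve to the
    lexicographically smallest feature name.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{j}" for j in range(X.shape[1])]
    if X.shape[1] == 0:
        raise ValueError("empty candidate set")
    if X.isna().any().any():
        raise ValueError("missing values in candidate matrix; filter first")
    yv = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if max_features is None:
        max_features = min(p, n - 3)
    if n <= max_features + 1:
        raise ValueError(f"need n > max_features + 1 (n={n}, max={max_features})")

    names = [str(c) for c in X.columns]
    order = np.argsort(names)  # lexicographic scan order makes ties deterministic
    cand_names = [names[j] for j in order]
    C = X.to_numpy(dtype=float)[:, order]

    q_basis = np.ones((n, 1)) / np.sqrt(n)
    r_y = yv - q_basis @ (q_basis.T @ yv)
    tss = float(r_y @ r_y)
    if tss == 0:
        raise ValueError("response is constant")

    available = np.ones(C.shape[1], dtype=bool)
    selected: list[str] = []
    r2_path: list[float] = []
    p_values: list[float] = []
    r2_current = 0.0
    stop_reason = "no_candidate"

    while True:
        if len(selected) >= max_features:
            stop_reason = "max_features"
            break
        df = n - (len(selected) + 1) - 1  # residual df after adding one column
        if df < 1:
            stop_reason = "no_candidate"
            break
        idx = np.flatnonzero(available)
        if idx.size == 0:
            stop_reason = "no_candidate"
            break
        cand = C[:, idx]
        c_res = cand - q_basis @ (q_basis.T @ cand)
        norms2 = np.einsum("ij,ij->j", c_res, c_res)
        col_scale = np.einsum("ij,ij->j", cand, cand)
        degenerate = norms2 <= 1e-12 * np.maximum(col_scale, 1.0)
        rss = float(r_y @ r_y)
        with np.errstate(divide="ignore", invalid="ignore"):
            partial_r = (c_res.T @ r_y) / np.sqrt(norms2 * rss)
        partial_r = np.where(degenerate, 0.0, np.clip(partial_r, -1.0, 1.0))
        r2_new = r2_current + partial_r**2 * (rss / tss)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = partial_r * np.sqrt(df / np.maximum(1.0 - partial_r**2, 1e-300))
        pvals = 2.0 * stats.t.sf(np.abs(t_stat), df)
        qualifies = (pvals < p_threshold) & ~degenerate
        if not qualifies.any():
            stop_reason = "no_candidate"
            break
        r2_masked = np.where(qualifies, r2_new, -np.inf)
        best_local = int(np.argmax(r2_masked))  # first max = lexicographic tie-break
        best_gain = r2_masked[best_local] - r2_current
        if best_gain < delta_r2_min:
            stop_reason = "plateau"
            break
        j = idx[best_local]
        q_new = c_res[:, best_local] / np.sqrt(norms2[best_local])
        q_basis = np.column_stack([q_basis, q_new])
        r_y = r_y - q_new * (q_new @ r_y)
        available[j] = False
        selected.append(cand_names[j])
        r2_current = float(r2_masked[best_local])
        r2_path.append(r2_current)
        p_values.append(float(pvals[best_local]))

    return SelectionTrace(
        selected=selected,
        r2_path=r2_path,
        p_values=p_values,
        stop_reason=stop_reason,
    )


def detect_outliers(
    model: LinearModel,
    cooks_rule: float | None = None,
    qq_rule: float = DEFAULT_QQ_RULE,
    combine: str = "union",
    iteration: int = 0,
) -> OutlierReport:
    """Flag observations by Cook's distance and studentized residuals.

    Default Cook's rule is the conventional 4/n; the Q-Q criterion is
    |externally studentized residual| > 3.  ``combine`` chooses whether a
    single criterion suffices ("union", default) or both must fire
    ("intersection").
    """
    n, p = model.n_obs, model.n_features
    if n <= p + 2:
        raise ValueError(
            f"external studentization undefined for n ≤ p + 2 (n={n}, p={p})"
        )
    threshold = 4.0 / n if cooks_rule is None else float(cooks_rule)
    index = pd.Index(model.observation_index)
    cooks = pd.Series(model.cooks_distance, index=index)
    student = pd.Series(model.studentized_external, index=index)
    # numerically perfect fit: residuals are rounding noise, not influence
    perfect = model.rmse <= 1e-10 * max(1.0, float(np.std(model.fitted)))
    by_cooks = (cooks > threshold) & ~perfect
    by_qq = (student.abs() > qq_rule) & ~perfect
    if combine == "union":
        mask = by_cooks | by_qq
    elif combine == "intersection":
        mask = by_cooks & by_qq
    else:
        raise ValueError("combine must be 'union' or 'intersection'")
    return OutlierReport(
        flagged=list(index[mask]),
        cooks_distance=cooks,
        studentized_external=student,
        cooks_threshold=threshold,
        qq_threshold=qq_rule,
        combine=combine,
        iteration=iteration,
    )


def iterate_selection(
    X: pd.DataFrame,
    y: pd.Series,
    config: SelectionConfig | None = None,
) -> IterationResult:
    """Alternate forward selection, OLS refit and outlier removal.

    Terminates when an iteration flags no new outlier or after
    ``max_iterations``.  Removals are logged with their iteration index
    and never reinstated.  Aborts with a diagnostic if removals would
    leave too few observations to studentize the residuals.
    """
    config = config or SelectionConfig()
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{j}" for j in range(X.shape[1])]
    yv = pd.Series(np.asarray(y, dtype=float).ravel(), index=X.index)

    active = X.index.to_list()
    removed: dict = {}
    reports: list[OutlierReport] = []
    model = None
    trace = None
    converged = False
    iterations_run = 0

    for iteration in range(1, config.max_iterations + 1):
        iterations_run = iteration
        x_it = X.loc[active]
        y_it = yv.loc[active]
        trace = forward_select(
            x_it,
            y_it,
            p_threshold=config.p_threshold,
            delta_r2_min=config.delta_r2_min,
            max_features=config.max_features,
        )
        if not trace.selected:
            raise ValueError(
                "forward selection chose no variable "
                f"(stop_reason={trace.stop_reason}); thresholds too strict?"
            )
        model = fit_ols(x_it[trace.selected], y_it, observation_index=active)
        report = detect_outliers(
            model,
            cooks_rule=config.cooks_rule,
            qq_rule=config.qq_rule,
            combine=config.combine,
            iteration=iteration,
        )
        reports.append(report)
        new_flags = [v for v in report.flagged if v not in removed]
        if not new_flags:
            converged = True
            break
        for v in new_flags:
            removed[v] = iteration
        active = [v for v in active if v not in removed]
        p_now = len(trace.selected)
        if len(active) <= p_now + 2:
            raise ValueError(
                f"outlier removal exhausted the data: {len(active)} observations "
                f"left for {p_now} selected variables (need > p + 2)"
            )

    return IterationResult(
        model=model,
        trace=trace,
        reports=reports,
        removed=removed,
        n_iterations=iterations_run,
        converged=converged,
    )
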