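"""Repeated train/test validation, variant prediction and 3D-location annotation.

Validation follows repeated random subsampling: each of the (default 20)
splits withholds a fixed number of variants (default 10) for testing and
trains MLR and PLSR — the PLSR component count chosen by leave-one-out
PRESS on the training part — on the rest.  Splits are independent draws,
not a partition.  Feature selection and outlier removal are assumed done
beforehand; this stage never reselects.

Trained models are then applied to unlabeled variants.  Predictions are
reported raw and clipped to the activity range, and binned into activity
groups on the clipped value: AG1 [0, 20), AG2 [20, 50), AG3 [50, 80),
AG4 [80, ∞) — percent of wild-type activity.  Variants missing any model
feature are flagged unpredictable, never imputed.

Structural-location annotation classifies a variant's residue as
``near_DNA``, ``interface``, ``surface`` or ``buried`` from Cα-distance
proxies on a complex model with per-chain roles, with the precedence
near_DNA > interface > (surface | buried).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .gnm import CalphaModel
from .regression import LinearModel, PLSModel, evaluate, fit_ols, fit_plsr, loo_cv_plsr

__all__ = [
    "SplitScheme",
    "ValidationReport",
    "ACTIVITY_GROUP_BOUNDS",
    "make_splits",
    "run_validation",
    "assign_activity_group",
    "predict_variants",
    "annotate_location",
]

#: Lower bounds (inclusive) of the activity groups, % of wild-type activity.
ACTIVITY_GROUP_BOUNDS = {"AG1": 0.0, "AG2": 20.0, "AG3": 50.0, "AG4": 80.0}


@dataclass(frozen=True)
class SplitScheme:
    """Repeated random train/test subsampling plan."""

    n_variants: int
    test_size: int
    splits: tuple  # of (train_idx tuple, test_idx tuple)
    seed: int

    @property
    def n_splits(self) -> int:
        return len(self.splits)


def make_splits(
    n_variants: int,
    test_size: int = 10,
    n_splits: int = 20,
    seed: int = 0,
) -> SplitScheme:
    """Independent random subsamples: each split holds out ``test_size`` variants."""
    if test_size >= n_variants:
        raise ValueError(
            f"test_size {test_size} must be smaller than n_variants {n_variants}"
        )
    if test_size < 1 or n_splits < 1:
        raise ValueError("test_size and n_splits must be ≥ 1")
    rng = np.random.default_rng(seed)
    splits = []
    everyone = np.arange(n_variants)
    for _ in range(n_splits):
        test = np.sort(rng.choice(n_variants, size=test_size, replace=False))
        train = np.setdiff1d(everyone, test)
        splits.append((tuple(int(i) for i in train), tuple(int(i) for i in test)))
    return SplitScheme(
        n_variants=n_variants, test_size=test_size, splits=tuple(splits), seed=seed
    )


@dataclass
class ValidationReport:
    """Per split × method metrics plus failures (rank-deficient splits etc.)."""

    table: pd.DataFrame  # split, method, train/test metrics, n_components
    failures: list = field(default_factory=list)  # (split, method, message)

    def top(self, method: str) -> pd.Series:
        """Best split of a method by test R² (squared Pearson)."""
        sub = self.table[self.table["method"] == method]
        if sub.empty:
            raise ValueError(f"no successful split for method {method!r}")
        return sub.loc[sub["test_r2"].idxmax()]

    def mean_test_r2(self, method: str) -> float:
        sub = self.table[self.table["method"] == method]
        return float(sub["test_r2"].mean())


def run_validation(
    X: pd.DataFrame,
    y,
    scheme: SplitScheme,
    selected_features=None,
    max_components: int | None = None,
) -> ValidationReport:
    """Fit MLR and LOO-tuned PLSR per split; evaluate on the held-out part."""
    if selected_features is not None:
        X = X[list(selected_features)]
    if len(X) != scheme.n_variants:
        raise ValueError(
            f"scheme built for {scheme.n_variants} variants, X has {len(X)}"
        )
    yv = np.asarray(y, dtype=float).ravel()
    arr = X.to_numpy(dtype=float)
    p = arr.shape[1]
    rows, failures = [], []
    for split_no, (train, test) in enumerate(scheme.splits):
        tr, te = np.asarray(train), np.asarray(test)
        x_tr, y_tr, x_te, y_te = arr[tr], yv[tr], arr[te], yv[te]

        try:
            mlr = fit_ols(pd.DataFrame(x_tr, columns=X.columns), y_tr)
        except ValueError as exc:
            failures.append((split_no, "mlr", str(exc)))
            mlr = None
        if mlr is not None:
            m_tr = evaluate(mlr.predict(x_tr), y_tr)
            m_te = evaluate(mlr.predict(x_te), y_te)
            rows.append(
                {
                    "split": split_no,
                    "method": "mlr",
                    "train_r2": m_tr.r_squared,
                    "train_rmse": m_tr.rmse,
                    "test_r2": m_te.r_squared,
                    "test_rmse": m_te.rmse,
                    "test_r2_ss": m_te.r_squared_ss,
                    "n_components": np.nan,
                }
            )

        try:
            kmax = max_components or min(p, len(tr) - 2)
            chosen, _ = loo_cv_plsr(x_tr, y_tr, kmax)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pls = fit_plsr(
                    pd.DataFrame(x_tr, columns=X.columns), y_tr, chosen
                )
        except ValueError as exc:
            failures.append((split_no, "plsr", str(exc)))
            continue
        p_tr = evaluate(pls.predict(x_tr), y_tr)
        p_te = evaluate(pls.predict(x_te), y_te)
        rows.append(
            {
                "split": split_no,
                "method": "plsr",
                "train_r2": p_tr.r_squared,
                "train_rmse": p_tr.rmse,
                "test_r2": p_te.r_squared,
                "test_rmse": p_te.rmse,
                "test_r2_ss": p_te.r_squared_ss,
                "n_components": pls.n_components,
            }
        )
    return ValidationReport(table=pd.DataFrame(rows), failures=failures)


def assign_activity_group(activity_clipped: float) -> str:
    """AG1 [0,20), AG2 [20,50), AG3 [50,80), AG4 [80,∞) on clipped activity."""
    if activity_clipped < ACTIVITY_GROUP_BOUNDS["AG2"]:
        return "AG1"
    if activity_clipped < ACTIVITY_GROUP_BOUNDS["AG3"]:
        return "AG2"
    if activity_clipped < ACTIVITY_GROUP_BOUNDS["AG4"]:
        return "AG3"
    return "AG4"


def predict_variants(
    model: LinearModel | PLSModel,
    features: FeatureMatrix,
    clip_range: tuple = (0.0, 150.0),
    model_id: str = "",
    locations: pd.Series | None = None,
) -> pd.DataFrame:
    """Apply a trained model to a feature matrix; bin into activity groups.

    Rows missing any model feature are flagged ``predictable=False`` with
    NaN predictions.  Columns: predicted_activity_raw, predicted_activity
    (clipped), activity_group, predictable, location (optional), model_id.
    """
    needed = model.feature_names
    missing_cols = [c for c in needed if c not in features.values.columns]
    if missing_cols:
        raise KeyError(f"feature matrix lacks model features: {missing_cols}")
    ok = features.complete_rows(needed)
    if len(ok) == 0:
        raise ValueError("no variant has a complete feature set for this model")
    lo, hi = clip_range
    out = pd.DataFrame(index=features.values.index)
    out["predicted_activity_raw"] = np.nan
    raw = model.predict(features.values.loc[ok, needed])
    out.loc[ok, "predicted_activity_raw"] = raw
    out["predicted_activity"] = out["predicted_activity_raw"].clip(lo, hi)
    out["activity_group"] = [
        assign_activity_group(v) if np.isfinite(v) else ""
        for v in out["predicted_activity"]
    ]
    out["predictable"] = out.index.isin(ok)
    if locations is not None:
        out["location"] = locations.reindex(out.index)
    out["model_id"] = model_id
    return out


def annotate_location(
    residues,
    model: CalphaModel,
    chain_roles: dict,
    dna_cutoff: float = 8.0,
    iface_cutoff: float = 8.0,
    neighbor_radius: float = 10.0,
    burial_threshold: int = 16,
) -> list[str]:
    """Structural-location category per (protein_role, residue_number).

    ``chain_roles`` maps role names (e.g. "RAG1", "RAG2", "DNA") to chain
    id tuples of the complex model.  Precedence: near_DNA (min distance of
    the variant's Cα to any DNA-chain site ≤ dna_cutoff) > interface (min
    Cα distance to the partner protein's chains ≤ iface_cutoff) > surface
    vs buried by the number of protein sites within ``neighbor_radius``.
    Residues absent from the model map to ``"unmapped"``.
    """
    chain_of = {}
    for role, chains in chain_roles.items():
        for c in chains:
            chain_of[c] = role
    coords = model.coords
    rid_rows: dict = {}
    for i, rid in enumerate(model.residue_ids):
        rid_rows.setdefault(rid, i)
    roles = np.array(
        [chain_of.get(rid[0], "?") for rid in model.residue_ids], dtype=object
    )
    protein_mask = (roles != "DNA") & (roles != "?")
    dna_xyz = coords[roles == "DNA"]

    categories = []
    for protein, resnum in residues:
        partner = "RAG2" if protein == "RAG1" else "RAG1"
        own_rows = [
            rid_rows[(c, resnum)]
            for c in chain_roles.get(protein, ())
            if (c, resnum) in rid_rows
        ]
        if not own_rows:
            categories.append("unmapped")
            continue
        own_xyz = coords[own_rows]
        if dna_xyz.size and (
            np.min(
                np.linalg.norm(own_xyz[:, None, :] - dna_xyz[None, :, :], axis=-1)
            )
            <= dna_cutoff
        ):
            categories.append("near_DNA")
            continue
        partner_xyz = coords[np.isin(roles, [partner])]
        if partner_xyz.size and (
            np.min(
                np.linalg.norm(
                    own_xyz[:, None, :] - partner_xyz[None, :, :], axis=-1
                )
            )
            <= iface_cutoff
        ):
            categories.append("interface")
            continue
        prot_xyz = coords[protein_mask]
        dists = np.linalg.norm(prot_xyz[None, :, :] - own_xyz[:, None, :], axis=-1)
        # neighbors within radius, not counting the residue's own copies
        n_neighbors = int(np.max(((dists > 1e-9) & (dists <= neighbor_radius)).sum(axis=1)))
        categories.append("surface" if n_neighbors < burial_threshold else "buried")
    return categories
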