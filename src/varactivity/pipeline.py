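"""End-to-end workflow: features → selection/outlier iteration → validation
→ classification → prediction, with a manifest for reproducibility.

The pipeline consumes a variant/score table (measured activity for the
training subset, scores for everyone), runs forward selection with
iterative outlier removal on the labeled complete-case rows, validates
the selected feature set with repeated train/test splits (MLR and
LOO-tuned PLSR), scans activity cutoffs for the best ROC-AUC of a chosen
sequence score, refits the final MLR on all retained observations, and
predicts activity groups for every variant with a complete feature set.

Every run directory gets a ``manifest.json`` recording the config hash,
derived per-stage seeds, package version and per-stage outputs; reruns
with the same manifest inputs are byte-identical for all deterministic
stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import scan_cutoffs
from .features import FeatureMatrix
from .io import config_hash, save_model, stage_seed, write_variant_table
from .regression import fit_ols
from .selection import SelectionConfig, iterate_selection
from .validate import make_splits, predict_variants, run_validation

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "selection": {
        "p_threshold": 1e-3,
        "delta_r2_min": 0.005,
        "max_features": None,
        "qq_rule": 3.0,
        "cooks_rule": None,
        "combine": "union",
        "max_iterations": 10,
    },
    "validation": {"n_splits": 20, "test_size": 10, "max_components": None},
    "classification": {"score_col": "VEST4_S", "lo": 70.0, "hi": 150.0, "step": 1.0},
    "prediction": {"clip": [0.0, 150.0], "refit_full": True},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    """Nested stage parameters; unspecified values take documented defaults."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self):
        self.raw = _merge(DEFAULT_CONFIG, self.raw)

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def hash(self) -> str:
        return config_hash(self.raw)


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    selection: object = None
    validation: object = None
    classification: object = None
    predictions: pd.DataFrame | None = None


def run_pipeline(
    features: FeatureMatrix,
    activity: pd.Series,
    outdir,
    config: PipelineConfig | dict | None = None,
    skip: tuple = (),
) -> PipelineResult:
    """Run the full workflow on an in-memory feature matrix.

    ``activity`` may contain NaN for unlabeled variants — those are used
    only at the prediction stage.  ``skip`` names stages to omit
    ("classify", "validate", "predict").
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.raw,
        "config_hash": config.hash,
        "version": __version__,
        "seeds": {},
        "stages": {},
        "n_variants": int(features.n_variants),
    }
    result = PipelineResult(outdir=outdir, manifest=manifest)
    log_lines: list[str] = [f"varactivity {__version__} config={config.hash}"]

    def _fail(stage: str, exc: Exception):
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    labeled = activity.dropna().index
    score_cols = features.feature_names
    complete = features.complete_rows(score_cols)
    train_ids = [v for v in labeled if v in set(complete)]
    log_lines.append(
        f"labeled={len(labeled)} complete-case training rows={len(train_ids)}"
    )

    # --- selection / outlier iteration -------------------------------------
    sel_cfg = config["selection"]
    try:
        selection = iterate_selection(
            features.values.loc[train_ids],
            activity.loc[train_ids],
            SelectionConfig(
                p_threshold=sel_cfg["p_threshold"],
                delta_r2_min=sel_cfg["delta_r2_min"],
                max_features=sel_cfg["max_features"],
                cooks_rule=sel_cfg["cooks_rule"],
                qq_rule=sel_cfg["qq_rule"],
                combine=sel_cfg["combine"],
                max_iterations=sel_cfg["max_iterations"],
            ),
        )
    except ValueError as exc:
        _fail("select", exc)
    result.selection = selection
    retained = [v for v in train_ids if v not in selection.removed]
    selection_payload = {
        "selected": selection.trace.selected,
        "r2_path": selection.trace.r2_path,
        "p_values": selection.trace.p_values,
        "stop_reason": selection.trace.stop_reason,
        "outliers": {str(k): v for k, v in selection.removed.items()},
        "n_iterations": selection.n_iterations,
        "converged": selection.converged,
        "final_r2": selection.model.r_squared,
        "n_observations": selection.model.n_obs,
    }
    (outdir / "selection.json").write_text(json.dumps(selection_payload, indent=1))
    manifest["stages"]["select"] = {
        "status": "ok",
        "n_selected": len(selection.trace.selected),
        "n_outliers": len(selection.removed),
        "final_r2": selection.model.r_squared,
    }
    log_lines.append(
        f"selected {len(selection.trace.selected)} variables, "
        f"{len(selection.removed)} outliers, R2={selection.model.r_squared:.3f}"
    )

    x_sel = features.values.loc[retained, selection.trace.selected]
    y_sel = activity.loc[retained]

    # --- validation ---------------------------------------------------------
    if "validate" not in skip:
        val_cfg = config["validation"]
        seed = stage_seed(config.seed, "validate")
        manifest["seeds"]["validate"] = seed
        try:
            scheme = make_splits(
                len(retained),
                test_size=val_cfg["test_size"],
                n_splits=val_cfg["n_splits"],
                seed=seed,
            )
            report = run_validation(
                x_sel, y_sel, scheme, max_components=val_cfg["max_components"]
            )
        except ValueError as exc:
            _fail("validate", exc)
        result.validation = report
        report.table.to_csv(outdir / "validation.csv", index=False)
        manifest["stages"]["validate"] = {
            "status": "ok",
            "mean_test_r2_mlr": report.mean_test_r2("mlr"),
            "mean_test_r2_plsr": report.mean_test_r2("plsr"),
            "n_failures": len(report.failures),
        }
        log_lines.append(
            f"validation mean test R2: mlr={report.mean_test_r2('mlr'):.3f} "
            f"plsr={report.mean_test_r2('plsr'):.3f}"
        )

    # --- classification -----------------------------------------------------
    if "classify" not in skip:
        cls_cfg = config["classification"]
        score_col = cls_cfg["score_col"]
        if score_col not in features.values.columns:
            seq_cols = [
                c for c, t in features.categories.items() if t == "seq"
            ]
            if not seq_cols:
                _fail("classify", ValueError("no sequence score column available"))
            score_col = sorted(seq_cols)[0]
            log_lines.append(f"classification falling back to score {score_col}")
        try:
            scan = scan_cutoffs(
                features.values.loc[retained, score_col].to_numpy(),
                y_sel.to_numpy(),
                lo=cls_cfg["lo"],
                hi=cls_cfg["hi"],
                step=cls_cfg["step"],
            )
        except ValueError as exc:
            _fail("classify", exc)
        result.classification = scan
        pd.DataFrame({"cutoff": scan.cutoffs, "auc": scan.aucs}).to_csv(
            outdir / "auc_curve.csv", index=False
        )
        (outdir / "classification.json").write_text(
            json.dumps(
                {
                    "score_col": score_col,
                    "best_cutoff": scan.best_cutoff,
                    "best_auc": scan.best_auc,
                },
                indent=1,
            )
        )
        manifest["stages"]["classify"] = {
            "status": "ok",
            "score_col": score_col,
            "best_cutoff": scan.best_cutoff,
            "best_auc": scan.best_auc,
        }
        log_lines.append(
            f"cutoff scan: best AUC {scan.best_auc:.3f} at {scan.best_cutoff:.0f}%"
        )

    # --- prediction ---------------------------------------------------------
    if "predict" not in skip:
        pred_cfg = config["prediction"]
        try:
            final_model = (
                fit_ols(x_sel, y_sel, observation_index=retained)
                if pred_cfg["refit_full"]
                else selection.model
            )
            model_id = f"mlr-{config.hash}"
            predictions = predict_variants(
                final_model,
                features.select(selection.trace.selected),
                clip_range=tuple(pred_cfg["clip"]),
                model_id=model_id,
            )
        except (ValueError, KeyError) as exc:
            _fail("predict", exc)
        result.predictions = predictions
        save_model(
            final_model,
            outdir / "model.json",
            metadata={"config_hash": config.hash, "version": __version__},
        )
        out = predictions.reset_index().rename(columns={"index": "variant"})
        write_variant_table(out, outdir / "predictions.csv")
        manifest["stages"]["predict"] = {
            "status": "ok",
            "n_predicted": int(predictions["predictable"].sum()),
            "model_id": model_id,
        }
        log_lines.append(
            f"predicted {int(predictions['predictable'].sum())} variants"
        )

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return result
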