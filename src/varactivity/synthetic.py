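"""Synthetic variant tables, toy structures and energy tables with ground truth.

The generator emulates the shape of a variant-effect study dataset: one
row per missense variant carrying a measured recombinase activity (% of
wild type) and a panel of named numeric scores split into sequence-based
(``seq``) and structure-based (``struct``) categories.  Activity is
generated as an exact linear function of a chosen *informative* subset of
scores plus Gaussian noise, then truncated to the assay's activity range;
a configurable fraction of variants is additionally shifted up or down by
a fixed amount to plant outliers whose mechanism the linear model cannot
represent.  Every dataset ships its ground truth (true coefficients,
planted-outlier flags), so downstream selection, regression and outlier
screening can be scored for recovery.

Score marginals are uniform on the nominal [0, 1] range.  Scores with a
requested Pearson correlation to activity are produced via a Gaussian
copula against the pre-truncation activity; the latent correlation is
inflated by √(π/3) to offset the attenuation the uniform marginal
transform causes in Pearson's r.

The study-shaped configuration (:func:`study_config`) reproduces the
conditions of the recovery benchmark: 150 variants, the full 68-score
layout, five informative scores at a target generating R² of 0.9, and
five planted outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .features import FeatureMatrix, study_score_categories, study_score_names
from .gnm import CalphaModel

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_feature_table",
    "generate_helix_coords",
    "generate_residue_energy_tables",
    "noise_sd_for_target_r2",
    "study_config",
    "STUDY_INFORMATIVE_COEFFICIENTS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Pearson attenuation factor of mapping a normal margin to uniform.
_COPULA_INFLATION = math.sqrt(math.pi / 3.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for one synthetic variant/score/activity table."""

    n_variants: int
    coefficients: tuple  # activity % per score unit, one per informative score
    n_noise: int
    noise_sd: float  # activity %
    intercept: float = 100.0
    outlier_fraction: float = 0.0
    outlier_shift: float = 0.0  # activity %
    target_correlations: dict = field(default_factory=dict)
    activity_range: tuple = (0.0, 150.0)
    seed: int = 0
    protein: str = "RAG1"
    informative_names: tuple | None = None
    noise_names: tuple | None = None
    categories: dict | None = None

    def __post_init__(self):
        if self.n_variants < 1:
            raise ValueError("n_variants must be ≥ 1")
        if self.n_noise < 0:
            raise ValueError("n_noise must be non-negative")
        if self.n_informative + self.n_noise < 1:
            raise ValueError("need at least one feature")
        if not (0.0 <= self.outlier_fraction <= 1.0):
            raise ValueError("outlier_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        for name, r in self.target_correlations.items():
            if not abs(r) < 1.0:
                raise ValueError(
                    f"|target correlation| must be < 1 (got {name}={r})"
                )
        if self.informative_names is not None and len(self.informative_names) != (
            self.n_informative
        ):
            raise ValueError("informative_names length must match coefficients")
        if self.noise_names is not None and len(self.noise_names) != self.n_noise:
            raise ValueError("noise_names length must match n_noise")

    @property
    def n_informative(self) -> int:
        return len(self.coefficients)

    def resolved_names(self) -> tuple[list[str], list[str], list[str]]:
        """(informative, noise, correlated) column names, auto-filled if unset."""
        informative = (
            list(self.informative_names)
            if self.informative_names is not None
            else [f"informative_{j + 1:02d}" for j in range(self.n_informative)]
        )
        noise = (
            list(self.noise_names)
            if self.noise_names is not None
            else [f"noise_{j + 1:02d}" for j in range(self.n_noise)]
        )
        correlated = [c for c in self.target_correlations if c not in informative]
        clash = set(correlated) & set(noise)
        if clash:
            raise ValueError(
                f"target_correlations names collide with noise columns: {sorted(clash)}"
            )
        overlap_inf = set(self.target_correlations) & set(informative)
        if overlap_inf:
            raise ValueError(
                "target_correlations cannot target informative columns "
                f"(their correlation is implied by the coefficients): {sorted(overlap_inf)}"
            )
        return informative, noise, correlated

    def resolved_categories(self) -> dict:
        informative, noise, correlated = self.resolved_names()
        if self.categories is not None:
            cats = dict(self.categories)
            missing = (set(informative) | set(noise) | set(correlated)) - set(cats)
            if missing:
                raise ValueError(f"categories missing for columns: {sorted(missing)}")
            return cats
        cats = {c: "struct" for c in informative}
        cats.update({c: "seq" for c in noise})
        cats.update({c: "seq" for c in correlated})
        return cats


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did — enough to score recovery."""

    coefficients: dict  # informative score name → true coefficient
    intercept: float
    noise_sd: float
    outlier_flags: pd.Series  # bool per variant key
    informative_names: tuple
    target_correlations: dict

    @property
    def outlier_ids(self) -> list:
        return list(self.outlier_flags.index[self.outlier_flags])


@dataclass(frozen=True)
class SyntheticDataset:
    features: FeatureMatrix
    activity: pd.Series  # % of WT, truncated to the activity range
    truth: GroundTruth
    protein: str = "RAG1"

    def to_frame(self) -> pd.DataFrame:
        """protein, variant, activity, then score columns (CSV layout)."""
        out = pd.DataFrame(
            {
                "protein": self.protein,
                "variant": [k.split(":", 1)[1] for k in self.features.values.index],
                "activity": self.activity.to_numpy(),
            },
            index=self.features.values.index,
        )
        return pd.concat([out, self.features.values], axis=1)


def noise_sd_for_target_r2(coefficients, target_r2: float) -> float:
    """Noise SD making the generating model's population R² hit the target.

    Informative scores are i.i.d. uniform on [0, 1] (variance 1/12), so the
    signal variance is Σ β²/12 and noise_sd = √(signal_var · (1/R² − 1)).
    """
    if not (0.0 < target_r2 <= 1.0):
        raise ValueError("target_r2 must lie in (0, 1]")
    signal_var = float(np.sum(np.square(coefficients))) / 12.0
    return math.sqrt(signal_var * (1.0 / target_r2 - 1.0))


def _variant_keys(rng: np.random.Generator, n: int, protein: str) -> list[str]:
    positions = rng.choice(np.arange(1, max(4 * n, 100)), size=n, replace=False)
    positions.sort()
    keys = []
    for pos in positions:
        wt, mut = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
        keys.append(f"{protein}:{wt}{int(pos)}{mut}")
    return keys


def generate_feature_table(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a variant × score table with linearly generated activity.

    activity_i = intercept + Σ_j β_j · score_ij + ε_i, ε ~ N(0, noise_sd²),
    a fraction of variants shifted by ±outlier_shift, everything truncated
    to the activity range.  Byte-identical for identical configs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    informative, noise_cols, correlated = config.resolved_names()
    categories = config.resolved_categories()

    keys = _variant_keys(rng, n, config.protein)
    beta = np.asarray(config.coefficients, dtype=float)

    x_inf = rng.uniform(0.0, 1.0, size=(n, len(informative)))
    x_noise = rng.uniform(0.0, 1.0, size=(n, len(noise_cols)))
    eps = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
    activity = config.intercept + x_inf @ beta + eps

    # correlated columns: Gaussian copula against the pre-truncation activity
    corr_data = {}
    if correlated:
        sd = activity.std(ddof=0)
        z_act = (activity - activity.mean()) / (sd if sd > 0 else 1.0)
        for name in correlated:
            rho = float(
                np.clip(config.target_correlations[name] * _COPULA_INFLATION, -0.999, 0.999)
            )
            latent = rho * z_act + math.sqrt(1.0 - rho * rho) * rng.normal(size=n)
            corr_data[name] = norm.cdf(latent)

    flags = np.zeros(n, dtype=bool)
    n_out = int(round(config.outlier_fraction * n))
    if n_out > 0:
        idx = rng.choice(n, size=n_out, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_out)
        activity[idx] += signs * config.outlier_shift
        flags[idx] = True

    lo, hi = config.activity_range
    activity = np.clip(activity, lo, hi)

    values = pd.DataFrame(x_inf, columns=informative, index=keys)
    for j, name in enumerate(noise_cols):
        values[name] = x_noise[:, j]
    for name in correlated:
        values[name] = corr_data[name]
    values.index.name = "variant"

    features = FeatureMatrix(values=values, categories=categories)
    truth = GroundTruth(
        coefficients=dict(zip(informative, beta)),
        intercept=config.intercept,
        noise_sd=config.noise_sd,
        outlier_flags=pd.Series(flags, index=values.index),
        informative_names=tuple(informative),
        target_correlations=dict(config.target_correlations),
    )
    return SyntheticDataset(
        features=features,
        activity=pd.Series(activity, index=values.index, name="activity"),
        truth=truth,
        protein=config.protein,
    )


# ---------------------------------------------------------------------------
# study-shaped benchmark configuration
# ---------------------------------------------------------------------------

#: Informative scores and their effect sizes (% activity per score unit) of
#: the recovery benchmark.  Pathogenicity- and destabilization-like scores
#: get negative signs: higher score ⇒ lower activity.
STUDY_INFORMATIVE_COEFFICIENTS = (
    ("VEST4_S", -60.0),
    ("foldx_total_energy", -45.0),
    ("delta_energy_configurational", -40.0),
    ("REVEL_S", -35.0),
    ("delta_frustration_mutational", 30.0),
)


def study_config(
    seed: int,
    n_variants: int = 150,
    target_r2: float = 0.9,
    n_outliers: int = 5,
    outlier_shift: float = 60.0,
) -> SyntheticConfig:
    """Study-conditions benchmark: 68 named scores, 5 informative, planted outliers.

    The intercept centers the mean activity at 75 % of wild type; noise is
    solved analytically so the generating model's population R² equals
    ``target_r2``.
    """
    informative = [name for name, _ in STUDY_INFORMATIVE_COEFFICIENTS]
    beta = [c for _, c in STUDY_INFORMATIVE_COEFFICIENTS]
    all_names = study_score_names()
    missing = set(informative) - set(all_names)
    if missing:
        raise ValueError(f"informative names not in study layout: {sorted(missing)}")
    noise_cols = [c for c in all_names if c not in informative]
    intercept = 75.0 - 0.5 * float(np.sum(beta))  # uniform scores average 0.5
    return SyntheticConfig(
        n_variants=n_variants,
        coefficients=tuple(beta),
        n_noise=len(noise_cols),
        noise_sd=noise_sd_for_target_r2(beta, target_r2),
        intercept=intercept,
        outlier_fraction=n_outliers / n_variants,
        outlier_shift=outlier_shift,
        seed=seed,
        informative_names=tuple(informative),
        noise_names=tuple(noise_cols),
        categories=study_score_categories(),
    )


# ---------------------------------------------------------------------------
# toy structures and residue energy tables
# ---------------------------------------------------------------------------


def generate_helix_coords(
    n_res: int,
    rise: float = 1.5,
    radius: float = 2.3,
    twist: float = 100.0,
    chain: str = "A",
) -> CalphaModel:
    """Ideal α-helical Cα trace (rise Å/residue, radius Å, twist °/residue)."""
    if n_res < 2:
        raise ValueError("a helix needs at least 2 residues")
    k = np.arange(n_res)
    theta = np.deg2rad(twist) * k
    coords = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * k]
    )
    residue_ids = tuple((chain, int(i + 1)) for i in k)
    return CalphaModel(residue_ids=residue_ids, coords=coords)


def generate_residue_energy_tables(
    n_res: int,
    mutated_position: int,
    planted_deltas: dict,
    seed: int = 0,
    frustration_deltas: dict | None = None,
):
    """Wild-type and mutant per-residue energy/frustration tables.

    The mutant differs from the wild type only at ``mutated_position``:
    energies shift by ``planted_deltas[method]`` and frustration indices
    by ``frustration_deltas[method]`` (both default 0 for absent methods).
    Background values are seeded noise shared between the two tables.
    """
    from .features import FRUSTRATION_METHODS, ResidueEnergyTable

    if not (1 <= mutated_position <= n_res):
        raise ValueError(
            f"mutated_position {mutated_position} out of range 1..{n_res}"
        )
    unknown = set(planted_deltas) - set(FRUSTRATION_METHODS)
    if unknown:
        raise ValueError(f"unknown methods in planted_deltas: {sorted(unknown)}")
    frustration_deltas = frustration_deltas or {}
    rng = np.random.default_rng(seed)
    rows = []
    for res in range(1, n_res + 1):
        for method in FRUSTRATION_METHODS:
            rows.append(
                {
                    "residue_id": res,
                    "method": method,
                    "energy": float(rng.normal(0.0, 1.0)),
                    "frustration_index": float(rng.normal(0.0, 1.0)),
                }
            )
    wt_df = pd.DataFrame(rows)
    mut_df = wt_df.copy()
    at = mut_df["residue_id"] == mutated_position
    for method, delta in planted_deltas.items():
        sel = at & (mut_df["method"] == method)
        mut_df.loc[sel, "energy"] += float(delta)
    for method, delta in frustration_deltas.items():
        sel = at & (mut_df["method"] == method)
        mut_df.loc[sel, "frustration_index"] += float(delta)
    return ResidueEnergyTable(wt_df), ResidueEnergyTable(mut_df)
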