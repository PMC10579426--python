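"""Structure-derived feature engineering and feature-matrix assembly.

Two kinds of structure-based variant features are produced here:

* frustration/energy scores derived from per-residue tables (wild type vs
  mutant) as written by local-frustration analysis tools.  Each table
  carries three estimation methods — ``configurational``, ``mutational``
  and ``single_residue`` — with an energy and a frustration index per
  residue.  The ``default21`` schema turns a (wt, mut) pair into 21 named
  scores: per method, the wild-type and mutant energy sums and their
  difference, the same triple for the frustration index, and the change in
  the count of highly frustrated entries (frustration index < −1).

* the joined variant × score feature matrix combining sequence-based
  pathogenicity scores (tagged ``seq``) with structure-based energy,
  frustration and flexibility scores (tagged ``struct``).  The study-shaped
  layout has 68 score columns: 22 dbNSFP-style predictors, 4 VARITY models
  and 5 esm1v models on the sequence side, 16 FoldX energy terms and the
  21 frustration-derived scores on the structure side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FRUSTRATION_METHODS",
    "HIGH_FRUSTRATION_THRESHOLD",
    "ResidueEnergyTable",
    "DerivedScoreSet",
    "derive_frustration_scores",
    "default21_score_names",
    "FeatureMatrix",
    "ScoreSource",
    "assemble_feature_matrix",
    "SEQUENCE_SCORE_NAMES",
    "FOLDX_SCORE_NAMES",
    "study_score_names",
    "study_score_categories",
]

FRUSTRATION_METHODS = ("configurational", "mutational", "single_residue")

#: A contact/residue with frustration index below this is "highly frustrated".
HIGH_FRUSTRATION_THRESHOLD = -1.0


# ---------------------------------------------------------------------------
# per-residue energy/frustration tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidueEnergyTable:
    """Per-residue, per-method energy and frustration-index table.

    Backed by a DataFrame with columns ``residue_id, method, energy,
    frustration_index``; one row per (residue, method), all three methods
    present for every listed residue.
    """

    data: pd.DataFrame

    REQUIRED_COLUMNS = ("residue_id", "method", "energy", "frustration_index")

    def __post_init__(self):
        df = self.data
        missing = [c for c in self.REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        unknown = set(df["method"]) - set(FRUSTRATION_METHODS)
        if unknown:
            raise ValueError(f"unknown frustration methods: {sorted(unknown)}")
        if df.duplicated(["residue_id", "method"]).any():
            dups = df[df.duplicated(["residue_id", "method"], keep=False)]
            raise ValueError(
                f"duplicate (residue, method) rows: {dups[['residue_id', 'method']].values.tolist()}"
            )
        counts = df.groupby("residue_id")["method"].nunique()
        incomplete = counts[counts != len(FRUSTRATION_METHODS)]
        if len(incomplete):
            raise ValueError(
                f"residues missing methods: {incomplete.index.tolist()}"
            )

    @property
    def residue_ids(self) -> np.ndarray:
        return np.unique(self.data["residue_id"].to_numpy())

    def lookup(self, residue_id, method: str) -> tuple[float, float]:
        """(energy, frustration_index) for one residue and method."""
        rows = self.data[
            (self.data["residue_id"] == residue_id)
            & (self.data["method"] == method)
        ]
        if rows.empty:
            raise KeyError(f"no entry for residue {residue_id}, method {method!r}")
        row = rows.iloc[0]
        return float(row["energy"]), float(row["frustration_index"])

    def method_frame(self, method: str) -> pd.DataFrame:
        return self.data[self.data["method"] == method]


def default21_score_names() -> list[str]:
    """The 21 score names of the ``default21`` frustration schema, in order."""
    names = []
    for method in FRUSTRATION_METHODS:
        names += [
            f"energy_{method}_wt",
            f"energy_{method}_mut",
            f"delta_energy_{method}",
            f"frustration_{method}_wt",
            f"frustration_{method}_mut",
            f"delta_frustration_{method}",
        ]
    names += [f"delta_high_frustration_count_{m}" for m in FRUSTRATION_METHODS]
    return names


@dataclass(frozen=True)
class DerivedScoreSet:
    """Named frustration-derived scores (plus optional FoldX pass-through)
    for a single variant. Missing inputs yield NaN entries, never silent zeros."""

    scores: dict
    schema: str = "default21"

    def __post_init__(self):
        if self.schema == "default21":
            expected = set(default21_score_names())
            frustration_keys = {
                k for k in self.scores if k in expected
            }
            if frustration_keys != expected:
                raise ValueError(
                    f"default21 schema requires exactly {len(expected)} "
                    f"frustration keys; missing {sorted(expected - frustration_keys)}"
                )

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, dtype=float)


def derive_frustration_scores(
    wt: ResidueEnergyTable,
    mut: ResidueEnergyTable,
    mutated_position,
    schema: str = "default21",
    foldx_terms: dict | None = None,
) -> DerivedScoreSet:
    """Derive the per-variant frustration scores from wt/mut residue tables.

    Sums are taken over the mutated residue's entries; differences are
    mutant − wild type (antisymmetric under swapping the two tables).
    A method absent from either table yields NaN for its scores.
    """
    if schema != "default21":
        raise ValueError(f"unknown schema {schema!r}")
    scores: dict = {}
    for method in FRUSTRATION_METHODS:
        try:
            e_wt, f_wt = wt.lookup(mutated_position, method)
        except KeyError:
            e_wt = f_wt = np.nan
        try:
            e_mut, f_mut = mut.lookup(mutated_position, method)
        except KeyError:
            e_mut = f_mut = np.nan
        scores[f"energy_{method}_wt"] = e_wt
        scores[f"energy_{method}_mut"] = e_mut
        scores[f"delta_energy_{method}"] = e_mut - e_wt
        scores[f"frustration_{method}_wt"] = f_wt
        scores[f"frustration_{method}_mut"] = f_mut
        scores[f"delta_frustration_{method}"] = f_mut - f_wt

        # change in number of highly frustrated entries across the chain
        wt_frame = wt.method_frame(method)
        mut_frame = mut.method_frame(method)
        if wt_frame.empty or mut_frame.empty:
            scores[f"delta_high_frustration_count_{method}"] = np.nan
        else:
            n_wt = int(
                (wt_frame["frustration_index"] < HIGH_FRUSTRATION_THRESHOLD).sum()
            )
            n_mut = int(
                (mut_frame["frustration_index"] < HIGH_FRUSTRATION_THRESHOLD).sum()
            )
            scores[f"delta_high_frustration_count_{method}"] = float(n_mut - n_wt)
    if foldx_terms:
        overlap = set(foldx_terms) & set(scores)
        if overlap:
            raise ValueError(f"FoldX term names collide with schema keys: {overlap}")
        scores.update({k: float(v) for k, v in foldx_terms.items()})
    return DerivedScoreSet(scores=scores, schema=schema)


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Variants × named numeric scores with category tags and a missing mask.

    ``values`` is a DataFrame indexed by variant key (e.g. ``RAG1:G709S``);
    ``categories`` maps each column to ``"seq"`` or ``"struct"``.  Activity
    is deliberately *not* a column here — it travels alongside as the
    regression outcome.
    """

    values: pd.DataFrame
    categories: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature columns: {dup}")
        unknown = set(self.categories) - set(self.values.columns)
        if unknown:
            raise ValueError(f"categories for unknown columns: {sorted(unknown)}")
        bad = {c: t for c, t in self.categories.items() if t not in ("seq", "struct")}
        if bad:
            raise ValueError(f"invalid category tags: {bad}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_variants(self) -> int:
        return len(self.values)

    def complete_rows(self, columns=None) -> pd.Index:
        """Index of variants with no missing value in the given columns."""
        sub = self.values if columns is None else self.values[list(columns)]
        return sub.index[~sub.isna().any(axis=1)]

    def select(self, columns) -> "FeatureMatrix":
        cols = list(columns)
        return FeatureMatrix(
            values=self.values[cols].copy(),
            categories={c: self.categories[c] for c in cols if c in self.categories},
        )


@dataclass(frozen=True)
class ScoreSource:
    """One named table of scores keyed by (protein, variant)."""

    name: str
    table: pd.DataFrame  # indexed by variant key, columns are score names
    category: str  # "seq" or "struct"

    def __post_init__(self):
        if self.category not in ("seq", "struct"):
            raise ValueError(f"category must be seq|struct, got {self.category!r}")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"source {self.name!r} has duplicate variants: {dup}")


def assemble_feature_matrix(variant_keys, sources) -> FeatureMatrix:
    """Left-join score sources onto the variant list.

    Variants absent from a source keep their row with those cells masked
    (NaN).  Duplicate column names across sources are an error, as are
    duplicate variant rows within a source (checked at ScoreSource
    construction).
    """
    keys = list(variant_keys)
    if len(set(keys)) != len(keys):
        seen: set = set()
        dups = [k for k in keys if k in seen or seen.add(k)]
        raise ValueError(f"duplicate variant keys: {dups}")
    frames = []
    categories: dict = {}
    for src in sources:
        clash = set(src.table.columns) & set(categories)
        if clash:
            raise ValueError(
                f"duplicate score columns across sources: {sorted(clash)}"
            )
        frames.append(src.table.reindex(keys))
        categories.update({c: src.category for c in src.table.columns})
    values = pd.concat(frames, axis=1) if frames else pd.DataFrame(index=keys)
    values.index = pd.Index(keys, name="variant")
    return FeatureMatrix(values=values, categories=categories)


# ---------------------------------------------------------------------------
# study-shaped score schema: 68 named scores
# ---------------------------------------------------------------------------

#: 22 dbNSFP-style predictors + 4 VARITY models + 5 esm1v models = 31 seq scores.
SEQUENCE_SCORE_NAMES = (
    "SIFT_S",
    "SIFT4G_S",
    "PolyPhen2_HDIV_S",
    "PolyPhen2_HVAR_S",
    "LRT_S",
    "MutationTaster_S",
    "MutationAssessor_S",
    "FATHMM_S",
    "PROVEAN_S",
    "VEST4_S",
    "MetaSVM_S",
    "MetaLR_S",
    "M_CAP_S",
    "REVEL_S",
    "MutPred_S",
    "MVP_S",
    "PrimateAI_S",
    "DEOGEN2_S",
    "CADD_S",
    "DANN_S",
    "GenoCanyon_S",
    "LIST_S2_S",
    "VARITY_R",
    "VARITY_ER",
    "VARITY_R_LOO",
    "VARITY_ER_LOO",
    "esm1v_1",
    "esm1v_2",
    "esm1v_3",
    "esm1v_4",
    "esm1v_5",
)

#: 16 FoldX empirical energy terms consumed as structure features.
FOLDX_SCORE_NAMES = (
    "foldx_total_energy",
    "foldx_backbone_hbond",
    "foldx_sidechain_hbond",
    "foldx_van_der_waals",
    "foldx_electrostatics",
    "foldx_solvation_polar",
    "foldx_solvation_hydrophobic",
    "foldx_vdw_clashes",
    "foldx_entropy_sidechain",
    "foldx_entropy_mainchain",
    "foldx_torsional_clash",
    "foldx_backbone_clash",
    "foldx_helix_dipole",
    "foldx_disulfide",
    "foldx_electrostatic_kon",
    "foldx_energy_ionisation",
)


def study_score_names() -> list[str]:
    """All 68 score names of the study-shaped feature layout."""
    return (
        list(SEQUENCE_SCORE_NAMES)
        + list(FOLDX_SCORE_NAMES)
        + default21_score_names()
    )


def study_score_categories() -> dict:
    """Category tag (seq|struct) for every study-shaped score column."""
    cats = {name: "seq" for name in SEQUENCE_SCORE_NAMES}
    cats.update({name: "struct" for name in FOLDX_SCORE_NAMES})
    cats.update({name: "struct" for name in default21_score_names()})
    return cats
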