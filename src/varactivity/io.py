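"""Readers and writers for the pipeline's external formats.

Formats: delimited text (CSV default, TSV accepted) for variant/score and
per-residue energy tables, minimal PDB for Cα coordinate fixtures, JSON
for models/reports/manifests and the feature-category sidecar, YAML for
configuration.  Every writer has a paired reader that reproduces the
in-memory values.

Variant notation is one-letter amino acids with 1-based protein
coordinates (``G709S``); three-letter and ``p.``-prefixed forms are
accepted and normalized.  Unparseable rows are collected in a rejects
report with line numbers — never dropped silently.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

from .features import (
    FeatureMatrix,
    ResidueEnergyTable,
    study_score_categories,
)
from .gnm import CalphaModel

__all__ = [
    "VariantRecord",
    "VariantParseError",
    "RejectReport",
    "parse_substitution",
    "read_variant_table",
    "write_variant_table",
    "write_feature_matrix",
    "read_feature_matrix",
    "read_calpha_pdb",
    "write_calpha_pdb",
    "read_residue_energy_table",
    "write_residue_energy_table",
    "save_model",
    "load_model",
    "SimplePredictor",
    "config_hash",
    "stage_seed",
]

AA1 = set("ACDEFGHIKLMNPQRSTVWY")

_SUB_ONE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")
_SUB_THREE = re.compile(r"^(?:p\.)?([A-Za-z]{3})(\d+)([A-Za-z]{3})$")


class VariantParseError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    """One protein missense substitution, optionally with measured activity."""

    protein: str
    wt: str
    position: int
    mut: str
    activity: float | None = None
    source: str = ""

    def __post_init__(self):
        if self.wt == self.mut:
            raise VariantParseError(
                f"synonymous substitution {self.wt}{self.position}{self.mut}"
            )
        if self.wt not in AA1 or self.mut not in AA1:
            raise VariantParseError(
                f"unknown amino acid in {self.wt}{self.position}{self.mut}"
            )
        if self.position < 1:
            raise VariantParseError(f"position must be ≥ 1, got {self.position}")
        if self.activity is not None and self.activity < 0:
            raise VariantParseError(f"negative activity {self.activity}")

    @property
    def substitution(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"

    @property
    def key(self) -> str:
        return f"{self.protein}:{self.substitution}"


def parse_substitution(text: str) -> tuple[str, int, str]:
    """Normalize ``G709S`` / ``Gly709Ser`` / ``p.Gly709Ser`` to (wt, pos, mut)."""
    s = str(text).strip()
    m = _SUB_ONE.match(s)
    if m:
        return m.group(1), int(m.group(2)), m.group(3)
    m = _SUB_THREE.match(s)
    if m:
        try:
            wt = seq1(m.group(1).capitalize())
            mut = seq1(m.group(3).capitalize())
        except Exception as exc:  # unknown three-letter code
            raise VariantParseError(f"cannot parse substitution {text!r}") from exc
        if wt == "X" or mut == "X":
            raise VariantParseError(f"unknown residue code in {text!r}")
        return wt, int(m.group(2)), mut
    raise VariantParseError(f"cannot parse substitution {text!r}")


@dataclass
class RejectReport:
    """Rows a reader refused, with their line numbers and reasons."""

    rejects: list = field(default_factory=list)  # (line_no, raw, reason)

    def add(self, line_no: int, raw, reason: str) -> None:
        self.rejects.append((line_no, raw, reason))

    def __len__(self) -> int:
        return len(self.rejects)


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect in ("csv", "comma"):
        return ","
    if dialect in ("tsv", "tab"):
        return "\t"
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_variant_table(
    path,
    dialect: str | None = None,
    categories: dict | None = None,
    column_map: dict | None = None,
):
    """Read a variant/score table → (records, FeatureMatrix, rejects).

    Expected columns (renameable via ``column_map``): ``protein``,
    ``variant``, optional ``activity``, then numeric score columns.
    Duplicate variant ids are an error naming the duplicates.  Rows with
    unparseable substitutions or negative activity land in the rejects
    report with their (1-based, header-inclusive) line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    if column_map:
        df = df.rename(columns=column_map)
    for col in ("protein", "variant"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path}")
    has_activity = "activity" in df.columns
    score_cols = [
        c for c in df.columns if c not in ("protein", "variant", "activity")
    ]

    records: list[VariantRecord] = []
    keys: list[str] = []
    keep_rows: list[int] = []
    rejects = RejectReport()
    for i, row in df.iterrows():
        line_no = int(i) + 2  # header is line 1
        try:
            wt, pos, mut = parse_substitution(row["variant"])
            activity = None
            if has_activity and pd.notna(row["activity"]):
                activity = float(row["activity"])
            rec = VariantRecord(
                protein=str(row["protein"]), wt=wt, position=pos, mut=mut,
                activity=activity,
            )
        except (VariantParseError, ValueError) as exc:
            rejects.add(line_no, row["variant"], str(exc))
            continue
        records.append(rec)
        keys.append(rec.key)
        keep_rows.append(i)

    dup = pd.Index(keys)[pd.Index(keys).duplicated()]
    if len(dup):
        raise ValueError(f"duplicate variant ids in {path}: {sorted(set(dup))}")

    values = df.loc[keep_rows, score_cols].apply(pd.to_numeric, errors="coerce")
    values.index = pd.Index(keys, name="variant")
    if categories is None:
        sidecar = path.with_suffix(path.suffix + ".categories.json")
        if sidecar.exists():
            categories = json.loads(sidecar.read_text())
        else:
            known = study_score_categories()
            categories = {c: known.get(c, "seq") for c in score_cols}
    features = FeatureMatrix(values=values, categories=categories)
    return records, features, rejects


def write_variant_table(frame: pd.DataFrame, path, categories: dict | None = None):
    """Write a protein/variant/activity/scores table (CSV or TSV by suffix).

    A ``<name>.categories.json`` sidecar records the seq/struct tag of each
    score column when ``categories`` is given.
    """
    path = Path(path)
    frame.to_csv(path, sep=_sep_for(path, None), index=False)
    if categories is not None:
        sidecar = path.with_suffix(path.suffix + ".categories.json")
        sidecar.write_text(json.dumps(categories, indent=1, sort_keys=True))


def write_feature_matrix(features: FeatureMatrix, path) -> None:
    path = Path(path)
    features.values.to_csv(path, sep=_sep_for(path, None))
    sidecar = path.with_suffix(path.suffix + ".categories.json")
    sidecar.write_text(json.dumps(features.categories, indent=1, sort_keys=True))


def read_feature_matrix(path) -> FeatureMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep=_sep_for(path, None), index_col=0)
    sidecar = path.with_suffix(path.suffix + ".categories.json")
    categories = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return FeatureMatrix(values=values, categories=categories)


# ---------------------------------------------------------------------------
# minimal PDB
# ---------------------------------------------------------------------------


def read_calpha_pdb(path, atom_names: tuple = ("CA",)) -> CalphaModel:
    """Read a Cα (or other single-atom-per-residue) model from PDB ATOM records.

    Residues are identified by (chain id, residue number); insertion codes
    are rejected with a diagnostic since the pipeline's residue keys
    cannot represent them.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    residue_ids, coords = [], []
    for pdb_model in structure:
        for chain in pdb_model:
            for residue in chain:
                hetflag, resseq, icode = residue.get_id()
                if hetflag.strip():
                    continue
                if icode.strip():
                    raise ValueError(
                        f"insertion code {icode!r} at {chain.id}{resseq} in {path}; "
                        "renumber the model first"
                    )
                atom = next(
                    (residue[name] for name in atom_names if name in residue), None
                )
                if atom is None:
                    continue
                residue_ids.append((chain.id, int(resseq)))
                coords.append(atom.get_coord())
        break  # first MODEL only
    if len(coords) < 2:
        raise ValueError(f"fewer than 2 {'/'.join(atom_names)} atoms in {path}")
    return CalphaModel(residue_ids=tuple(residue_ids), coords=np.asarray(coords, float))


def write_calpha_pdb(model: CalphaModel, path) -> None:
    """Write ATOM records (CA only) for a Cα model; chain from residue ids."""
    lines = []
    for serial, (rid, xyz) in enumerate(zip(model.residue_ids, model.coords), 1):
        chain, resseq = rid
        lines.append(
            f"ATOM  {serial:>5}  CA  GLY {chain}{resseq:>4}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# per-residue energy tables
# ---------------------------------------------------------------------------


def read_residue_energy_table(path) -> ResidueEnergyTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, None))
    return ResidueEnergyTable(df)


def write_residue_energy_table(table: ResidueEnergyTable, path) -> None:
    path = Path(path)
    table.data.to_csv(path, sep=_sep_for(path, None), index=False)


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimplePredictor:
    """Deserialized regression model: enough to predict, nothing more."""

    kind: str  # mlr | plsr
    feature_names: list[str]
    params: dict
    metadata: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            arr = X[self.feature_names].to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
        if self.kind == "mlr":
            return self.params["intercept"] + arr @ np.asarray(
                self.params["coefficients"]
            )
        xs = (arr - np.asarray(self.params["x_mean"])) / np.asarray(
            self.params["x_scale"]
        )
        return self.params["y_mean"] + xs @ np.asarray(
            self.params["coefficients_std_scale"]
        )


def save_model(model, path, metadata: dict | None = None) -> None:
    """Serialize a fitted LinearModel/PLSModel to JSON with metadata."""
    payload = model.to_dict()
    payload["metadata"] = metadata or {}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> SimplePredictor:
    payload = json.loads(Path(path).read_text())
    kind = payload.pop("kind")
    metadata = payload.pop("metadata", {})
    names = payload.pop("feature_names")
    return SimplePredictor(
        kind=kind, feature_names=names, params=payload, metadata=metadata
    )


# ---------------------------------------------------------------------------
# config hashing and seed derivation
# ---------------------------------------------------------------------------


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2³¹)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
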