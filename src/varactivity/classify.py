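"""Two-class classification of variants from a continuous score.

Measured recombinase activity (% of wild type) is binarized at a cutoff:
label 1 means *impaired* (activity strictly below the cutoff), label 0
means at-or-above.  A sequence-based pathogenicity score is then assessed
as a classifier of that binarization: higher score ⇒ impaired.  The AUC
is the Mann-Whitney concordance probability with half-credit for score
ties (exact and reproducible); the ROC curve itself comes from a
threshold sweep.  Scanning the cutoff over a grid (70–150 % by default)
finds the activity threshold at which the score separates best.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

__all__ = [
    "ROCCurve",
    "CutoffScanResult",
    "ConfusionSummary",
    "DegenerateLabelsError",
    "binarize_activity",
    "roc_auc",
    "scan_cutoffs",
    "confusion_at",
]


class DegenerateLabelsError(ValueError):
    """Raised when one of the two classes is empty."""


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray  # score thresholds of the sweep, decreasing
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc must lie in [0, 1]")


@dataclass(frozen=True)
class CutoffScanResult:
    cutoffs: np.ndarray  # activity cutoffs (% WT) actually evaluated
    aucs: np.ndarray
    best_cutoff: float
    best_auc: float
    class_sizes: list  # (n_below, n_above) per evaluated cutoff
    skipped_cutoffs: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float  # operating score threshold (predict 1 if score ≥ t)
    sensitivity: float  # accuracy on the impaired ("below") class
    specificity: float  # accuracy on the intact ("above") class
    accuracy: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def binarize_activity(activity, cutoff: float) -> np.ndarray:
    """1 for activity strictly below cutoff (impaired), else 0.

    A value exactly equal to the cutoff is labelled 0 (the "above" class).
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    y = np.asarray(activity, dtype=float)
    return (y < cutoff).astype(int)


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve and Mann-Whitney AUC of a score for binary labels.

    Higher score ⇒ class 1.  AUC = (R₁ − n₁(n₁+1)/2) / (n₁ n₀) with
    mid-ranks, i.e. tied scores earn half credit.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=int)
    if s.shape != lab.shape:
        raise ValueError("scores and labels length mismatch")
    n1 = int(lab.sum())
    n0 = lab.size - n1
    if n1 == 0 or n0 == 0:
        raise DegenerateLabelsError(
            f"both classes must be non-empty (n_pos={n1}, n_neg={n0})"
        )
    ranks = rankdata(s)  # mid-ranks → half credit for ties
    auc = (ranks[lab == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    fpr, tpr, thresholds = roc_curve(lab, s)
    return ROCCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(auc))


def scan_cutoffs(
    scores,
    activity,
    lo: float = 70.0,
    hi: float = 150.0,
    step: float = 1.0,
) -> CutoffScanResult:
    """AUC of the score at every activity cutoff on the grid lo..hi.

    Cutoffs where one class would be empty are skipped and recorded.
    Best cutoff is the argmax of AUC; exact ties go to the lowest cutoff.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    grid = np.arange(lo, hi + 0.5 * step, step)
    if grid.size == 0:
        raise ValueError("empty cutoff grid")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(activity, dtype=float)
    cutoffs, aucs, sizes, skipped = [], [], [], []
    for cutoff in grid:
        labels = binarize_activity(y, cutoff)
        n1 = int(labels.sum())
        if n1 == 0 or n1 == labels.size:
            skipped.append(cutoff)
            continue
        cutoffs.append(float(cutoff))
        aucs.append(roc_auc(s, labels).auc)
        sizes.append((n1, labels.size - n1))
    if not cutoffs:
        raise DegenerateLabelsError(
            f"no admissible cutoff in [{lo}, {hi}]: every grid point leaves "
            "a single class"
        )
    aucs_arr = np.asarray(aucs)
    best = int(np.argmax(aucs_arr))  # first max → lowest cutoff on ties
    return CutoffScanResult(
        cutoffs=np.asarray(cutoffs),
        aucs=aucs_arr,
        best_cutoff=cutoffs[best],
        best_auc=float(aucs_arr[best]),
        class_sizes=sizes,
        skipped_cutoffs=np.asarray(skipped),
    )


def confusion_at(scores, labels, operating_rule="youden") -> ConfusionSummary:
    """Confusion counts and class-conditional accuracies at a threshold.

    ``operating_rule`` is either ``"youden"`` (threshold maximizing
    TPR − FPR on the ROC; ties → lower threshold) or a number used as a
    fixed score threshold.  Prediction rule: label 1 if score ≥ threshold.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=int)
    n1 = int(lab.sum())
    if n1 == 0 or n1 == lab.size:
        raise DegenerateLabelsError("both classes must be non-empty")
    if operating_rule == "youden":
        candidates = np.unique(s)
        best_t, best_j = None, -np.inf
        for t in candidates:  # ascending → on J ties keep the lowest threshold
            pred = s >= t
            tpr = (pred & (lab == 1)).sum() / n1
            fpr = (pred & (lab == 0)).sum() / (lab.size - n1)
            j = tpr - fpr
            if j > best_j + 1e-15:
                best_j, best_t = j, t
        threshold = float(best_t)
    else:
        threshold = float(operating_rule)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (lab == 1)).sum())
    fp = int(((pred == 1) & (lab == 0)).sum())
    tn = int(((pred == 0) & (lab == 0)).sum())
    fn = int(((pred == 0) & (lab == 1)).sum())
    return ConfusionSummary(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        threshold=threshold,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / lab.size,
    )
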