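"""Segmentation and screening evaluation: IoU, confusion metrics, ROC, OLS.

Conventions:

* IoU of two empty masks is 1.0 (perfect agreement on "nothing there");
  exactly one empty mask gives 0.0.  The same convention is used by the
  training harness when it tracks validation IoU.
* The positive class for screening is *dry eye*.  Because a lower TMH means
  more positive, the ROC score is the negated TMH; the sweep runs over all
  unique scores plus a sentinel, and the AUC is the trapezoidal area, which
  equals the tie-corrected Mann–Whitney rank statistic.
* Regression agreement fits ordinary least squares of the manual (reference)
  TMH on the automatic TMH and reports R² = SSR/SST, which for OLS with an
  intercept equals the usual 1 − SSE/SST.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .core import DRY_EYE_THRESHOLD_MM, MeniscusMask, UndefinedMetricError, as_bool_mask
from .metry import NoMeniscusError, measure_tmh

__all__ = [
    "ConfusionMatrix",
    "RocResult",
    "RegressionResult",
    "EvalReport",
    "iou",
    "mean_iou",
    "confusion",
    "sensitivity",
    "specificity",
    "youden",
    "roc_auc",
    "regression_agreement",
    "evaluate",
]


def iou(a, b) -> float:
    """Intersection over union of two same-shape binary masks."""
    pa, pb = as_bool_mask(a), as_bool_mask(b)
    if pa.shape != pb.shape:
        raise ValueError(f"mask shapes differ: {pa.shape} vs {pb.shape}")
    union = np.logical_or(pa, pb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pa, pb).sum() / union)


def mean_iou(pairs: Sequence[tuple]) -> float:
    """Arithmetic mean of per-image IoU over (predicted, truth) pairs."""
    if len(pairs) == 0:
        raise ValueError("mean_iou needs at least one (predicted, truth) pair")
    return float(np.mean([iou(p, t) for p, t in pairs]))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predicted_labels, true_labels) -> ConfusionMatrix:
    """Tally a 2x2 confusion matrix; positive class = dry eye = True."""
    pred = np.asarray(predicted_labels, dtype=bool)
    true = np.asarray(true_labels, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError(
            f"label lengths differ: {pred.shape[0]} predicted vs {true.shape[0]} true"
        )
    return ConfusionMatrix(
        tp=int(np.sum(pred & true)),
        fp=int(np.sum(pred & ~true)),
        tn=int(np.sum(~pred & ~true)),
        fn=int(np.sum(~pred & true)),
    )


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN): the fraction of dry eyes correctly flagged."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive (dry-eye) cases")
    return cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP): the fraction of normals correctly passed."""
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative (normal) cases")
    return cm.tn / (cm.tn + cm.fp)


def youden(cm: ConfusionMatrix) -> float:
    """Youden index = sensitivity + specificity − 1, bounded in [−1, 1]."""
    return sensitivity(cm) + specificity(cm) - 1.0


@dataclass
class RocResult:
    """ROC sweep over TMH thresholds for dry-eye discrimination.

    ``thresholds`` are the swept score cutoffs (score = −TMH in mm), starting
    with a sentinel above every score so the curve begins at (0, 0).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_auc(tmh_values, true_dry_eye) -> RocResult:
    """ROC curve and trapezoidal AUC for dry-eye discrimination from TMH.

    Lower TMH is more indicative of dry eye, so samples are scored by −TMH.
    Ties are handled by sweeping unique scores only, which makes the
    trapezoidal area equal to the tie-corrected rank (Mann–Whitney) statistic.
    """
    tmh = np.asarray(tmh_values, dtype=float)
    true = np.asarray(true_dry_eye, dtype=bool)
    if tmh.shape != true.shape:
        raise ValueError("tmh_values and true_dry_eye must have equal length")
    n_pos = int(true.sum())
    n_neg = int(true.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            "ROC undefined: both dry-eye and normal cases are required"
        )
    scores = -tmh
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_true = true[order]
    # indices where the score strictly drops: each is one swept threshold
    distinct = np.flatnonzero(np.diff(sorted_scores))
    cuts = np.r_[distinct, sorted_true.size - 1]
    tps = np.cumsum(sorted_true)[cuts]
    fps = 1 + cuts - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[cuts]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    ssr: float
    sst: float


def regression_agreement(auto_tmh, manual_tmh) -> RegressionResult:
    """OLS of manual TMH (reference) on automatic TMH; R² = SSR/SST."""
    x = np.asarray(auto_tmh, dtype=float)
    y = np.asarray(manual_tmh, dtype=float)
    if x.shape != y.shape:
        raise ValueError("auto_tmh and manual_tmh must have equal length")
    if x.size < 3:
        raise ValueError(f"regression needs at least 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("regression undefined: zero variance in TMH values")
    xbar, ybar = x.mean(), y.mean()
    slope = float(np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2))
    intercept = float(ybar - slope * xbar)
    yhat = slope * x + intercept
    ssr = float(np.sum((yhat - ybar) ** 2))
    sst = float(np.sum((y - ybar) ** 2))
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r_squared=ssr / sst,
        ssr=ssr,
        sst=sst,
    )


@dataclass
class EvalReport:
    """Aggregate evaluation of a segmentation + measurement run."""

    mean_iou: float
    per_image_iou: list[float]
    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    youden: float
    roc: RocResult
    regression: RegressionResult
    threshold_mm: float
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "mean_iou": self.mean_iou,
            "per_image_iou": list(self.per_image_iou),
            "confusion": asdict(self.confusion),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "youden": self.youden,
            "auc": self.roc.auc,
            "roc": {
                "thresholds": self.roc.thresholds.tolist(),
                "fpr": self.roc.fpr.tolist(),
                "tpr": self.roc.tpr.tolist(),
            },
            "regression": asdict(self.regression),
            "threshold_mm": self.threshold_mm,
            "n_failed": self.n_failed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def plot_roc(self, path) -> None:
        """Save the ROC curve (AUC in the legend) as a figure."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(self.roc.fpr, self.roc.tpr, label=f"AUC = {self.roc.auc:.3f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def evaluate(
    pred_masks: Sequence,
    true_masks: Sequence,
    manual_tmh_mm: Sequence[float],
    mm_per_px: float,
    threshold_mm: float = DRY_EYE_THRESHOLD_MM,
) -> EvalReport:
    """Full evaluation of predicted masks against reference masks and TMH.

    Computes per-image IoU, measures TMH on every predicted mask, classifies
    both the automatic and the manual readings at ``threshold_mm``, and
    reports the confusion matrix, sensitivity/specificity/Youden, the ROC
    sweep over the continuous automatic TMH, and the OLS agreement of manual
    on automatic TMH.  A predicted mask with no meniscus is scored as TMH
    0 mm (maximally dry) and counted in ``n_failed``.
    """
    if not (len(pred_masks) == len(true_masks) == len(manual_tmh_mm)):
        raise ValueError(
            "pred_masks, true_masks and manual_tmh_mm must be aligned: got "
            f"{len(pred_masks)}/{len(true_masks)}/{len(manual_tmh_mm)} records"
        )
    per_image = [iou(p, t) for p, t in zip(pred_masks, true_masks)]
    auto = np.empty(len(pred_masks))
    n_failed = 0
    for i, mask in enumerate(pred_masks):
        try:
            auto[i] = measure_tmh(mask, mm_per_px, threshold_mm).tmh_mm
        except NoMeniscusError:
            auto[i] = 0.0
            n_failed += 1
    manual = np.asarray(manual_tmh_mm, dtype=float)
    pred_labels = auto < threshold_mm
    true_labels = manual < threshold_mm
    cm = confusion(pred_labels, true_labels)
    return EvalReport(
        mean_iou=float(np.mean(per_image)),
        per_image_iou=per_image,
        confusion=cm,
        sensitivity=sensitivity(cm),
        specificity=specificity(cm),
        youden=youden(cm),
        roc=roc_auc(auto, true_labels),
        regression=regression_agreement(auto, manual),
        threshold_mm=threshold_mm,
        n_failed=n_failed,
    )
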