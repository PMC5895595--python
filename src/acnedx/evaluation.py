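"""Binary-classifier and multiclass evaluation.

ROC curves, trapezoidal AUC, Youden's index J = max(TPR - FPR) with
its maximizing ("best") threshold, accuracy/sensitivity/specificity at
a threshold, one-vs-rest score batches for multiclass probabilities,
and raw/row-normalized confusion matrices.

Conventions: items scoring exactly the threshold are predicted
positive (>=); among thresholds tied on J the smallest is returned
(favoring sensitivity).  ROC is evaluated per binary class; multiclass
performance is read from the normalized confusion matrix, whose
diagonal is per-class recall.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc


@dataclass
class ScoredBatch:
    """Positive-class scores with binary ground truth."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be parallel 1-D arrays")
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValueError("scores must lie in [0, 1]")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")


@dataclass
class RocCurve:
    thresholds: np.ndarray   # descending; leading sentinel above max score
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class ThresholdReport:
    """The Table-4 row schema: AUC, Youden's J, best threshold, and
    ACC/SEN/SPE evaluated at that threshold."""

    auc: float
    youden_j: float
    best_threshold: float
    acc: float
    sen: float
    spe: float


@dataclass
class ConfusionMatrix:
    counts: np.ndarray                       # (k, k) int, rows = actual
    normalized: np.ndarray | None = None     # rows sum to 1 where defined
    zero_rows: np.ndarray | None = None      # classes with no actual items


def roc_curve(batch: ScoredBatch) -> RocCurve:
    """Empirical ROC over the distinct scores (descending), with a
    sentinel threshold above the maximum so the curve starts at (0,0)
    and ends at (1,1)."""
    if len(np.unique(batch.labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc(batch.labels, batch.scores,
                            drop_intermediate=False)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def youden_best(curve: RocCurve) -> tuple[float, float]:
    """Max of J(t) = TPR(t) - FPR(t) and its threshold; ties on J are
    broken toward the smallest threshold."""
    j = curve.tpr - curve.fpr
    jmax = j.max()
    # thresholds are descending, so the last maximizer is the smallest
    idx = np.flatnonzero(j == jmax)[-1]
    thr = curve.thresholds[idx]
    if np.isinf(thr):  # degenerate: predict nothing positive
        thr = 1.0
    return float(jmax), float(thr)


def threshold_metrics(batch: ScoredBatch,
                      threshold: float) -> tuple[float, float, float]:
    """(ACC, SEN, SPE) with the >= positive-prediction convention."""
    pred = batch.scores >= threshold
    pos = batch.labels == 1
    tp = int((pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(batch.labels)
    return acc, sen, spe


def threshold_report(batch: ScoredBatch) -> ThresholdReport:
    """Full per-class report at the Youden-optimal threshold."""
    curve = roc_curve(batch)
    j, thr = youden_best(curve)
    acc, sen, spe = threshold_metrics(batch, thr)
    return ThresholdReport(auc=auc(curve), youden_j=j, best_threshold=thr,
                           acc=acc, sen=sen, spe=spe)


def one_vs_rest_batches(probs: np.ndarray,
                        labels: np.ndarray) -> list[ScoredBatch]:
    """Batch i scores class i's probability column against (label == i)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.ndim != 2 or len(probs) != len(labels):
        raise ValueError("probs must be (n, k) aligned with labels")
    if np.abs(probs.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("probability rows must be normalized")
    return [ScoredBatch(probs[:, i], (labels == i).astype(int))
            for i in range(probs.shape[1])]


def confusion(pred_labels: np.ndarray, true_labels: np.ndarray,
              k: int) -> ConfusionMatrix:
    """Counts[actual][predicted]."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    for arr, what in ((pred, "predicted"), (true, "true")):
        if len(arr) and (arr.min() < 0 or arr.max() >= k):
            raise ValueError(f"{what} labels fall outside [0, {k})")
    counts = _sk_confusion(true, pred, labels=np.arange(k))
    return ConfusionMatrix(counts=counts)


def normalize_rows(cm: ConfusionMatrix) -> ConfusionMatrix:
    """Divide each actual-class row by its total; empty rows stay zero
    and are flagged in ``zero_rows``."""
    totals = cm.counts.sum(axis=1)
    zero = totals == 0
    norm = np.zeros_like(cm.counts, dtype=float)
    norm[~zero] = cm.counts[~zero] / totals[~zero, None]
    return ConfusionMatrix(counts=cm.counts, normalized=norm, zero_rows=zero)


# ---------------------------------------------------------------------------
# report writers

def reports_to_csv(rows: list[tuple[str, str, ThresholdReport]],
                   path: str | Path) -> None:
    """Table-4-style CSV: Model, Class, AUC, Y index, Best T, ACC, SEN, SPE."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["Model", "Class", "AUC", "Y index", "Best T",
                    "ACC", "SEN", "SPE"])
        for model, cls, r in rows:
            w.writerow([model, cls] + [f"{v:.3f}" for v in (
                r.auc, r.youden_j, r.best_threshold, r.acc, r.sen, r.spe)])


def confusion_to_csv(cm: ConfusionMatrix, class_names, path: str | Path,
                     normalized: bool = False) -> None:
    mat = cm.normalized if normalized else cm.counts
    if mat is None:
        raise ValueError("matrix not available; call normalize_rows first")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["actual\\predicted", *class_names])
        for name, row in zip(class_names, mat):
            w.writerow([name] + [f"{v:.3f}" if normalized else int(v)
                                 for v in row])


__all__ = [
    "ScoredBatch", "RocCurve", "ThresholdReport", "ConfusionMatrix",
    "roc_curve", "auc", "youden_best", "threshold_metrics",
    "threshold_report", "one_vs_rest_batches", "confusion",
    "normalize_rows", "reports_to_csv", "confusion_to_csv",
]
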