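"""Segmentation and phenotype-agreement metrics.

Semantic segmentation is scored per class with one-vs-rest confusion counts
(IoU, precision, recall, F1) plus global overall accuracy; phenotype
extraction is scored against reference measurements with R^2 and RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SegMetrics", "confusion_counts", "regression_metrics"]


@dataclass
class SegMetrics:
    """Per-class confusion counts and the derived measures."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    iou: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    miou: float
    oa: float

    def per_class_table(self) -> list[dict]:
        rows = []
        for q in range(len(self.tp)):
            rows.append(
                {
                    "class": q,
                    "tp": int(self.tp[q]),
                    "fp": int(self.fp[q]),
                    "tn": int(self.tn[q]),
                    "fn": int(self.fn[q]),
                    "iou": float(self.iou[q]),
                    "precision": float(self.precision[q]),
                    "recall": float(self.recall[q]),
                    "f1": float(self.f1[q]),
                }
            )
        return rows


def _safe_div(num: np.ndarray, den: np.ndarray, vacuous: float) -> np.ndarray:
    out = np.full(num.shape, vacuous, dtype=np.float64)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def confusion_counts(
    pred: np.ndarray, truth: np.ndarray, num_classes: int, vacuous_iou: float = 1.0
) -> SegMetrics:
    """One-vs-rest confusion counts per class and the derived measures.

    IoU = TP/(TP+FP+FN); precision = TP/(TP+FP); recall = TP/(TP+FN);
    F1 = 2PR/(P+R); OA = (sum of correct)/n computed once globally. A class
    absent from both prediction and truth is vacuous and scores
    ``vacuous_iou`` (default 1.0; pass ``np.nan`` to skip it in the mIoU
    mean).
    """
    pred = np.asarray(pred, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if pred.min(initial=0) < 0 or truth.min(initial=0) < 0:
        raise ValueError("labels must be non-negative")
    if max(pred.max(initial=0), truth.max(initial=0)) >= num_classes:
        raise ValueError("labels exceed num_classes")
    n = pred.size
    tp = np.empty(num_classes, dtype=np.int64)
    fp = np.empty(num_classes, dtype=np.int64)
    fn = np.empty(num_classes, dtype=np.int64)
    for q in range(num_classes):
        p = pred == q
        t = truth == q
        tp[q] = int(np.sum(p & t))
        fp[q] = int(np.sum(p & ~t))
        fn[q] = int(np.sum(~p & t))
    tn = n - tp - fp - fn
    iou = _safe_div(tp, tp + fp + fn, vacuous_iou)
    precision = _safe_div(tp, tp + fp, vacuous_iou)
    recall = _safe_div(tp, tp + fn, vacuous_iou)
    pr = precision * recall
    f1 = _safe_div(2 * pr, precision + recall, vacuous_iou)
    oa = float((pred == truth).sum() / n)
    miou = float(np.nanmean(iou))
    return SegMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn, iou=iou, precision=precision, recall=recall,
        f1=f1, miou=miou, oa=oa,
    )


def regression_metrics(estimates: np.ndarray, references: np.ndarray) -> tuple[float, float]:
    """(R^2, RMSE) of estimated phenotype values against reference measurements.

    R^2 = 1 - sum (C - C_ref)^2 / sum (C_ref - mean(C_ref))^2;
    RMSE = sqrt(mean (C - C_ref)^2).
    """
    est = np.asarray(estimates, dtype=np.float64)
    ref = np.asarray(references, dtype=np.float64)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("estimates and references must be equal-length vectors")
    if est.size < 2:
        raise ValueError("need at least two pairs")
    ss_tot = float(((ref - ref.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("reference values have zero variance; R^2 undefined")
    ss_res = float(((est - ref) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / est.size))
    return r2, rmse
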