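"""Pixelwise evaluation: precision, recall, F1 and IoU, per caries type.

All metrics are percentages in [0, 100]. Predictions are binarised at a
threshold (default 0.5) and confusion counts are pooled over the whole test
set per type (micro aggregation) before the ratios are formed; per-image
macro averaging is available via ``aggregate='macro'``. Degenerate
denominators return 0 (and an empty union returns IoU 100: two empty masks
agree perfectly).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ShapeError, ValidationError

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts",
           "precision_recall_f1", "f1_from_pr", "miou", "weighted_average",
           "evaluate_testset", "TYPE_NAMES"]

TYPE_NAMES = ("Type I", "Type II", "Type III")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _binarize(pred: np.ndarray, threshold: float) -> np.ndarray:
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    return np.asarray(pred) >= threshold


def confusion_counts(pred, gt, threshold: float = 0.5) -> ConfusionCounts:
    """Pixelwise TP/FP/FN/TN after binarising `pred` at >= threshold."""
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ShapeError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    pb = _binarize(pred, threshold)
    gb = gt.astype(bool)
    tp = int(np.count_nonzero(pb & gb))
    fp = int(np.count_nonzero(pb & ~gb))
    fn = int(np.count_nonzero(~pb & gb))
    tn = int(pb.size - tp - fp - fn)
    return ConfusionCounts(tp, fp, fn, tn)


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """(precision %, recall %, F1 %); zero denominators yield 0."""
    prec = 100.0 * c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    rec = 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    if (c.tp + c.fp == 0) or (c.tp + c.fn == 0):
        warnings.warn("degenerate confusion counts: metric defined as 0",
                      stacklevel=2)
    f1 = 2.0 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percent, 2 dp)."""
    if not (0 <= precision <= 100 and 0 <= recall <= 100):
        raise ValueError("precision/recall must be percentages in [0, 100]")
    if precision + recall == 0:
        return 0.0
    return round(2.0 * precision * recall / (precision + recall), 2)


def miou(pred, gt, threshold: float = 0.5) -> float:
    """100 * |pred ∩ gt| / |pred ∪ gt|; both-empty counts as 100."""
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ShapeError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    pb = _binarize(pred, threshold)
    gb = gt.astype(bool)
    union = int(np.count_nonzero(pb | gb))
    if union == 0:
        warnings.warn("empty union: IoU defined as 100", stacklevel=2)
        return 100.0
    return float(100.0 * np.count_nonzero(pb & gb) / union)


def weighted_average(values, weights) -> float:
    """Sum(w_k v_k) / Sum(w_k); weights are per-type lesion-label counts."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ShapeError("values and weights must align")
    if (weights < 0).any():
        raise ValidationError("weights must be non-negative")
    if weights.sum() == 0:
        raise ValidationError("weights must not all be zero")
    return float((values * weights).sum() / weights.sum())


@dataclass
class MetricsReport:
    """Per-type precision/recall/F1/mIoU (percent) plus the weighted F1."""

    per_type: dict[str, dict[str, float]]
    weights: dict[str, int]
    weighted_f1: float
    threshold: float = 0.5
    aggregate: str = "micro"
    evaluation_hw: tuple[int, int] | None = None
    extras: dict = field(default_factory=dict)

    def round(self, ndigits: int = 2) -> "MetricsReport":
        per = {t: {m: round(v, ndigits) for m, v in d.items()}
               for t, d in self.per_type.items()}
        return MetricsReport(per, dict(self.weights), round(self.weighted_f1, ndigits),
                             self.threshold, self.aggregate, self.evaluation_hw,
                             dict(self.extras))

    def to_json(self, path) -> None:
        d = {"per_type": self.per_type, "weights": self.weights,
             "weighted_f1": self.weighted_f1, "threshold": self.threshold,
             "aggregate": self.aggregate,
             "evaluation_hw": list(self.evaluation_hw) if self.evaluation_hw else None}
        d.update(self.extras)
        Path(path).write_text(json.dumps(d, indent=2))

    def to_csv(self, path, model_name: str = "DCDNet") -> None:
        """Table layout: one row per metric, one column per caries type."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["Model", "Metrics", *TYPE_NAMES, "Weighted Average F1"])
            for metric in ("precision", "recall", "f1", "miou"):
                row = [model_name if metric == "precision" else "", metric.capitalize()
                       if metric != "miou" else "mIoU"]
                row += [f"{self.per_type[t][metric]:.2f}" for t in TYPE_NAMES]
                row.append(f"{self.weighted_f1:.2f}" if metric == "f1" else "")
                writer.writerow(row)


def evaluate_testset(predict_fn, test_set, threshold: float = 0.5,
                     aggregate: str = "micro") -> MetricsReport:
    """Evaluate per-type segmentation quality over a test set.

    predict_fn: callable mapping an image batch (B,H,W) or (B,3,H,W) ->
        (B,3,H,W) probability maps (e.g. wrapping DCDNet.predict).
    test_set: sequence of (image, mask) pairs, mask (3,H,W) binary.
    Weights for the weighted F1 are the per-type ground-truth positive-pixel
    bearing lesion label counts when the dataset provides them (attribute
    `label_counts`), else per-type positive-pixel counts.
    """
    if aggregate not in ("micro", "macro"):
        raise ValueError("aggregate must be 'micro' or 'macro'")
    items = list(test_set)
    if not items:
        raise ValueError("empty test set")
    counts = [ConfusionCounts() for _ in range(3)]
    inter = np.zeros(3, dtype=np.int64)
    union = np.zeros(3, dtype=np.int64)
    macro = [[] for _ in range(3)]  # per-image (P,R,F1,IoU)
    eval_hw = None
    for image, mask in items:
        mask = np.asarray(mask)
        pred = np.asarray(predict_fn(image[None]))[0]
        if pred.shape != mask.shape:
            raise ShapeError(f"prediction {pred.shape} vs mask {mask.shape}")
        eval_hw = mask.shape[-2:]
        for k in range(3):
            c = confusion_counts(pred[k], mask[k], threshold)
            counts[k] = counts[k] + c
            inter[k] += c.tp
            union[k] += c.tp + c.fp + c.fn
            if aggregate == "macro":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p, r, f1 = precision_recall_f1(c)
                    macro[k].append((p, r, f1, miou(pred[k], mask[k], threshold)))
    per_type: dict[str, dict[str, float]] = {}
    weights: dict[str, int] = {}
    label_counts = getattr(test_set, "label_counts", None)
    for k, tname in enumerate(TYPE_NAMES):
        if aggregate == "micro":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p, r, f1 = precision_recall_f1(counts[k])
            iou = float(100.0 * inter[k] / union[k]) if union[k] else 100.0
        else:
            p, r, f1, iou = (float(np.mean([m[i] for m in macro[k]]))
                             for i in range(4))
        per_type[tname] = {"precision": float(p), "recall": float(r),
                           "f1": float(f1), "miou": iou}
        weights[tname] = int(label_counts[k]) if label_counts is not None \
            else counts[k].tp + counts[k].fn
    wvals = [per_type[t]["f1"] for t in TYPE_NAMES]
    wts = [weights[t] for t in TYPE_NAMES]
    wf1 = weighted_average(wvals, wts) if sum(wts) else 0.0
    return MetricsReport(per_type=per_type, weights=weights, weighted_f1=wf1,
                         threshold=threshold, aggregate=aggregate,
                         evaluation_hw=eval_hw)
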