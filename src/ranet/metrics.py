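"""Overlap and pixel-classification metrics with per-item and aggregate
reporting: DSC, IoU, accuracy, sensitivity, specificity.

Accuracy follows the textual definition (proportion of correctly
predicted pixels, (TP+TN)/N); the per-item DSC and IoU always satisfy
dsc = 2·iou/(1+iou). Empty-vs-empty mask pairs score 1 for DSC/IoU by
default (correctly predicting absence), configurable. Undefined ratios
(zero denominators) are reported as missing (NaN), never as 0.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

METRIC_NAMES = ("dsc", "iou", "accuracy", "sensitivity", "specificity")


def _check_binary_pair(pred, truth):
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    for name, m in (("pred", p), ("truth", t)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    return p.astype(bool), t.astype(bool)


def confusion_counts(pred, truth) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN); the four counts partition the pixel grid."""
    p, t = _check_binary_pair(pred, truth)
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    tn = int((~p & ~t).sum())
    return tp, fp, fn, tn


def dsc(pred, truth, *, empty_score: float = 1.0) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); ``empty_score`` when both empty."""
    p, t = _check_binary_pair(pred, truth)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return float(empty_score)
    return 2.0 * int((p & t).sum()) / denom


def iou(pred, truth, *, empty_score: float = 1.0) -> float:
    """Jaccard index |A∩B| / |A∪B|; ``empty_score`` when both empty."""
    p, t = _check_binary_pair(pred, truth)
    union = int((p | t).sum())
    if union == 0:
        return float(empty_score)
    return int((p & t).sum()) / union


def accuracy_sensitivity_specificity(counts) -> tuple[float, float, float]:
    """From (TP, FP, FN, TN); zero-denominator ratios come back as NaN."""
    tp, fp, fn, tn = counts
    n = tp + fp + fn + tn
    acc = (tp + tn) / n if n else math.nan
    sens = tp / (tp + fn) if tp + fn else math.nan
    spec = tn / (tn + fp) if tn + fp else math.nan
    return acc, sens, spec


@dataclass
class MetricsReport:
    per_item: dict[str, list[float]] = field(
        default_factory=lambda: {m: [] for m in METRIC_NAMES})

    @property
    def n_items(self) -> int:
        return len(self.per_item["dsc"])

    def add(self, pred, truth, *, empty_score: float = 1.0):
        counts = confusion_counts(pred, truth)
        acc, sens, spec = accuracy_sensitivity_specificity(counts)
        self.per_item["dsc"].append(dsc(pred, truth, empty_score=empty_score))
        self.per_item["iou"].append(iou(pred, truth, empty_score=empty_score))
        self.per_item["accuracy"].append(acc)
        self.per_item["sensitivity"].append(sens)
        self.per_item["specificity"].append(spec)

    def mean(self, name: str) -> float:
        return float(np.nanmean(self.per_item[name])) if self.n_items else math.nan

    def sd(self, name: str) -> float:
        return float(np.nanstd(self.per_item[name])) if self.n_items else math.nan

    def summary(self) -> dict[str, dict[str, float]]:
        return {m: {"mean": self.mean(m), "sd": self.sd(m)} for m in METRIC_NAMES}

    # -- reporting -----------------------------------------------------
    def to_csv(self, path):
        """One row per item plus a summary row, percentages to 2 decimals."""
        path = Path(path)
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["item"] + [f"{m}_pct" for m in METRIC_NAMES])
            for i in range(self.n_items):
                writer.writerow([i] + [
                    _fmt_pct(self.per_item[m][i]) for m in METRIC_NAMES])
            writer.writerow(["mean"] + [_fmt_pct(self.mean(m))
                                        for m in METRIC_NAMES])
        return path

    def to_json(self, path=None):
        payload = {"n_items": self.n_items, "summary_pct": {
            m: {"mean": _round_pct(self.mean(m)), "sd": _round_pct(self.sd(m))}
            for m in METRIC_NAMES}}
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload


def _fmt_pct(x: float) -> str:
    return "" if math.isnan(x) else f"{100.0 * x:.2f}"


def _round_pct(x: float):
    return None if math.isnan(x) else round(100.0 * x, 2)


def evaluate_masks(preds, truths, *, empty_score: float = 1.0) -> MetricsReport:
    """Score a sequence of predicted masks against references."""
    report = MetricsReport()
    for p, t in zip(preds, truths, strict=True):
        report.add(p, t, empty_score=empty_score)
    return report
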