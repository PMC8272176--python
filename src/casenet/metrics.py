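"""Segmentation evaluation: confusion counts, DSC/recall/precision,
pixel-comparison maps, and the statistics used to compare architectures.

Positive = foreground = 1. DSC = 2TP/(2TP+FP+FN) is computed per 2D slice.
When a slice is empty in both prediction and reference, DSC, recall and
precision are defined as 1.0 (correct prediction of absence); this is
configurable at aggregation time by excluding empty slices instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "confusion",
    "dsc",
    "recall",
    "precision",
    "evaluate_slices",
    "MetricsReport",
    "summarize_scores",
    "comparison_map",
    "compare_architectures",
    "observer_mse",
    "COMPARISON_PALETTE",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-slice pixel tallies."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_binary(arr, name):
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary 0/1, found values {vals[:5]}")
    return arr.astype(bool)


def confusion(pred_mask, true_mask) -> ConfusionCounts:
    p = _check_binary(pred_mask, "pred_mask")
    t = _check_binary(true_mask, "true_mask")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs true {t.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient, 2TP/(2TP+FP+FN); empty-vs-empty -> 1.0."""
    denom = 2 * c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else 2 * c.tp / denom


def recall(c: ConfusionCounts) -> float:
    """True-positive rate TP/(TP+FN); empty reference -> 1.0."""
    denom = c.tp + c.fn
    return 1.0 if denom == 0 else c.tp / denom


def precision(c: ConfusionCounts) -> float:
    """Positive predictive value TP/(TP+FP); empty prediction -> 1.0."""
    denom = c.tp + c.fp
    return 1.0 if denom == 0 else c.tp / denom


def evaluate_slices(pred_masks, true_masks, ids=None) -> pd.DataFrame:
    """Per-slice DSC/recall/precision table for paired mask sequences."""
    rows = []
    for i, (p, t) in enumerate(zip(pred_masks, true_masks)):
        c = confusion(p, t)
        row = {"dsc": dsc(c), "recall": recall(c), "precision": precision(c)}
        if ids is not None:
            row["patient_id"], row["slice_index"] = ids[i]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class MetricsReport:
    """Aggregate of per-slice scores: mean +/- std and boxplot quartiles."""

    mean: float
    std: float
    quartiles: tuple[float, float, float, float, float]  # Q0..Q4
    n: int


def summarize_scores(scores, exclude_empty: bool = False) -> MetricsReport:
    s = np.asarray(scores, dtype=float)
    if exclude_empty:
        s = s[~np.isnan(s)]
    if s.size == 0:
        raise ValueError("no scores to aggregate")
    q = np.percentile(s, [0, 25, 50, 75, 100])
    return MetricsReport(float(s.mean()), float(s.std(ddof=1)) if s.size > 1 else 0.0,
                         tuple(float(v) for v in q), int(s.size))


#: RGB palette of the pixel-to-pixel comparison map.
COMPARISON_PALETTE = {
    "tp": (255, 255, 255),  # white
    "tn": (128, 128, 128),  # grey
    "fp": (0, 0, 255),      # blue
    "fn": (255, 0, 0),      # red
}


def comparison_map(pred_mask, true_mask) -> np.ndarray:
    """Color-coded agreement image: TP white, TN grey, FP blue, FN red."""
    p = _check_binary(pred_mask, "pred_mask")
    t = _check_binary(true_mask, "true_mask")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs true {t.shape}")
    out = np.empty(p.shape + (3,), dtype=np.uint8)
    out[p & t] = COMPARISON_PALETTE["tp"]
    out[~p & ~t] = COMPARISON_PALETTE["tn"]
    out[p & ~t] = COMPARISON_PALETTE["fp"]
    out[~p & t] = COMPARISON_PALETTE["fn"]
    return out


def compare_architectures(scores_a, scores_b):
    """Two-sided Welch (unequal-variance) independent-samples t-test.

    Returns ``(t, p, ci_low, ci_high)`` where the CI is the 95% confidence
    interval on the mean difference (a - b). Degenerate zero-variance groups
    are handled explicitly: identical means give t=0, p=1; separated means
    give an infinite statistic and p=0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 scores per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        if diff == 0:
            return 0.0, 1.0, 0.0, 0.0
        t = np.inf if diff > 0 else -np.inf
        return float(t), 0.0, float(diff), float(diff)
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(0.95)
    return float(res.statistic), float(res.pvalue), float(ci.low), float(ci.high)


def observer_mse(seg_a, seg_b) -> float:
    """Mean squared per-pixel difference between two label volumes."""
    a = np.asarray(seg_a, dtype=float)
    b = np.asarray(seg_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))
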