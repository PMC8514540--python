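"""Object-detection and pixel-classification quality scoring.

Predicted label maps are matched one-to-one to ground truth by greedy
descending-IoU assignment at a configurable IoU floor (default 0.5,
the standard detection convention).  From the matching come object
precision, recall and F1; the Matthews correlation coefficient is
computed at pixel level, where the true-negative count is well defined.
Undefined metrics are reported as NaN, never silently as zero — except
the conventional MCC = 0 when a denominator factor vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .core import NucleusLabelMap


@dataclass
class DetectionMatchResult:
    pairs: List[Tuple[int, int, float]]  # (gt_label, pred_label, IoU)
    n_tp: int
    n_fp: int
    n_fn: int
    iou_threshold: float


@dataclass
class QualityMetrics:
    precision: float
    recall: float
    f1: float
    mcc: float = float("nan")


def _label_array(m) -> np.ndarray:
    return np.asarray(getattr(m, "labels", m))


def match_objects(gt: NucleusLabelMap, pred: NucleusLabelMap,
                  iou_threshold: float = 0.5) -> DetectionMatchResult:
    """Greedy one-to-one matching of predicted to true objects by IoU.

    Candidate pairs with IoU >= ``iou_threshold`` are assigned in
    descending IoU order; ties break on (gt_label, pred_label) so the
    result is deterministic.
    """
    g = _label_array(gt)
    p = _label_array(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: gt {g.shape} vs pred {p.shape}")
    n_gt = int(g.max(initial=0))
    n_pred = int(p.max(initial=0))

    # joint histogram of overlapping (gt, pred) label pairs
    both = (g > 0) & (p > 0)
    if both.any():
        pair_idx = g[both].astype(np.int64) * (n_pred + 1) + p[both].astype(np.int64)
        counts = np.bincount(pair_idx, minlength=(n_gt + 1) * (n_pred + 1))
        inter = counts.reshape(n_gt + 1, n_pred + 1)
    else:
        inter = np.zeros((n_gt + 1, n_pred + 1), dtype=np.int64)
    gt_areas = np.bincount(g.ravel(), minlength=n_gt + 1)
    pred_areas = np.bincount(p.ravel(), minlength=n_pred + 1)

    candidates = []
    gi, pi = np.nonzero(inter[1:, 1:])
    for i, j in zip(gi + 1, pi + 1):
        union = gt_areas[i] + pred_areas[j] - inter[i, j]
        iou = inter[i, j] / union
        if iou >= iou_threshold:
            candidates.append((-iou, int(i), int(j)))
    candidates.sort()

    used_gt, used_pred = set(), set()
    pairs: List[Tuple[int, int, float]] = []
    for neg_iou, i, j in candidates:
        if i in used_gt or j in used_pred:
            continue
        used_gt.add(i)
        used_pred.add(j)
        pairs.append((i, j, -neg_iou))

    n_tp = len(pairs)
    return DetectionMatchResult(
        pairs=pairs, n_tp=n_tp, n_fp=n_pred - n_tp, n_fn=n_gt - n_tp,
        iou_threshold=iou_threshold,
    )


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if np.isnan(precision) or np.isnan(recall):
        return float("nan")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def object_metrics(match: DetectionMatchResult) -> QualityMetrics:
    """Precision, recall and F1 from matched-object counts.

    With zero objects on both sides all three are undefined (NaN).
    """
    tp, fp, fn = match.n_tp, match.n_fp, match.n_fn
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return QualityMetrics(precision=precision, recall=recall,
                          f1=f1_from_precision_recall(precision, recall))


def pixel_mcc(gt_mask: np.ndarray, pred_mask: np.ndarray) -> float:
    """Matthews correlation coefficient over pixels, in [-1, 1].

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any zero
    factor gives MCC = 0 by convention.
    """
    g = np.asarray(gt_mask).astype(bool)
    p = np.asarray(pred_mask).astype(bool)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: gt {g.shape} vs pred {p.shape}")
    # Python ints: the four-factor product overflows int64 on full fields
    tp = int(np.count_nonzero(g & p))
    tn = int(np.count_nonzero(~g & ~p))
    fp = int(np.count_nonzero(~g & p))
    fn = int(np.count_nonzero(g & ~p))
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    import math

    return (tp * tn - fp * fn) / math.sqrt(denom_sq)
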