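"""Evaluation: precision/recall, AP and mAP50 for boxes and masks, paired
t-test on repeated runs, and model-complexity accounting.

Matching is greedy by descending score: each prediction takes the
highest-IoU unmatched ground-truth instance of its image and class, and a
match requires IoU >= the threshold. AP is the area under the
precision-recall curve with monotone (all-point) interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .softnms import box_iou

__all__ = ["MetricCounts", "EvalResult", "mask_iou", "precision_recall",
           "average_precision", "map50", "paired_t_test", "count_parameters",
           "match_predictions", "evaluate_detections"]


@dataclass
class MetricCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class EvalResult:
    precision_box: float
    recall_box: float
    map50_box: float
    precision_mask: float
    recall_mask: float
    map50_mask: float
    n_classes: int = 1


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """|A n B| / |A u B| of two aligned binary rasters."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a raster shape")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("IoU of two empty masks is undefined")
    return float(np.logical_and(a, b).sum() / union)


def precision_recall(counts: MetricCounts) -> tuple[float, float]:
    """TP/(TP+FP) and TP/(TP+FN); 0 by convention when the denominator is 0."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return p, r


def _pair_iou(pred, gt, mode: str) -> float:
    if mode == "box":
        return box_iou(pred["box"], gt["box"])
    return mask_iou(pred["mask"], gt["mask"])


def match_predictions(predictions, ground_truth, iou_thr: float = 0.5,
                      mode: str = "box"):
    """Greedy one-to-one matching; returns (scores desc, tp flags, n_gt).

    `predictions`: dicts with keys score, image_id and box (x1,y1,x2,y2)
    and/or mask; `ground_truth`: dicts with image_id and box/mask.
    """
    order = sorted(range(len(predictions)),
                   key=lambda i: -predictions[i]["score"])
    gt_by_img: dict = {}
    for j, g in enumerate(ground_truth):
        gt_by_img.setdefault(g.get("image_id", 0), []).append(j)
    taken = set()
    scores, flags = [], []
    for i in order:
        p = predictions[i]
        best_iou, best_j = 0.0, -1
        for j in gt_by_img.get(p.get("image_id", 0), []):
            if j in taken:
                continue
            iou = _pair_iou(p, ground_truth[j], mode)
            if iou > best_iou:
                best_iou, best_j = iou, j
        ok = best_iou >= iou_thr and best_j >= 0
        if ok:
            taken.add(best_j)
        scores.append(p["score"])
        flags.append(ok)
    return np.asarray(scores), np.asarray(flags, bool), len(ground_truth)


def ap_from_matches(scores: np.ndarray, is_tp: np.ndarray, n_gt: int) -> float:
    """Area under the PR curve, monotone all-point interpolation."""
    if n_gt == 0:
        raise ValueError("AP undefined without ground truth")
    if len(scores) == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(is_tp[order])
    fp = np.cumsum(~is_tp[order])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # precision envelope (monotone non-increasing from the right)
    prec = np.maximum.accumulate(precision[::-1])[::-1]
    r = np.concatenate([[0.0], recall])
    return float(np.sum((r[1:] - r[:-1]) * prec))


def average_precision(predictions, ground_truth, iou_thr: float = 0.5,
                      mode: str = "box") -> float:
    scores, flags, n_gt = match_predictions(predictions, ground_truth,
                                            iou_thr, mode)
    return ap_from_matches(scores, flags, n_gt)


def map50(per_class_ap) -> float:
    """Arithmetic mean of per-class AP values."""
    aps = list(per_class_ap.values()) if isinstance(per_class_ap, dict) \
        else list(per_class_ap)
    if not aps:
        raise ValueError("need at least one class with a defined AP")
    return float(np.mean(aps))


def paired_t_test(x, y) -> tuple[float, float]:
    """Two-sided paired t-test on differences x - y (n-1 dof).

    Degenerate case: zero variance of the differences gives t = +/-inf
    (p = 0) for a nonzero mean difference, and t = 0, p = 1 otherwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = x - y
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return 0.0, 1.0
        return float(np.sign(d[0]) * np.inf), 0.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def count_parameters(model) -> int:
    """Total trainable scalar parameters of a built network."""
    return int(model.num_parameters())


def estimate_flops(model, input_size: int = 640) -> float:
    """Informational forward-pass cost in GFLOPs (2x multiply-accumulates of
    the convolution ops at the given square input). Convention-dependent;
    pooling, normalization and activations are not counted."""
    from . import nn
    from .nn.functional import mac_counter
    model.eval()
    x = nn.Tensor(np.zeros((1, 3, input_size, input_size), np.float32))
    with nn.no_grad(), mac_counter() as counter:
        model(x)
    return 2.0 * counter.macs / 1e9


def evaluate_detections(predictions, ground_truth, iou_thr: float = 0.5) -> EvalResult:
    """Single-class dataset-level evaluation over both boxes and masks."""
    out = {}
    for mode in ("box", "mask"):
        scores, flags, n_gt = match_predictions(predictions, ground_truth,
                                                iou_thr, mode)
        ap = ap_from_matches(scores, flags, n_gt) if n_gt else 0.0
        tp = int(flags.sum())
        counts = MetricCounts(tp=tp, fp=len(flags) - tp, fn=n_gt - tp)
        p, r = precision_recall(counts)
        out[mode] = (p, r, ap)
    return EvalResult(precision_box=out["box"][0], recall_box=out["box"][1],
                      map50_box=out["box"][2], precision_mask=out["mask"][0],
                      recall_mask=out["mask"][1], map50_mask=out["mask"][2])
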