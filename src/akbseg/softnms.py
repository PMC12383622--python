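"""Non-maximum suppression with Gaussian score decay (Soft-NMS).

Dense cell cultures produce heavily overlapping true detections; classical
NMS deletes neighbors outright and causes missed cells. Soft-NMS instead
decays the score of a neighbor b_i of the current maximum M:

    S_i <- S_i * exp(-IoU(M, b_i)^2 / sigma)   if IoU(M, b_i) >= Nt
    S_i unchanged                              otherwise

Detections whose final score falls below a floor are dropped. The classical
(hard) variant is recovered in the sigma -> 0 limit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["Detection", "NMSConfig", "box_iou", "soft_nms", "hard_nms"]


@dataclass
class Detection:
    box: np.ndarray                 # (x1, y1, x2, y2), half-open pixel coords
    score: float
    class_id: int = 0
    mask_coeffs: np.ndarray | None = None
    mask: np.ndarray | None = None  # instance raster, filled in downstream

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.box.shape != (4,):
            raise ValueError("box must have four coordinates")
        x1, y1, x2, y2 = self.box
        if not (x2 > x1 and y2 > y1):
            raise ValueError("degenerate box: require x2 > x1 and y2 > y1")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


@dataclass
class NMSConfig:
    nt: float = 0.5          # IoU threshold triggering decay
    sigma: float = 0.5       # Gaussian decay scale
    score_min: float = 0.001  # final-score floor
    method: str = "gaussian"  # {"gaussian", "hard"}

    def __post_init__(self):
        if not 0.0 <= self.nt <= 1.0:
            raise ValueError("Nt must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.score_min <= 1.0:
            raise ValueError("score_min must lie in [0, 1]")
        if self.method not in ("gaussian", "hard"):
            raise ValueError("method must be 'gaussian' or 'hard'")


def box_iou(a, b) -> float:
    """Intersection over union of two (x1, y1, x2, y2) boxes."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    for box in (a, b):
        if not (box[2] > box[0] and box[3] > box[1]):
            raise ValueError("degenerate box")
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    union = ((a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    return inter / union


def _ious_against(box: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    ix = np.clip(np.minimum(box[2], boxes[:, 2]) - np.maximum(box[0], boxes[:, 0]),
                 0.0, None)
    iy = np.clip(np.minimum(box[3], boxes[:, 3]) - np.maximum(box[1], boxes[:, 1]),
                 0.0, None)
    inter = ix * iy
    area = (box[2] - box[0]) * (box[3] - box[1])
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    return inter / (area + areas - inter)


def _argmax_with_ties(scores: np.ndarray, boxes: np.ndarray) -> int:
    """Highest score; ties broken by lexicographic box coordinates."""
    best = np.flatnonzero(scores == scores.max())
    if len(best) == 1:
        return int(best[0])
    order = np.lexsort((boxes[best, 3], boxes[best, 2],
                        boxes[best, 1], boxes[best, 0]))
    return int(best[order[0]])


def soft_nms(dets: list[Detection], cfg: NMSConfig | None = None) -> list[Detection]:
    """Gaussian-decay suppression of same-class detections.

    Returns kept detections with decayed scores, sorted descending. The
    caller partitions detections by class.
    """
    cfg = cfg or NMSConfig()
    if cfg.method == "hard":
        return hard_nms(dets, cfg.nt)
    if not dets:
        return []
    boxes = np.stack([d.box for d in dets])
    scores = np.array([d.score for d in dets], dtype=np.float64)
    idx = np.arange(len(dets))
    kept: list[tuple[int, float]] = []
    while len(idx):
        m = _argmax_with_ties(scores, boxes)
        kept.append((int(idx[m]), float(scores[m])))
        rest = np.ones(len(idx), bool)
        rest[m] = False
        ious = _ious_against(boxes[m], boxes[rest])
        s = scores[rest]
        decay = ious >= cfg.nt
        s[decay] *= np.exp(-(ious[decay] ** 2) / cfg.sigma)
        idx, boxes, scores = idx[rest], boxes[rest], s
    out = [replace(dets[i], score=s) for i, s in kept if s >= cfg.score_min]
    out.sort(key=lambda d: (-d.score, *d.box))
    return out


def hard_nms(dets: list[Detection], iou_thr: float = 0.5) -> list[Detection]:
    """Classical greedy suppression: drop boxes overlapping a kept box by
    more than `iou_thr`."""
    if not dets:
        return []
    boxes = np.stack([d.box for d in dets])
    scores = np.array([d.score for d in dets], dtype=np.float64)
    idx = np.arange(len(dets))
    kept = []
    while len(idx):
        m = _argmax_with_ties(scores, boxes)
        kept.append(int(idx[m]))
        rest = np.ones(len(idx), bool)
        rest[m] = False
        ious = _ious_against(boxes[m], boxes[rest])
        keep = ious < iou_thr
        idx, boxes, scores = idx[rest][keep], boxes[rest][keep], scores[rest][keep]
    out = [dets[i] for i in kept]
    out.sort(key=lambda d: (-d.score, *d.box))
    return out
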