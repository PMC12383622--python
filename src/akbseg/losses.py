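"""Training objective: classification, box-regression and segmentation terms.

The total objective is a weighted sum

    L = lambda_cls * L_cls + lambda_box * L_box + lambda_seg * L_seg

with L_cls the mean categorical cross-entropy over one-hot class targets,
L_box a coordinate squared-error over matched (cx, cy, w, h) box pairs
scaled by lambda_cor, and L_seg the mean binary cross-entropy over pixel
probabilities. All probabilities are clipped to (eps, 1-eps) before logs.

Every function accepts either numpy arrays (returns a float) or autodiff
Tensors (returns a scalar Tensor, so the trainer can backpropagate through
the same definitions the tests pin down).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["LossWeights", "classification_loss", "box_loss",
           "segmentation_loss", "total_loss", "PROB_EPS"]

PROB_EPS = 1e-7


@dataclass
class LossWeights:
    cls_weight: float = 1.0
    box_weight: float = 1.0
    seg_weight: float = 1.0
    lambda_cor: float = 1.0

    def __post_init__(self):
        if min(self.cls_weight, self.box_weight, self.seg_weight) < 0:
            raise ValueError("term weights must be >= 0")
        if self.lambda_cor <= 0:
            raise ValueError("lambda_cor must be positive")


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _ret(value, tensor_mode: bool):
    return value if tensor_mode else float(value.data)


def classification_loss(targets, probs):
    """-(1/N) sum_i sum_c y_ic log(p_ic) over one-hot targets (N, C)."""
    tensor_mode = _is_tensor(targets, probs)
    y = targets if isinstance(targets, Tensor) else Tensor(np.asarray(targets))
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs))
    if y.shape != p.shape:
        raise ValueError("targets and predictions must share shape (N, C)")
    n = y.shape[0]
    loss = -(y * p.clip(PROB_EPS, 1.0 - PROB_EPS).log()).sum() * (1.0 / n)
    return _ret(loss, tensor_mode)


def box_loss(target_boxes, pred_boxes, lambda_cor: float = 1.0,
             form: str = "sq_error"):
    """Box regression over matched (cx, cy, w, h) pairs.

    form="sq_error" (default): lambda_cor * sum_i of the four coordinate
    squared errors. form="ciou": lambda_cor * sum_i (1 - CIoU_i), the
    complete-IoU alternative (overlap + center distance + aspect terms).
    """
    tensor_mode = _is_tensor(target_boxes, pred_boxes)
    t = target_boxes if isinstance(target_boxes, Tensor) else Tensor(np.asarray(target_boxes))
    p = pred_boxes if isinstance(pred_boxes, Tensor) else Tensor(np.asarray(pred_boxes))
    if t.shape != p.shape:
        raise ValueError("matched box arrays must share shape (N, 4)")
    if form == "sq_error":
        loss = ((t - p) ** 2.0).sum() * lambda_cor
    elif form == "ciou":
        loss = _ciou_term(t, p).sum() * lambda_cor
    else:
        raise ValueError("box loss form must be 'sq_error' or 'ciou'")
    return _ret(loss, tensor_mode)


def _tmax(a, b):
    return a + (b - a).relu()


def _tmin(a, b):
    return a - (a - b).relu()


def _ciou_term(t: Tensor, p: Tensor) -> Tensor:
    """Per-pair 1 - CIoU for (cx, cy, w, h) boxes (alpha held constant)."""
    eps = 1e-9
    tx1, ty1 = t[:, 0] - t[:, 2] * 0.5, t[:, 1] - t[:, 3] * 0.5
    tx2, ty2 = t[:, 0] + t[:, 2] * 0.5, t[:, 1] + t[:, 3] * 0.5
    px1, py1 = p[:, 0] - p[:, 2] * 0.5, p[:, 1] - p[:, 3] * 0.5
    px2, py2 = p[:, 0] + p[:, 2] * 0.5, p[:, 1] + p[:, 3] * 0.5
    iw = (_tmin(tx2, px2) - _tmax(tx1, px1)).relu()
    ih = (_tmin(ty2, py2) - _tmax(ty1, py1)).relu()
    inter = iw * ih
    union = t[:, 2] * t[:, 3] + p[:, 2] * p[:, 3] - inter + eps
    iou = inter / union
    # squared center distance over squared enclosing-box diagonal
    cw = _tmax(tx2, px2) - _tmin(tx1, px1)
    ch = _tmax(ty2, py2) - _tmin(ty1, py1)
    c2 = cw ** 2.0 + ch ** 2.0 + eps
    rho2 = (t[:, 0] - p[:, 0]) ** 2.0 + (t[:, 1] - p[:, 1]) ** 2.0
    # aspect-consistency term with its usual constant trade-off factor
    v = (4.0 / np.pi ** 2) * \
        (((t[:, 2] / (t[:, 3] + eps)).atan()
          - (p[:, 2] / (p[:, 3] + eps)).atan()) ** 2.0)
    alpha = v.data / (1.0 - iou.data + v.data + eps)
    return 1.0 - iou + rho2 / c2 + v * alpha


def segmentation_loss(targets, probs):
    """Mean binary cross-entropy over pixels."""
    tensor_mode = _is_tensor(targets, probs)
    y = targets if isinstance(targets, Tensor) else Tensor(np.asarray(targets, dtype=np.float32))
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs))
    if y.shape != p.shape:
        raise ValueError("targets and predictions must share shape")
    pc = p.clip(PROB_EPS, 1.0 - PROB_EPS)
    n = int(np.prod(y.shape))
    loss = -((y * pc.log() + (1.0 - y) * (1.0 - pc).log()).sum()) * (1.0 / n)
    return _ret(loss, tensor_mode)


def total_loss(l_cls, l_box, l_seg, weights: LossWeights | None = None):
    """Weighted sum of the three terms (floats or scalar Tensors)."""
    w = weights or LossWeights()
    return w.cls_weight * l_cls + w.box_weight * l_box + w.seg_weight * l_seg
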