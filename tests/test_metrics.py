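"""Evaluation metrics: IoU, PR, AP against an exhaustive threshold-sweep
oracle, the paired t-test worked example, and parameter accounting."""

import numpy as np
import pytest

from akbseg import nn
from akbseg.metrics import (MetricCounts, ap_from_matches, average_precision,
                            count_parameters, map50, mask_iou, paired_t_test,
                            precision_recall, match_predictions)
from conftest import random_boxes
from akbseg.softnms import box_iou


def test_mask_iou_examples():
    a = np.zeros((4, 4), bool)
    a[:2, :2] = True
    assert mask_iou(a, a) == 1.0
    b = np.zeros((4, 4), bool)
    b[2:, 2:] = True
    assert mask_iou(a, b) == 0.0
    c = np.zeros((4, 4), bool)
    c[0:2, 1:3] = True  # shares 2 of 4 pixels with a
    assert mask_iou(a, c) == pytest.approx(2 / 6)
    with pytest.raises(ValueError):
        mask_iou(np.zeros((4, 4), bool), np.zeros((4, 4), bool))
    with pytest.raises(ValueError):
        mask_iou(a, np.zeros((3, 3), bool))


def test_precision_recall_examples():
    assert precision_recall(MetricCounts(9, 1, 0))[0] == pytest.approx(0.9)
    assert precision_recall(MetricCounts(9, 0, 3))[1] == pytest.approx(0.75)
    assert precision_recall(MetricCounts(0, 0, 5)) == (0.0, 0.0)
    with pytest.raises(ValueError):
        MetricCounts(-1, 0, 0)


def test_ap_simple_cases():
    gt = [{"image_id": 0, "box": np.array([0, 0, 10, 10.0])}]
    preds = [{"image_id": 0, "score": 0.9, "box": np.array([0, 0, 10, 10.0])}]
    assert average_precision(preds, gt) == pytest.approx(1.0)

    gt2 = gt + [{"image_id": 0, "box": np.array([50, 50, 60, 60.0])}]
    preds2 = [{"image_id": 0, "score": 0.9, "box": np.array([0, 0, 10, 10.0])},
              {"image_id": 0, "score": 0.8, "box": np.array([80, 80, 90, 90.0])}]
    # PR curve: (p=1, r=0.5) then (p=0.5, r=0.5) -> area 0.5
    assert average_precision(preds2, gt2) == pytest.approx(0.5)


def test_map50_examples():
    assert map50([0.7]) == pytest.approx(0.7)
    assert map50({1: 1.0, 2: 0.5}) == pytest.approx(0.75)
    assert map50([0.42] * 7) == pytest.approx(0.42)
    with pytest.raises(ValueError):
        map50([])


def ap_threshold_sweep_oracle(preds, gts, iou_thr=0.5):
    """Exhaustive oracle: evaluate (precision, recall) at every score
    cutoff with independent greedy matching, then integrate the envelope."""

    def pr_at(cutoff):
        sub = [p for p in preds if p["score"] >= cutoff]
        sub.sort(key=lambda p: -p["score"])
        taken = set()
        tp = 0
        for p in sub:
            best, bj = 0.0, None
            for j, g in enumerate(gts):
                if j in taken or g["image_id"] != p["image_id"]:
                    continue
                iou = box_iou(p["box"], g["box"])
                if iou > best:
                    best, bj = iou, j
            if bj is not None and best >= iou_thr:
                taken.add(bj)
                tp += 1
        fp = len(sub) - tp
        prec = tp / (tp + fp) if sub else 1.0
        return prec, tp / len(gts)

    points = sorted({p["score"] for p in preds}, reverse=True)
    prs = [pr_at(c) for c in points]
    recalls = [r for _, r in prs]
    ap, prev_r = 0.0, 0.0
    for r in sorted(set(recalls)):
        p_max = max(p for p, rr in prs if rr >= r)
        ap += (r - prev_r) * p_max
        prev_r = r
    return ap


def test_ap_matches_threshold_sweep_oracle_on_random_scenes(rng):
    mismatches = 0
    for scene in range(100):
        n_gt = int(rng.integers(1, 6))
        gts = [{"image_id": 0, "box": b}
               for b in random_boxes(rng, n_gt, span=60)]
        preds = []
        for g in gts:
            if rng.uniform() < 0.8:  # jittered true positives
                jitter = rng.normal(0, 2.0, 4)
                box = g["box"] + jitter
                if box[2] - box[0] > 1 and box[3] - box[1] > 1:
                    preds.append({"image_id": 0, "score": float(rng.uniform()),
                                  "box": box})
        for b in random_boxes(rng, int(rng.integers(0, 4)), span=60):
            preds.append({"image_id": 0, "score": float(rng.uniform()),
                          "box": b})
        if not preds:
            continue
        got = average_precision(preds, gts)
        want = ap_threshold_sweep_oracle(preds, gts)
        if abs(got - want) > 1e-9:
            mismatches += 1
    assert mismatches == 0


def test_map_extremes(rng):
    gts = [{"image_id": i, "box": b}
           for i, b in enumerate(random_boxes(rng, 10, span=50))]
    perfect = [{"image_id": g["image_id"], "score": 0.9, "box": g["box"]}
               for g in gts]
    assert average_precision(perfect, gts) == pytest.approx(1.0)
    assert average_precision([], gts) == 0.0
    scores, flags, n = match_predictions(perfect, gts)
    assert flags.all() and n == 10
    ap = ap_from_matches(scores, flags, n)
    assert 0.0 <= ap <= 1.0


def test_paired_t_worked_example():
    x = [0.950, 0.946, 0.944, 0.951]
    y = [0.917, 0.919, 0.913, 0.915]
    t, p = paired_t_test(x, y)
    assert round(t, 2) == 16.82
    assert p == pytest.approx(0.00046, abs=2e-5)


def test_paired_t_degenerate_cases():
    x = np.array([0.25, 0.5, 0.75])  # binary fractions: shifts stay exact
    t, p = paired_t_test(x, x)
    assert t == 0.0 and p == 1.0
    t, p = paired_t_test(x + 0.25, x)
    assert t == np.inf and p == 0.0
    t, p = paired_t_test(x - 0.25, x)
    assert t == -np.inf
    with pytest.raises(ValueError):
        paired_t_test([1.0], [2.0])


def test_count_parameters_single_conv():
    conv = nn.Conv2d(8, 16, kernel=3, bias=False)
    assert count_parameters(conv) == 8 * 9 * 16 == 1152
    conv_b = nn.Conv2d(8, 16, kernel=3, bias=True)
    assert count_parameters(conv_b) == 1152 + 16
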