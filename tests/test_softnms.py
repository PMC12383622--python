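"""Score-decay suppression: hand values, the hard-NMS limit, and
brute-force oracles on random instances."""

import numpy as np
import pytest

from akbseg.softnms import Detection, NMSConfig, box_iou, hard_nms, soft_nms
from conftest import random_boxes


def dets_from(boxes, scores):
    return [Detection(box=b, score=float(s)) for b, s in zip(boxes, scores)]


def test_box_iou_examples():
    assert box_iou([0, 0, 2, 2], [0, 0, 2, 2]) == 1.0
    assert box_iou([0, 0, 1, 1], [5, 5, 6, 6]) == 0.0
    assert box_iou([0, 0, 2, 2], [1, 1, 3, 3]) == pytest.approx(1 / 7)
    with pytest.raises(ValueError):
        box_iou([0, 0, 0, 1], [0, 0, 1, 1])
    with pytest.raises(ValueError):
        Detection(box=[1, 1, 1, 2], score=0.5)


def test_single_and_empty_inputs():
    assert soft_nms([]) == []
    d = Detection(box=[0, 0, 4, 4], score=0.7)
    out = soft_nms([d])
    assert len(out) == 1 and out[0].score == 0.7


def test_gaussian_decay_hand_value():
    cfg = NMSConfig(nt=0.3, sigma=0.5)
    out = soft_nms(dets_from([[0, 0, 4, 4], [0, 0, 4, 4]], [0.9, 0.8]), cfg)
    assert out[0].score == pytest.approx(0.9)
    assert out[1].score == pytest.approx(0.8 * np.exp(-2.0), rel=1e-9)


def test_below_threshold_scores_unchanged():
    # IoU = 1/7 < Nt = 0.5: the printed piecewise rule leaves S_i alone
    cfg = NMSConfig(nt=0.5, sigma=0.5)
    out = soft_nms(dets_from([[0, 0, 2, 2], [1, 1, 3, 3]], [0.9, 0.8]), cfg)
    assert sorted(d.score for d in out) == [0.8, 0.9]


def brute_force_soft_nms(boxes, scores, nt, sigma):
    """Direct transcription of the decay rule, O(n^2)."""
    boxes = [np.asarray(b, float) for b in boxes]
    scores = list(map(float, scores))
    alive = list(range(len(boxes)))
    kept = []
    while alive:
        m = max(alive, key=lambda i: scores[i])
        kept.append((m, scores[m]))
        alive.remove(m)
        for i in alive:
            iou = box_iou(boxes[m], boxes[i])
            if iou >= nt:
                scores[i] *= np.exp(-iou ** 2 / sigma)
    return kept


def test_matches_bruteforce_oracle_on_random_instances(rng):
    for trial in range(5):
        boxes = random_boxes(rng, 40, span=60, max_side=25)
        scores = rng.uniform(0.05, 1.0, 40)
        cfg = NMSConfig(nt=0.4, sigma=0.6, score_min=0.01)
        out = soft_nms(dets_from(boxes, scores), cfg)
        ref = [(i, s) for i, s in
               brute_force_soft_nms(boxes, scores, 0.4, 0.6) if s >= 0.01]
        ref.sort(key=lambda t: -t[1])
        assert len(out) == len(ref)
        for d, (i, s) in zip(out, ref):
            assert d.score == pytest.approx(s, rel=1e-9)
            np.testing.assert_allclose(d.box, boxes[i])


def test_hard_nms_bruteforce_and_coincident():
    out = hard_nms(dets_from([[0, 0, 4, 4], [0, 0, 4, 4]], [0.9, 0.8]), 0.5)
    assert len(out) == 1 and out[0].score == 0.9
    rng = np.random.default_rng(7)
    boxes = random_boxes(rng, 50, span=80, max_side=30)
    scores = rng.uniform(0.05, 1.0, 50)
    out = hard_nms(dets_from(boxes, scores), 0.5)
    # brute force: keep iff no higher-scoring kept box overlaps >= thr
    kept = []
    for i in np.argsort(-scores):
        if all(box_iou(boxes[i], boxes[j]) < 0.5 for j in kept):
            kept.append(i)
    assert sorted(d.score for d in out) == sorted(scores[i] for i in kept)


def test_sigma_to_zero_limit_equals_hard_nms(rng):
    for n in (20, 100):
        boxes = random_boxes(rng, n, span=70, max_side=28)
        scores = rng.uniform(0.1, 1.0, n)
        soft = soft_nms(dets_from(boxes, scores),
                        NMSConfig(nt=0.5, sigma=1e-9, score_min=1e-6))
        hard = hard_nms(dets_from(boxes, scores), 0.5)
        soft_set = {tuple(d.box.round(6)) for d in soft}
        hard_set = {tuple(d.box.round(6)) for d in hard}
        assert soft_set == hard_set


def test_scores_never_increase_and_permutation_invariance(rng):
    boxes = random_boxes(rng, 30, span=50, max_side=25)
    scores = rng.uniform(0.05, 1.0, 30)
    cfg = NMSConfig(nt=0.3, sigma=0.5, score_min=0.0)
    out = soft_nms(dets_from(boxes, scores), cfg)
    by_box = {tuple(d.box): d.score for d in out}
    for b, s in zip(boxes, scores):
        assert by_box[tuple(b)] <= s + 1e-12
    perm = rng.permutation(30)
    out2 = soft_nms(dets_from(boxes[perm], scores[perm]), cfg)
    assert [tuple(d.box) for d in out2] == [tuple(d.box) for d in out]
    assert [d.score for d in out2] == pytest.approx([d.score for d in out])
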