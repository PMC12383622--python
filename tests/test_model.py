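"""Model assembly and training contracts at desk scale (narrow width,
small inputs): variant parameter ordering, deterministic builds, decode
and prediction invariants, optimizer behavior, checkpoint round-trip."""

import numpy as np
import pytest

from akbseg import nn
from akbseg.metrics import count_parameters
from akbseg.model import (Model, ModelSpec, TrainConfig, build_model,
                          load_checkpoint, model_from_checkpoint, predict,
                          save_checkpoint, train, assign_targets,
                          compute_loss)
from akbseg.synthetic import SceneConfig, generate_scene

TINY = dict(input_size=64, width_multiple=0.125)


def small_scene(seed=7, size=64):
    return generate_scene(SceneConfig(image_size=size, cell_count=(4, 4),
                                      radius_range=(5, 10), adhesion_prob=0.0,
                                      contrast=0.35, noise_sigma=0.02,
                                      seed=seed))


def test_variant_parameter_ordering():
    base = count_parameters(build_model(ModelSpec(variant="baseline_s_seg",
                                                  **TINY)))
    softnms = count_parameters(build_model(ModelSpec(variant="plus_softnms",
                                                     **TINY)))
    bifpn = count_parameters(build_model(ModelSpec(variant="plus_bifpn_softnms",
                                                   **TINY)))
    akb = count_parameters(build_model(ModelSpec(variant="akb_full", **TINY)))
    assert softnms == base          # suppression is parameter-free
    assert bifpn > base             # weighted fusion + extra skip edge
    assert akb < base               # adaptive kernels slim the neck


def test_deterministic_build_same_seed():
    spec = ModelSpec(variant="akb_full", **TINY)
    a = build_model(spec, seed=3)
    b = build_model(spec, seed=3)
    for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert na == nb
        np.testing.assert_array_equal(pa.data, pb.data)
    c = build_model(spec, seed=4)
    checks = [np.array_equal(pa.data, pc.data)
              for (_, pa), (_, pc) in zip(a.named_parameters(),
                                          c.named_parameters())]
    assert not all(checks)


def test_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(variant="nope")
    with pytest.raises(ValueError):
        ModelSpec(variant="akb_full", akconv_placement="backbone")
    with pytest.raises(ValueError):
        ModelSpec(input_size=100)
    ModelSpec(variant="plus_softnms", akconv_placement="backbone")  # Table-4 style


def test_predict_contract_untrained(rng):
    model = build_model(ModelSpec(variant="akb_full", **TINY), seed=0)
    img = np.zeros((64, 64), np.float32)
    res = predict(model, img, conf_thr=0.5)
    assert len(res.detections) == len(res.masks)
    img2 = rng.uniform(0, 1, (50, 70)).astype(np.float32)  # non-square
    res2 = predict(model, img2, conf_thr=0.01)
    assert len(res2.detections) == len(res2.masks)
    for d, m in zip(res2.detections, res2.masks):
        x1, y1, x2, y2 = d.box
        assert 0 <= x1 < x2 <= 70 and 0 <= y1 < y2 <= 50
        assert m.shape == (50, 70)


def test_inference_deterministic():
    model = build_model(ModelSpec(variant="akb_full", **TINY), seed=0)
    scene = small_scene()
    r1 = predict(model, scene.image, conf_thr=0.01)
    r2 = predict(model, scene.image, conf_thr=0.01)
    assert len(r1.detections) == len(r2.detections)
    for a, b in zip(r1.detections, r2.detections):
        assert a.score == b.score
        np.testing.assert_array_equal(a.box, b.box)


def test_assignment_routes_by_size():
    boxes = np.array([[2.0, 2.0, 20.0, 20.0],      # small -> stride 8
                      [0.0, 0.0, 60.0, 60.0]])     # large -> stride 16/32
    masks = [np.ones((64, 64), bool), np.ones((64, 64), bool)]
    targets = assign_targets(boxes, masks, 64)
    assert targets[0]["cls"].sum() > 0
    assert sum(t["cls"].sum() for t in targets[1:]) > 0
    lv_small = [lv for lv, t in enumerate(targets)
                if any(t["inst"][t["cls"] > 0] == 0)]
    lv_large = [lv for lv, t in enumerate(targets)
                if any(t["inst"][t["cls"] > 0] == 1)]
    assert max(lv_small) < min(lv_large)


def test_zero_lr_leaves_parameters_unchanged():
    scene = small_scene()
    recs = [{"image": scene.image, "masks": scene.instances}]
    model = build_model(ModelSpec(variant="akb_full", **TINY), seed=0)
    before = {k: v.copy() for k, v in model.state_dict().items()
              if not k.startswith("buf:")}
    cfg = TrainConfig(image_size=64, batch_size=1, epochs=2, lr=0.0,
                      weight_decay=0.0, seed=0)
    train(model, recs, cfg)
    after = model.state_dict()
    for k, v in before.items():
        np.testing.assert_array_equal(v, after[k])


def test_short_training_reduces_loss():
    scene = small_scene()
    recs = [{"image": scene.image, "masks": scene.instances}]
    model = build_model(ModelSpec(variant="akb_full", **TINY), seed=0)
    cfg = TrainConfig(image_size=64, batch_size=1, epochs=50, lr=0.02,
                      seed=0, lambda_box=5.0)
    _, log = train(model, recs, cfg)
    assert log[-1]["total"] < log[0]["total"]


def test_overfit_single_scene_matches_most_instances():
    """A model overfit on one synthetic image recovers at least 90% of its
    ground-truth instances at IoU >= 0.5."""
    scene = generate_scene(SceneConfig(image_size=96, cell_count=(5, 5),
                                       radius_range=(7, 14), adhesion_prob=0.0,
                                       contrast=0.35, noise_sigma=0.02, seed=7))
    recs = [{"image": scene.image, "masks": scene.instances}]
    model = build_model(ModelSpec(variant="akb_full", input_size=96,
                                  width_multiple=0.125), seed=1)
    cfg = TrainConfig(image_size=96, batch_size=1, epochs=150, lr=0.02,
                      seed=0, lambda_box=7.5)
    train(model, recs, cfg)
    from akbseg.model import evaluate_model
    result = evaluate_model(model, recs)
    assert result.recall_box >= 0.9
    assert result.recall_mask >= 0.9


def test_flops_estimate_scales_with_resolution():
    from akbseg.metrics import estimate_flops
    model = build_model(ModelSpec(variant="akb_full", **TINY), seed=0)
    f64 = estimate_flops(model, 64)
    f128 = estimate_flops(model, 128)
    assert f64 > 0
    assert f128 / f64 == pytest.approx(4.0, rel=0.3)


def test_checkpoint_roundtrip_and_resume(tmp_path):
    scene = small_scene()
    recs = [{"image": scene.image, "masks": scene.instances}]
    spec = ModelSpec(variant="akb_full", **TINY)

    model = build_model(spec, seed=0)
    cfg_a = TrainConfig(image_size=64, batch_size=1, epochs=4, lr=0.01, seed=0)
    ckpt, _ = train(model, recs, cfg_a)
    save_checkpoint(ckpt, tmp_path / "ck.npz")
    loaded = load_checkpoint(tmp_path / "ck.npz")
    restored = model_from_checkpoint(loaded)
    for (ka, pa), (kb, pb) in zip(model.named_parameters(),
                                  restored.named_parameters()):
        np.testing.assert_array_equal(pa.data, pb.data)

    # an uninterrupted 5-epoch run and a 4+1 resumed run take the same
    # next optimization step (same data order, optimizer state, weights)
    model_full = build_model(spec, seed=0)
    cfg_b = TrainConfig(image_size=64, batch_size=1, epochs=5, lr=0.01, seed=0)
    _, log_full = train(model_full, recs, cfg_b)

    resumed = model_from_checkpoint(loaded)
    opt_state = loaded["optimizer"]
    from akbseg.model import _prepare_sample
    prepared = _prepare_sample(recs[0], 64)
    opt = nn.SGD(resumed.parameters(), lr=0.01, momentum=0.9,
                 weight_decay=0.0005)
    opt.load_state_dict(opt_state)
    rng = np.random.default_rng(0)
    rng.bit_generator.state = loaded["rng"]
    resumed.train()
    imgs = nn.Tensor(prepared[0][None])
    out = resumed(imgs)
    loss, parts = compute_loss(out, [prepared[1]], [prepared[2]], 64)
    assert parts["total"] == pytest.approx(log_full[-1]["total"], rel=2e-2)
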