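"""Scene generator: determinism, placement contracts, coverage accounting,
and label round-trips through both formats."""

import numpy as np
import pytest

from akbseg.analytics import confluence
from akbseg.metrics import mask_iou
from akbseg.synthetic import (SceneConfig, generate_scene, generate_scenes,
                              read_dataset, write_dataset)

SMALL = dict(image_size=64, cell_count=(3, 7), radius_range=(4, 12),
             noise_sigma=0.02)


def test_same_seed_bitwise_identical():
    cfg = SceneConfig(**SMALL, seed=42)
    a, b = generate_scene(cfg), generate_scene(cfg)
    np.testing.assert_array_equal(a.image, b.image)
    assert len(a.instances) == len(b.instances)
    for ma, mb in zip(a.instances, b.instances):
        np.testing.assert_array_equal(ma, mb)


def test_no_adhesion_means_disjoint_masks():
    cfg = SceneConfig(**SMALL, adhesion_prob=0.0, min_separation=2.0, seed=3)
    scene = generate_scene(cfg)
    n = len(scene.instances)
    assert n >= 2
    for i in range(n):
        for j in range(i + 1, n):
            inter = scene.instances[i] & scene.instances[j]
            assert inter.sum() == 0


def test_coverage_matches_confluence_within_one_percent():
    for seed in (0, 1, 2):
        scene = generate_scene(SceneConfig(**SMALL, seed=seed))
        conf = confluence(scene.instances, scene.image.shape)
        assert abs(conf - 100.0 * scene.coverage) <= 1.0


def test_mean_cell_count_near_configured_mean():
    cfg = SceneConfig(**SMALL, seed=100)
    scenes = generate_scenes(200, cfg)
    counts = [len(s.instances) for s in scenes]
    target = np.mean(np.arange(cfg.cell_count[0], cfg.cell_count[1] + 1))
    assert abs(np.mean(counts) - target) <= 0.1 * target


def test_boundary_blur_reduces_edge_gradient():
    from scipy import ndimage
    sharp_grads, blurred_grads = [], []
    for seed in range(20):
        base = dict(SMALL, noise_sigma=0.0, seed=seed)
        sharp = generate_scene(SceneConfig(**base, boundary_blur_sigma=0.5))
        soft = generate_scene(SceneConfig(**base, boundary_blur_sigma=3.0))
        for scene, acc in ((sharp, sharp_grads), (soft, blurred_grads)):
            gx = ndimage.sobel(scene.image.astype(float), 1)
            gy = ndimage.sobel(scene.image.astype(float), 0)
            mag = np.hypot(gx, gy)
            edges = np.zeros(scene.image.shape, bool)
            for m in scene.instances:
                edges |= m ^ ndimage.binary_erosion(m)
            acc.append(mag[edges].mean())
    assert np.mean(blurred_grads) < np.mean(sharp_grads)


def test_polygons_consistent_with_masks():
    from akbseg.io import polygon_to_mask
    scene = generate_scene(SceneConfig(**SMALL, seed=9))
    size = scene.image.shape[0]
    for poly, mask in zip(scene.polygons, scene.instances):
        raster = polygon_to_mask(poly * size, mask.shape)
        assert mask_iou(raster, mask) >= 0.95
        assert poly.min() >= 0.0 and poly.max() <= 1.0


@pytest.mark.parametrize("fmt", ["yolo_seg", "coco"])
def test_dataset_roundtrip(tmp_path, fmt):
    scenes = generate_scenes(2, SceneConfig(**SMALL, seed=5))
    out = tmp_path / fmt
    write_dataset(scenes, out, fmt)
    back = read_dataset(out, fmt)
    assert len(back) == len(scenes)
    for scene, rec in zip(scenes, back):
        assert len(rec["masks"]) == len(scene.instances)
        matched = 0
        for m in scene.instances:
            best = max(mask_iou(m, r) if (m.any() or r.any()) else 0.0
                       for r in rec["masks"])
            if best >= 0.95:
                matched += 1
        assert matched == len(scene.instances)


def test_yolo_label_format(tmp_path):
    scenes = generate_scenes(1, SceneConfig(**SMALL, seed=6))
    write_dataset(scenes, tmp_path, "yolo_seg")
    text = (tmp_path / "labels" / "scene_00000.txt").read_text()
    lines = [l for l in text.splitlines() if l]
    assert len(lines) == len(scenes[0].instances)
    for line in lines:
        vals = line.split()
        assert vals[0] == "0"
        coords = np.array([float(v) for v in vals[1:]])
        assert len(coords) % 2 == 0
        assert coords.min() >= 0.0 and coords.max() <= 1.0


def test_coco_schema_fields(tmp_path):
    import json
    scenes = generate_scenes(1, SceneConfig(**SMALL, seed=8))
    write_dataset(scenes, tmp_path, "coco")
    doc = json.loads((tmp_path / "annotations.json").read_text())
    assert set(doc) >= {"images", "annotations", "categories"}
    assert doc["images"][0].keys() >= {"id", "file_name", "height", "width"}
    ann = doc["annotations"][0]
    assert ann.keys() >= {"id", "image_id", "category_id", "segmentation",
                          "bbox", "area"}


def test_config_validation():
    with pytest.raises(ValueError):
        SceneConfig(cell_count=(5, 3))
    with pytest.raises(ValueError):
        SceneConfig(adhesion_prob=1.5)
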