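"""Seeded generator of bright-field-like cell scenes with ground truth.

Scenes emulate the four stress axes of dense stem-cell cultures: irregular
cell shapes (deformed ellipses with low-frequency radial perturbation),
dense adhesion (cells placed touching/overlapping a neighbor with a
configurable probability), multi-scale size spread (log-uniform radii,
defaults spanning roughly one order of magnitude), and unclear outlines
(boundary blur, low foreground contrast, illumination gradient, noise).
Ground-truth masks and polygons are recorded before blur and noise, so they
are unambiguous. Everything is determined by the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import (polygon_to_mask, write_image, read_image, write_yolo_labels,
                 read_yolo_labels, write_coco, read_coco)

__all__ = ["SceneConfig", "SyntheticScene", "generate_scene", "generate_scenes",
           "write_dataset", "read_dataset"]


@dataclass
class SceneConfig:
    image_size: int = 640
    cell_count: tuple[int, int] = (15, 45)        # inclusive range per scene
    radius_range: tuple[float, float] = (4.0, 40.0)   # px; multi-scale spread
    eccentricity_range: tuple[float, float] = (1.0, 2.2)
    adhesion_prob: float = 0.3     # chance a cell is placed touching another
    min_separation: float = 2.0    # px between non-adherent cells
    boundary_blur_sigma: float = 1.5
    contrast: float = 0.25         # foreground-background intensity offset
    background_level: float = 0.55
    background_gradient: float = 0.08
    noise_sigma: float = 0.03
    poisson_noise: bool = False
    irregularity: float = 0.12     # radial perturbation amplitude
    seed: int = 0

    def __post_init__(self):
        for rng_pair in (self.cell_count, self.radius_range,
                         self.eccentricity_range):
            if rng_pair[0] > rng_pair[1]:
                raise ValueError("ranges must be ordered (lo, hi)")
        if not 0.0 <= self.adhesion_prob <= 1.0:
            raise ValueError("adhesion_prob must lie in [0, 1]")
        if self.image_size < 16:
            raise ValueError("image_size too small")


@dataclass
class SyntheticScene:
    image: np.ndarray                 # float32 HxW in [0, 1]
    instances: list[np.ndarray]       # per-instance boolean masks
    polygons: list[np.ndarray]        # per-instance (n, 2) normalized (x, y)
    coverage: float                   # analytic union coverage fraction
    config: SceneConfig = field(repr=False, default=None)

    @property
    def boxes(self) -> np.ndarray:
        """Tight (x1, y1, x2, y2) pixel boxes around each instance mask."""
        out = []
        for m in self.instances:
            ys, xs = np.nonzero(m)
            out.append([xs.min(), ys.min(), xs.max() + 1, ys.max() + 1])
        return np.asarray(out, dtype=np.float64)


def _cell_polygon(rng: np.random.Generator, center, radius, ecc, angle,
                  irregularity, n_vertices: int = 48) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    # low-frequency radial perturbation: irregular but smooth outline
    r = np.ones_like(theta)
    for k in range(2, 6):
        amp = irregularity * rng.uniform(0.2, 1.0) / (k - 1)
        r += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    r = np.clip(r, 0.3, None) * radius
    ex = np.cos(theta) * r * ecc ** 0.5
    ey = np.sin(theta) * r / ecc ** 0.5
    ca, sa = np.cos(angle), np.sin(angle)
    x = center[0] + ex * ca - ey * sa
    y = center[1] + ex * sa + ey * ca
    return np.stack([x, y], axis=1)


def generate_scene(cfg: SceneConfig) -> SyntheticScene:
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size
    n_target = int(rng.integers(cfg.cell_count[0], cfg.cell_count[1] + 1))
    masks, polys, centers, radii = [], [], [], []
    occupancy = np.zeros((size, size), bool)
    attempts_per_cell = 40
    for _ in range(n_target):
        placed = False
        for _ in range(attempts_per_cell):
            lo, hi = np.log(cfg.radius_range[0]), np.log(cfg.radius_range[1])
            radius = float(np.exp(rng.uniform(lo, hi)))
            radius = min(radius, size / 4.0)
            ecc = rng.uniform(*cfg.eccentricity_range)
            angle = rng.uniform(0, np.pi)
            adhere = centers and rng.uniform() < cfg.adhesion_prob
            if adhere:
                j = int(rng.integers(len(centers)))
                d = (radii[j] + radius) * rng.uniform(0.75, 1.0)
                phi = rng.uniform(0, 2 * np.pi)
                cx = centers[j][0] + d * np.cos(phi)
                cy = centers[j][1] + d * np.sin(phi)
            else:
                cx = rng.uniform(radius, size - radius)
                cy = rng.uniform(radius, size - radius)
            if not (0 <= cx < size and 0 <= cy < size):
                continue
            poly = _cell_polygon(rng, (cx, cy), radius, ecc, angle,
                                 cfg.irregularity)
            mask = polygon_to_mask(poly, (size, size))
            if not mask.any():
                continue
            if not adhere:
                grown = ndimage.binary_dilation(
                    mask, iterations=max(int(cfg.min_separation), 1))
                if (grown & occupancy).any():
                    continue
            masks.append(mask)
            polys.append(poly)
            centers.append((cx, cy))
            radii.append(radius)
            occupancy |= mask
            placed = True
            break
        if not placed:
            warnings.warn("placement failed after bounded retries; "
                          "scene has fewer cells than requested")
    # render: background plane + gradient, darker cell interiors, blur, noise
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64) / size
    gdir = rng.uniform(0, 2 * np.pi)
    img = cfg.background_level + cfg.background_gradient * (
        (xx - 0.5) * np.cos(gdir) + (yy - 0.5) * np.sin(gdir)) * 2.0
    for mask in masks:
        depth = cfg.contrast * rng.uniform(0.75, 1.25)
        img[mask] -= depth
    if cfg.boundary_blur_sigma > 0:
        img = ndimage.gaussian_filter(img, cfg.boundary_blur_sigma)
    if cfg.poisson_noise:
        photons = 2000.0
        img = rng.poisson(np.clip(img, 0, None) * photons) / photons
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    union = np.zeros((size, size), bool)
    for m in masks:
        union |= m
    coverage = float(union.mean())
    polys_norm = [np.clip(p / size, 0.0, 1.0) for p in polys]
    return SyntheticScene(image=img, instances=masks, polygons=polys_norm,
                          coverage=coverage, config=cfg)


def generate_scenes(n: int, cfg: SceneConfig) -> list[SyntheticScene]:
    """Generate `n` scenes with per-scene seeds derived from cfg.seed."""
    root = np.random.SeedSequence(cfg.seed)
    out = []
    for child in root.spawn(n):
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        scene_cfg = SceneConfig(**{**cfg.__dict__, "seed": seed})
        out.append(generate_scene(scene_cfg))
    return out


def write_dataset(scenes: list[SyntheticScene], out_dir, fmt: str = "yolo_seg"):
    """Write scenes as PNG images plus YOLO-seg labels or one COCO JSON."""
    if not scenes:
        raise ValueError("no scenes to write")
    if fmt not in ("yolo_seg", "coco"):
        raise ValueError("format must be 'yolo_seg' or 'coco'")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    records = []
    for i, scene in enumerate(scenes):
        name = f"scene_{i:05d}.png"
        write_image(out_dir / "images" / name, scene.image)
        size = scene.image.shape[0]
        if fmt == "yolo_seg":
            write_yolo_labels(out_dir / "labels" / f"scene_{i:05d}.txt",
                              scene.polygons)
        else:
            records.append({"file_name": name, "height": size, "width": size,
                            "polygons": [p * size for p in scene.polygons]})
    if fmt == "coco":
        write_coco(out_dir / "annotations.json", records)
    return out_dir


def read_dataset(data_dir, fmt: str = "yolo_seg") -> list[dict]:
    """Load a written dataset back as dicts with image, masks, polygons."""
    data_dir = Path(data_dir)
    out = []
    if fmt == "yolo_seg":
        for img_path in sorted((data_dir / "images").glob("*.png")):
            img = read_image(img_path)
            h, w = img.shape[:2]
            label = data_dir / "labels" / (img_path.stem + ".txt")
            if not label.exists():
                raise FileNotFoundError(f"missing labels for {img_path.name}")
            _, polys = read_yolo_labels(label)
            abs_polys = [p * [w, h] for p in polys]
            masks = [polygon_to_mask(p, (h, w)) for p in abs_polys]
            out.append({"file_name": img_path.name, "image": img,
                        "polygons": abs_polys, "masks": masks})
    else:
        for rec in read_coco(data_dir / "annotations.json"):
            img = read_image(data_dir / "images" / rec["file_name"])
            masks = [polygon_to_mask(p, (rec["height"], rec["width"]))
                     for p in rec["polygons"]]
            out.append({"file_name": rec["file_name"], "image": img,
                        "polygons": rec["polygons"], "masks": masks})
    return out
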