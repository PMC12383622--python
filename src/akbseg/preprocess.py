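"""Image enhancement: contrast-limited adaptive histogram equalization
followed (or preceded) by Gaussian smoothing.

Bright-field microscopy frames show low contrast, uneven illumination and
sensor noise. CLAHE equalizes the histogram independently in non-overlapping
tiles, clipping each tile histogram at a contrast-limiting ceiling so noise
in flat regions is not over-amplified, and blends the per-tile mappings
bilinearly to avoid tile-border artifacts. The Gaussian stage suppresses the
remaining high-frequency noise with a normalized kernel
exp(-(dx^2+dy^2) / 2 sigma^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["PreprocessConfig", "clahe", "gaussian_blur", "preprocess",
           "clip_histogram", "default_blur_sigma"]

_N_BINS = 256


@dataclass
class PreprocessConfig:
    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)
    blur_kernel: int = 3
    blur_sigma: float | None = None   # None: derived from the kernel size
    order: str = "clahe_then_blur"    # or "blur_then_clahe"

    def __post_init__(self):
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive")
        if len(self.tile_grid) != 2 or min(self.tile_grid) < 1:
            raise ValueError("tile_grid entries must be >= 1")
        if self.blur_kernel < 1 or self.blur_kernel % 2 == 0:
            raise ValueError("blur_kernel must be an odd positive integer")
        if self.blur_sigma is not None and self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be positive")
        if self.order not in ("clahe_then_blur", "blur_then_clahe"):
            raise ValueError("unknown preprocessing order")


def default_blur_sigma(kernel: int) -> float:
    """Sigma matched to the kernel extent: 0.3*((k-1)/2 - 1) + 0.8."""
    return 0.3 * ((kernel - 1) * 0.5 - 1.0) + 0.8


def _to_uint8(img: np.ndarray) -> tuple[np.ndarray, bool]:
    if img.dtype == np.uint8:
        return img, False
    if np.issubdtype(img.dtype, np.floating):
        return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8), True
    raise ValueError("expected uint8 or float image in [0, 1]")


def _from_uint8(img: np.ndarray, was_float: bool, dtype) -> np.ndarray:
    if was_float:
        return (img.astype(np.float32) / 255.0).astype(dtype)
    return img


def clip_histogram(hist: np.ndarray, clip_limit_abs: float) -> np.ndarray:
    """Clip histogram bins at the ceiling and redistribute the excess
    uniformly over all bins."""
    hist = hist.astype(np.float64)
    clipped = np.minimum(hist, clip_limit_abs)
    excess = hist.sum() - clipped.sum()
    return clipped + excess / len(hist)


def _tile_lut(tile: np.ndarray, clip_limit: float) -> np.ndarray:
    area = tile.size
    hist = np.bincount(tile.ravel(), minlength=_N_BINS).astype(np.float64)
    ceiling = max(clip_limit * area / _N_BINS, 1.0)
    hist = clip_histogram(hist, ceiling)
    cdf = np.cumsum(hist)
    return np.clip(np.rint(cdf * (_N_BINS - 1) / area), 0, 255).astype(np.uint8)


def _clahe_gray(img: np.ndarray, clip_limit: float,
                tile_grid: tuple[int, int]) -> np.ndarray:
    h, w = img.shape
    rows, cols = tile_grid
    th = int(np.ceil(h / rows))
    tw = int(np.ceil(w / cols))
    pad_h, pad_w = rows * th - h, cols * tw - w
    work = np.pad(img, ((0, pad_h), (0, pad_w)), mode="reflect") \
        if (pad_h or pad_w) else img
    luts = np.empty((rows, cols, _N_BINS), np.uint8)
    for r in range(rows):
        for c in range(cols):
            tile = work[r * th:(r + 1) * th, c * tw:(c + 1) * tw]
            luts[r, c] = _tile_lut(tile, clip_limit)
    # bilinear blend of the four surrounding tile mappings, clamped at borders
    yy, xx = np.mgrid[0:rows * th, 0:cols * tw]
    fy = (yy + 0.5) / th - 0.5
    fx = (xx + 0.5) / tw - 0.5
    r0 = np.clip(np.floor(fy).astype(int), 0, rows - 1)
    c0 = np.clip(np.floor(fx).astype(int), 0, cols - 1)
    r1 = np.minimum(r0 + 1, rows - 1)
    c1 = np.minimum(c0 + 1, cols - 1)
    wy = np.clip(fy - r0, 0.0, 1.0)
    wx = np.clip(fx - c0, 0.0, 1.0)
    v = work.astype(int)
    out = ((1 - wy) * (1 - wx) * luts[r0, c0, v]
           + (1 - wy) * wx * luts[r0, c1, v]
           + wy * (1 - wx) * luts[r1, c0, v]
           + wy * wx * luts[r1, c1, v])
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)[:h, :w]


def clahe(img: np.ndarray, clip_limit: float = 2.0,
          tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    `clip_limit` is the ceiling on each tile histogram expressed as a
    multiple of the uniform bin height (tile_area / 256). RGB images are
    equalized on a luminance channel and recombined.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    rows, cols = tile_grid
    if rows < 1 or cols < 1:
        raise ValueError("tile_grid entries must be >= 1")
    if img.ndim not in (2, 3):
        raise ValueError("expected HxW or HxWxC image")
    if img.shape[0] < rows or img.shape[1] < cols:
        raise ValueError("image smaller than one tile per grid cell")
    u8, was_float = _to_uint8(img)
    if u8.ndim == 2:
        out = _clahe_gray(u8, clip_limit, tile_grid)
    else:
        ycbcr = _rgb_to_ycbcr(u8)
        ycbcr[..., 0] = _clahe_gray(ycbcr[..., 0], clip_limit, tile_grid)
        out = _ycbcr_to_rgb(ycbcr)
    return _from_uint8(out, was_float, img.dtype)


def _rgb_to_ycbcr(rgb: np.ndarray) -> np.ndarray:
    m = np.array([[0.299, 0.587, 0.114],
                  [-0.168736, -0.331264, 0.5],
                  [0.5, -0.418688, -0.081312]])
    y = rgb.astype(np.float64) @ m.T + [0, 128, 128]
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


def _ycbcr_to_rgb(ycbcr: np.ndarray) -> np.ndarray:
    m = np.array([[1.0, 0.0, 1.402],
                  [1.0, -0.344136, -0.714136],
                  [1.0, 1.772, 0.0]])
    x = ycbcr.astype(np.float64) - [0, 128, 128]
    return np.clip(np.rint(x @ m.T), 0, 255).astype(np.uint8)


def gaussian_blur(img: np.ndarray, kernel: int = 3,
                  sigma: float | None = None) -> np.ndarray:
    """Convolution with a normalized 2-D Gaussian kernel of finite support
    `kernel` x `kernel`; borders handled by reflection."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd positive integer")
    sigma = default_blur_sigma(kernel) if sigma is None else sigma
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    radius = (kernel - 1) // 2

    def blur1(channel):
        return ndimage.gaussian_filter(channel.astype(np.float64), sigma,
                                       mode="mirror", radius=radius)

    if img.ndim == 2:
        out = blur1(img)
    elif img.ndim == 3:
        out = np.stack([blur1(img[..., c]) for c in range(img.shape[2])], axis=-1)
    else:
        raise ValueError("expected HxW or HxWxC image")
    if img.dtype == np.uint8:
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out.astype(img.dtype)


def preprocess(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Apply the two enhancement stages in the configured order."""
    cfg = cfg or PreprocessConfig()

    def do_clahe(x):
        return clahe(x, cfg.clip_limit, cfg.tile_grid)

    def do_blur(x):
        return gaussian_blur(x, cfg.blur_kernel, cfg.blur_sigma)

    if cfg.order == "clahe_then_blur":
        return do_blur(do_clahe(img))
    return do_clahe(do_blur(img))
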