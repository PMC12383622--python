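"""Confluence and cell-count analytics from segmentation output.

Confluence is the percentage of the image area covered by the union of
instance masks (pixels belonging to several adhering cells count once);
cell count is the number of instances kept after suppression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SegmentationResult

__all__ = ["ConfluenceReport", "confluence", "cell_count", "analyze_result"]


@dataclass
class ConfluenceReport:
    confluence: float         # percent in [0, 100]
    cell_count: int
    covered_pixels: int
    total_pixels: int
    image_id: str | int = 0

    def __post_init__(self):
        if not 0.0 <= self.confluence <= 100.0:
            raise ValueError("confluence must lie in [0, 100]")
        if self.cell_count < 0:
            raise ValueError("cell_count must be non-negative")


def confluence(masks: list[np.ndarray], image_shape: tuple[int, int]) -> float:
    """100 * |union of masks| / (H * W)."""
    h, w = image_shape
    if h < 1 or w < 1:
        raise ValueError("zero-area image")
    union = np.zeros(image_shape, bool)
    for m in masks:
        m = np.asarray(m, bool)
        if m.shape != tuple(image_shape):
            raise ValueError("mask not aligned to image shape")
        union |= m
    return 100.0 * float(union.sum()) / (h * w)


def cell_count(result: SegmentationResult, min_area: int = 0) -> int:
    """Number of kept instances; optionally ignore tiny ones."""
    if min_area <= 0:
        return len(result.masks)
    return int(sum(np.asarray(m, bool).sum() >= min_area for m in result.masks))


def analyze_result(result: SegmentationResult,
                   image_shape: tuple[int, int],
                   min_area: int = 0) -> ConfluenceReport:
    conf = confluence(result.masks, image_shape)
    union = np.zeros(image_shape, bool)
    for m in result.masks:
        union |= np.asarray(m, bool)
    return ConfluenceReport(confluence=conf,
                            cell_count=cell_count(result, min_area),
                            covered_pixels=int(union.sum()),
                            total_pixels=int(np.prod(image_shape)),
                            image_id=result.image_id)
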