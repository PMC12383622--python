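"""Adaptive-kernel convolution (AKConv).

A convolution whose kernel has an arbitrary number N of sampling points laid
out by grid expansion from a top-left (0,0) origin. A small internal
convolution predicts a per-position offset field of shape (B, 2N, H, W); the
feature map is resampled bilinearly at base + initial + learned-offset
positions (out-of-bounds clamped to the border), and the N sampled maps are
aggregated by a convolution that collapses the sampling axis, followed by
batch normalization and SiLU. Parameter count is affine in N, unlike the
quadratic growth of a k x k square kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F

__all__ = ["AKConvConfig", "initial_coordinates", "AKConv", "akconv_param_count"]


@dataclass
class AKConvConfig:
    in_channels: int
    out_channels: int
    num_param: int = 3
    stride: int = 1
    bias: bool = False

    def __post_init__(self):
        if self.num_param < 1:
            raise ValueError("num_param must be >= 1")
        if self.stride < 1 or self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("stride and channel counts must be positive")


def initial_coordinates(n: int) -> list[tuple[int, int]]:
    """Grid-expansion layout of the N initial sampling points.

    k = round(sqrt(N)) (minimum 1); floor(N/k) full rows of width k are filled
    row-major starting at the origin (0,0), followed by a partial row holding
    the remaining N mod k points.
    """
    if n < 1:
        raise ValueError("number of sampling points must be >= 1")
    k = max(1, int(round(np.sqrt(n))))
    coords = []
    full_rows = n // k
    for r in range(full_rows):
        for c in range(k):
            coords.append((r, c))
    for c in range(n % k):
        coords.append((full_rows, c))
    return coords


def akconv_param_count(c_in: int, c_out: int, n: int, offset_kernel: int = 3) -> int:
    """Closed-form trainable-parameter count of one AKConv layer (bias-free).

    offset predictor: c_in * offset_kernel^2 * 2N, aggregation: c_in * N * c_out,
    batch norm: 2 * c_out.
    """
    if min(c_in, c_out, n, offset_kernel) < 1:
        raise ValueError("arguments must be positive")
    return c_in * offset_kernel ** 2 * 2 * n + c_in * n * c_out + 2 * c_out


class AKConv(nn.Module):
    """See module docstring. Offset-predictor kernel is 3x3 at the layer stride."""

    def __init__(self, c_in: int, c_out: int, num_param: int = 3, stride: int = 1,
                 bias: bool = False):
        super().__init__()
        self.cfg = AKConvConfig(c_in, c_out, num_param, stride, bias)
        n = num_param
        self.p_conv = nn.Conv2d(c_in, 2 * n, kernel=3, stride=stride, bias=False)
        # Aggregation over the stacked sampling axis: equivalent to an (N,1)
        # kernel on the (B, C, N*H, W) reshaping -- c_in*N*c_out weights.
        self.agg = nn.Conv2d(c_in * n, c_out, kernel=1, bias=bias)
        self.bn = nn.BatchNorm2d(c_out)
        grid = np.asarray(initial_coordinates(n), dtype=np.float32)  # (N,2) row,col
        self.register_buffer("pn", grid)

    def predict_offsets(self, x: nn.Tensor) -> nn.Tensor:
        """Offset field of shape (B, 2N, H', W'), interleaved (drow, dcol)."""
        return self.p_conv(x)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        b, c, h, w = x.shape
        n = self.cfg.num_param
        s = self.cfg.stride
        offsets = self.predict_offsets(x)  # (B, 2N, Ho, Wo)
        _, _, ho, wo = offsets.shape
        # base output-cell positions P0 mapped into input coordinates
        base_r, base_c = np.meshgrid(np.arange(ho) * s, np.arange(wo) * s,
                                     indexing="ij")
        base = np.stack([base_r, base_c], axis=-1).astype(np.float32)  # (Ho,Wo,2)
        init = self.pn[None, :, None, None, :]  # (1,N,1,1,2)
        off = offsets.reshape(b, n, 2, ho, wo).transpose(0, 1, 3, 4, 2)
        pos = off + (base[None, None] + init)  # (B,N,Ho,Wo,2)
        sampled = F.bilinear_sample(x, pos)  # (B,C,N,Ho,Wo)
        stacked = sampled.reshape(b, c * n, ho, wo)
        out = self.bn(self.agg(stacked))
        return out.silu()
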