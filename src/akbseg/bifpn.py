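"""Bidirectional feature pyramid with fast-normalized weighted fusion.

Each fusion node combines same-shaped feature maps with learnable
non-negative per-edge weights:

    O = sum_i(w_i * F_i) / (eps + sum_j w_j)

Raw weights are rectified before normalization so the normalized
coefficients lie in [0, 1). The bidirectional layer runs one top-down pass
producing intermediate nodes and one bottom-up pass producing outputs; a
node that would have a single input edge is removed from the graph (the
coarsest level has no separate intermediate node). Each fusion is followed
by a depthwise-separable convolution + batch normalization + activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as NF

__all__ = ["FusionWeights", "fast_normalized_fusion", "resize_to",
           "WeightedFusion", "BiFPNLayer", "BiFPN"]

DEFAULT_EPS = 1e-4


@dataclass
class FusionWeights:
    weights: np.ndarray  # one non-negative real per fused input edge
    eps: float = DEFAULT_EPS

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.eps <= 0:
            raise ValueError("eps must be positive")


class FusionError(ValueError):
    pass


def fast_normalized_fusion(inputs, weights, eps: float = DEFAULT_EPS):
    """Fuse same-shaped arrays: sum_i(w_i F_i) / (eps + sum_j w_j).

    Negative weights are rectified to zero. Accepts a FusionWeights or a
    plain sequence of weights.
    """
    if isinstance(weights, FusionWeights):
        eps = weights.eps
        weights = weights.weights
    w = np.maximum(np.asarray(weights, dtype=np.float64), 0.0)
    arrays = [np.asarray(f, dtype=np.float64) for f in inputs]
    if len(arrays) == 0:
        raise FusionError("at least one input required")
    if len(w) != len(arrays):
        raise FusionError("one weight per input required")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise FusionError("all fused inputs must share a shape")
    num = sum(wi * a for wi, a in zip(w, arrays))
    return num / (eps + w.sum())


def resize_to(feature: np.ndarray, target_spatial: tuple[int, int]) -> np.ndarray:
    """Resize a (..., H, W) map: nearest-neighbor upsampling to enlarge,
    repeated stride-2 max-pooling to reduce. Identity if already the size."""
    th, tw = target_spatial
    if th < 1 or tw < 1:
        raise ValueError("target dims must be >= 1")
    out = np.asarray(feature)
    h, w = out.shape[-2:]
    if (h, w) == (th, tw):
        return out
    if th >= h and tw >= w:
        sh, sw = th // h, tw // w
        return out.repeat(sh, axis=-2).repeat(sw, axis=-1)
    while out.shape[-2] > th or out.shape[-1] > tw:
        h, w = out.shape[-2:]
        nh, nw = h - h % 2, w - w % 2
        trimmed = out[..., :nh, :nw]
        s = trimmed.shape
        blocks = trimmed.reshape(*s[:-2], nh // 2, 2, nw // 2, 2)
        out = blocks.max(axis=(-3, -1))
    return out


class WeightedFusion(nn.Module):
    """Learnable fast-normalized fusion node (graph-building counterpart of
    :func:`fast_normalized_fusion`); weights initialized to one."""

    def __init__(self, n_inputs: int, eps: float = DEFAULT_EPS):
        super().__init__()
        self.w = nn.Tensor(np.ones(n_inputs, np.float32), requires_grad=True)
        self.eps = eps
        self.n_inputs = n_inputs

    def normalized_weights(self) -> np.ndarray:
        w = np.maximum(self.w.data, 0.0)
        return w / (self.eps + w.sum())

    def forward(self, inputs: list[nn.Tensor]) -> nn.Tensor:
        if len(inputs) != self.n_inputs:
            raise FusionError("wrong number of fusion inputs")
        w = self.w.relu()
        denom = (w.sum() + self.eps) ** -1.0
        out = inputs[0] * (w[0] * denom)
        for i in range(1, len(inputs)):
            out = out + inputs[i] * (w[i] * denom)
        return out


class _Down(nn.Module):
    """Stride-2 max-pool downsampling used on bottom-up edges."""

    def forward(self, x):
        return NF.max_pool2d(x, 2, 2)


class BiFPNLayer(nn.Module):
    """One bidirectional pass over `n_levels` maps of equal channel width.

    Level 0 is the finest. Intermediate (top-down) nodes exist for levels
    0..n-2; the coarsest level's would-be intermediate has one input and is
    removed. Output (bottom-up) nodes fuse input, intermediate and the
    downsampled finer output (three edges; two at the extremes).
    """

    def __init__(self, channels: int, n_levels: int = 3, eps: float = DEFAULT_EPS,
                 transform: str = "dwsep"):
        super().__init__()
        if n_levels < 2:
            raise ValueError("a pyramid needs at least 2 levels")
        self.n_levels = n_levels
        self.td_fuse = nn.ModuleList(
            WeightedFusion(2, eps) for _ in range(n_levels - 1))
        out_fuse = []
        for lv in range(1, n_levels):
            out_fuse.append(WeightedFusion(2 if lv == n_levels - 1 else 3, eps))
        self.out_fuse = nn.ModuleList(out_fuse)

        def make_tf():
            return nn.DWSepConv(channels) if transform == "dwsep" else nn.Identity()

        self.td_tf = nn.ModuleList(make_tf() for _ in range(n_levels - 1))
        self.out_tf = nn.ModuleList(make_tf() for _ in range(n_levels - 1))

    def forward(self, levels: list[nn.Tensor]) -> list[nn.Tensor]:
        n = self.n_levels
        if len(levels) != n:
            raise FusionError(f"expected {n} pyramid levels, got {len(levels)}")
        td = [None] * n
        td[n - 1] = levels[n - 1]
        for lv in range(n - 2, -1, -1):
            up = NF.upsample_nearest2d(td[lv + 1], 2)
            fused = self.td_fuse[lv]([levels[lv], up])
            td[lv] = self.td_tf[lv](fused)
        out = [None] * n
        out[0] = td[0]
        for lv in range(1, n):
            down = NF.max_pool2d(out[lv - 1], 2, 2)
            if lv == n - 1:
                fused = self.out_fuse[lv - 1]([levels[lv], down])
            else:
                fused = self.out_fuse[lv - 1]([levels[lv], td[lv], down])
            out[lv] = self.out_tf[lv - 1](fused)
        return out


@dataclass
class BiFPNConfig:
    channels: int = 128
    n_levels: int = 3
    repeats: int = 5          # `bifpn_layers`
    eps: float = DEFAULT_EPS
    in_channels: tuple = ()   # per-level input widths; () = already `channels`


class BiFPN(nn.Module):
    """Stack of BiFPN layers with per-level 1x1 input projections."""

    def __init__(self, cfg: BiFPNConfig | None = None, **kwargs):
        super().__init__()
        cfg = cfg or BiFPNConfig(**kwargs)
        self.cfg = cfg
        if cfg.in_channels:
            if len(cfg.in_channels) != cfg.n_levels:
                raise FusionError("one input width per level required")
            self.proj = nn.ModuleList(
                nn.Conv(c, cfg.channels, 1, act=False) for c in cfg.in_channels)
        else:
            self.proj = nn.ModuleList(nn.Identity() for _ in range(cfg.n_levels))
        self.layers = nn.ModuleList(
            BiFPNLayer(cfg.channels, cfg.n_levels, cfg.eps)
            for _ in range(cfg.repeats))

    def forward(self, levels: list[nn.Tensor]) -> list[nn.Tensor]:
        levels = [p(x) for p, x in zip(self.proj, levels)]
        for layer in self.layers:
            levels = layer(levels)
        return levels
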