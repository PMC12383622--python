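"""Structured ops (convolution, pooling, resampling) with custom backward passes."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "conv2d",
    "conv_transpose2d",
    "max_pool2d",
    "upsample_nearest2d",
    "batch_norm2d",
    "bilinear_sample",
    "mac_counter",
]


class mac_counter:
    """Context manager accumulating multiply-accumulate counts of the
    convolution ops executed inside it (informational complexity metric)."""

    _active = None

    def __init__(self):
        self.macs = 0

    def __enter__(self):
        mac_counter._active = self
        return self

    def __exit__(self, *exc):
        mac_counter._active = None
        return False

    @classmethod
    def add(cls, n: int):
        if cls._active is not None:
            cls._active.macs += int(n)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Return column matrix (B, Ho*Wo, C*kh*kw) plus output dims."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    B, C, H, W = x.shape
    ho = (H - kh) // stride + 1
    wo = (W - kw) // stride + 1
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # (B, C, ho, wo, kh, kw) -> (B, ho*wo, C*kh*kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, ho * wo, C * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(gcols: np.ndarray, x_shape, kh, kw, stride, pad):
    """Scatter column gradients back to the (padded) input."""
    B, C, H, W = x_shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    ho = (Hp - kh) // stride + 1
    wo = (Wp - kw) // stride + 1
    g = gcols.reshape(B, ho, wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    gx = np.zeros((B, C, Hp, Wp), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += g[..., i, j]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    co, ci, kh, kw = weight.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(co, -1)
    mac_counter.add(cols.shape[0] * cols.shape[1] * cols.shape[2] * co)
    out = cols @ wmat.T  # (B, ho*wo, co)
    if bias is not None:
        out = out + bias.data[None, None, :]
    B = x.shape[0]
    out_data = out.transpose(0, 2, 1).reshape(B, co, ho, wo)

    def backward(g):
        g2 = g.reshape(B, co, ho * wo).transpose(0, 2, 1)  # (B, ho*wo, co)
        if weight.requires_grad:
            gw = np.einsum("bnc,bnk->ck", g2, cols, optimize=True)
            weight._accum(gw.reshape(weight.shape).astype(np.float32))
        if bias is not None and bias.requires_grad:
            bias._accum(g2.sum(axis=(0, 1)).astype(np.float32))
        if x.requires_grad:
            gcols = g2 @ wmat  # (B, ho*wo, ci*kh*kw)
            x._accum(_col2im(gcols, x.shape, kh, kw, stride, padding))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return x._make(out_data, parents, backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 2) -> Tensor:
    """Transposed convolution, weight (C_in, C_out, k, k); used by the mask
    prototype head's learned 2x upsampling."""
    ci, co, kh, kw = weight.shape
    B, _, H, W = x.shape
    Ho, Wo = (H - 1) * stride + kh, (W - 1) * stride + kw
    mac_counter.add(B * ci * co * H * W * kh * kw)
    y = np.einsum("bchw,cdij->bdhwij", x.data, weight.data, optimize=True)
    out_data = np.zeros((B, co, Ho, Wo), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            out_data[:, :, i:i + (H - 1) * stride + 1:stride,
                     j:j + (W - 1) * stride + 1:stride] += y[..., i, j]
    if bias is not None:
        out_data += bias.data[None, :, None, None]

    def backward(g):
        gsub = np.empty((B, co, H, W, kh, kw), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                gsub[..., i, j] = g[:, :, i:i + (H - 1) * stride + 1:stride,
                                    j:j + (W - 1) * stride + 1:stride]
        if weight.requires_grad:
            gw = np.einsum("bchw,bdhwij->cdij", x.data, gsub, optimize=True)
            weight._accum(gw.astype(np.float32))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)).astype(np.float32))
        if x.requires_grad:
            gx = np.einsum("bdhwij,cdij->bchw", gsub, weight.data, optimize=True)
            x._accum(gx.astype(np.float32))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return x._make(out_data, parents, backward)


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None,
               padding: int = 0) -> Tensor:
    stride = stride or kernel
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2),
                    constant_values=-np.inf)
    B, C, Hp, Wp = xd.shape
    win = sliding_window_view(xd, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    B, C, ho, wo = win.shape[:4]
    flat = win.reshape(B, C, ho, wo, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros((B, C, Hp, Wp), dtype=np.float32)
        ki, kj = np.unravel_index(idx, (kernel, kernel))
        bi, ci, hi, wi = np.indices(idx.shape, sparse=False)
        rows = hi * stride + ki
        cols = wi * stride + kj
        np.add.at(gx, (bi, ci, rows, cols), g)
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        x._accum(gx)

    return x._make(out_data.astype(np.float32), (x,), backward)


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    out_data = x.data.repeat(scale, axis=2).repeat(scale, axis=3)
    B, C, H, W = x.shape

    def backward(g):
        if x.requires_grad:
            gx = g.reshape(B, C, H, scale, W, scale).sum(axis=(3, 5))
            x._accum(gx.astype(np.float32))

    return x._make(out_data, (x,), backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Channelwise standardization; running statistics updated in place."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        # biased variance on purpose: running stats then reproduce
        # train-mode normalization exactly after a recalibration pass,
        # which matters because per-layer normalization mismatches are
        # strongly amplified through the deep stack
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out_data = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)).astype(np.float32))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)).astype(np.float32))
        if not x.requires_grad:
            return
        gi = g * gamma.data[None, :, None, None]
        if training:
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            gmean = gi.mean(axis=(0, 2, 3), keepdims=True)
            gdot = (gi * xhat).mean(axis=(0, 2, 3), keepdims=True)
            gx = (gi - gmean - xhat * gdot) * inv[None, :, None, None]
        else:
            gx = gi * inv[None, :, None, None]
        x._accum(gx.astype(np.float32))

    return x._make(out_data.astype(np.float32), (x, gamma, beta), backward)


def bilinear_sample(x: Tensor, pos: Tensor) -> Tensor:
    """Sample `x` (B,C,H,W) at fractional positions `pos` (B,N,Ho,Wo,2).

    Positions are (row, col) in pixel units; out-of-bounds positions are
    clamped to the border. Gradients flow to both the feature map and the
    positions (the offset-learning path). Returns (B, C, N, Ho, Wo).
    """
    B, C, H, W = x.shape
    _, N, Ho, Wo, _ = pos.shape
    r = np.clip(pos.data[..., 0], 0.0, H - 1.0)
    c = np.clip(pos.data[..., 1], 0.0, W - 1.0)
    r0 = np.floor(r).astype(np.int64)
    c0 = np.floor(c).astype(np.int64)
    r1 = np.minimum(r0 + 1, H - 1)
    c1 = np.minimum(c0 + 1, W - 1)
    dr = (r - r0).astype(np.float32)
    dc = (c - c0).astype(np.float32)

    xf = x.data.reshape(B, C, H * W)
    bidx = np.arange(B)[:, None, None, None]

    def gather(ri, ci):
        flat = (ri * W + ci)  # (B,N,Ho,Wo)
        v = np.take_along_axis(xf, flat.reshape(B, 1, -1).repeat(C, axis=1), axis=2)
        return v.reshape(B, C, N, Ho, Wo)

    v00, v01 = gather(r0, c0), gather(r0, c1)
    v10, v11 = gather(r1, c0), gather(r1, c1)
    w00 = ((1 - dr) * (1 - dc))[:, None]
    w01 = ((1 - dr) * dc)[:, None]
    w10 = (dr * (1 - dc))[:, None]
    w11 = (dr * dc)[:, None]
    out_data = v00 * w00 + v01 * w01 + v10 * w10 + v11 * w11

    def backward(g):
        if x.requires_grad:
            gx = np.zeros((B, C, H * W), dtype=np.float32)
            for v, ri, ci, wgt in ((v00, r0, c0, w00), (v01, r0, c1, w01),
                                   (v10, r1, c0, w10), (v11, r1, c1, w11)):
                flat = (ri * W + ci).reshape(B, 1, -1).repeat(C, axis=1)
                np.add.at(gx, (bidx[..., 0].reshape(B, 1, 1),
                               np.arange(C)[None, :, None], flat),
                          (g * wgt).reshape(B, C, -1))
            x._accum(gx.reshape(B, C, H, W))
        if pos.requires_grad:
            # d out / d r and d c, summed over channels; zero where clamped.
            gr = (g * ((v10 - v00) * (1 - dc)[:, None] + (v11 - v01) * dc[:, None])).sum(axis=1)
            gc = (g * ((v01 - v00) * (1 - dr)[:, None] + (v11 - v10) * dr[:, None])).sum(axis=1)
            in_r = (pos.data[..., 0] > 0.0) & (pos.data[..., 0] < H - 1.0)
            in_c = (pos.data[..., 1] > 0.0) & (pos.data[..., 1] < W - 1.0)
            gp = np.stack([gr * in_r, gc * in_c], axis=-1)
            pos._accum(gp.astype(np.float32))

    return x._make(out_data.astype(np.float32), (x, pos), backward)
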