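"""Layer modules: parameter registration, train/eval state, serialization."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module", "Sequential", "ModuleList", "Identity",
    "Conv2d", "ConvTranspose2d", "BatchNorm2d", "Conv", "DWSepConv",
    "MaxPool2d", "Upsample",
]


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield prefix + n, b
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        out = {n: p.data.copy() for n, p in self.named_parameters()}
        out.update({"buf:" + n: b.copy() for n, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict):
        for n, p in self.named_parameters():
            p.data[...] = state[n]
        for n, b in self.named_buffers():
            b[...] = state["buf:" + n]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._seq = list(mods)

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._seq)

    def __getitem__(self, i):
        return self._seq[i]


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = float(np.sqrt(1.0 / fan_in))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int):
    """Make subsequent layer construction deterministic."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel=1, stride=1, padding=None, bias=True):
        super().__init__()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = c_in * kernel * kernel
        self.weight = Tensor(_kaiming(_INIT_RNG, (c_out, c_in, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(_kaiming(_INIT_RNG, (c_out,), fan_in), requires_grad=True) \
            if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, c_in, c_out, kernel=2, stride=2, bias=True):
        super().__init__()
        self.stride = stride
        fan_in = c_in * kernel * kernel
        self.weight = Tensor(_kaiming(_INIT_RNG, (c_in, c_out, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(_kaiming(_INIT_RNG, (c_out,), fan_in), requires_grad=True) \
            if bias else None

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.weight = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(c, np.float32))
        self.register_buffer("running_var", np.ones(c, np.float32))

    def forward(self, x):
        return F.batch_norm2d(x, self.weight, self.bias, self.running_mean,
                              self.running_var, self.training, self.momentum, self.eps)


class Conv(Module):
    """Convolution + BatchNorm + SiLU, the network's standard block."""

    def __init__(self, c_in, c_out, kernel=1, stride=1, padding=None, act=True):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, kernel, stride, padding, bias=False)
        self.bn = BatchNorm2d(c_out)
        self.act = act

    def forward(self, x):
        x = self.bn(self.conv(x))
        return x.silu() if self.act else x


class DWSepConv(Module):
    """Depthwise 3x3 (per-channel) followed by pointwise 1x1, + BN + SiLU."""

    def __init__(self, c, kernel=3):
        super().__init__()
        fan_in = kernel * kernel
        self.dw_weight = Tensor(_kaiming(_INIT_RNG, (c, 1, kernel, kernel), fan_in),
                                requires_grad=True)
        self.pw = Conv2d(c, c, 1, bias=False)
        self.bn = BatchNorm2d(c)
        self.kernel = kernel
        self.c = c

    def forward(self, x):
        B, C, H, W = x.shape
        y = self._dw(x.reshape(B * C, 1, H, W), B, C, H, W)
        y = self.pw(y)
        return self.bn(y).silu()

    def _dw(self, xr, B, C, H, W):
        # Channelwise conv: treat channels as batch, one 1-in/1-out kernel per channel.
        # Implemented by tiling: conv each channel with its own kernel via grouped matmul.
        from .functional import _im2col
        k = self.kernel
        cols, ho, wo = _im2col(xr.data, k, k, 1, k // 2)  # (B*C, ho*wo, k*k)
        wmat = self.dw_weight.data.reshape(C, k * k)
        colsr = cols.reshape(B, C, ho * wo, k * k)
        out = np.einsum("bcnk,ck->bcn", colsr, wmat, optimize=True)
        out_data = out.reshape(B, C, ho, wo).astype(np.float32)
        x = xr
        dw = self.dw_weight

        def backward(g):
            g2 = g.reshape(B, C, ho * wo)
            if dw.requires_grad:
                gw = np.einsum("bcn,bcnk->ck", g2, colsr, optimize=True)
                dw._accum(gw.reshape(dw.shape).astype(np.float32))
            if x.requires_grad:
                gcols = np.einsum("bcn,ck->bcnk", g2, wmat, optimize=True)
                from .functional import _col2im
                gx = _col2im(gcols.reshape(B * C, ho * wo, k * k),
                             (B * C, 1, H, W), k, k, 1, k // 2)
                x._accum(gx)

        return x._make(out_data, (x, dw), backward)


class MaxPool2d(Module):
    def __init__(self, kernel, stride=None, padding=0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel, self.stride, self.padding)


class Upsample(Module):
    def __init__(self, scale=2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return F.upsample_nearest2d(x, self.scale)
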