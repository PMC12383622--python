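"""Numerical checks of the autodiff engine against finite differences and
scipy reference implementations."""

import numpy as np
import pytest
from scipy import ndimage, signal

from akbseg import nn
from akbseg.nn import functional as F


def numeric_grad(f, x, eps=1e-3):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grad_matches(build, tensors, tol=2e-2):
    loss = build()
    loss.backward()
    analytic = [t.grad.copy() for t in tensors]
    for t, an in zip(tensors, analytic):
        nu = numeric_grad(lambda: build().item(), t.data)
        err = np.abs(an - nu).max() / (np.abs(nu).max() + 1e-6)
        assert err < tol


@pytest.fixture
def x(rng):
    return nn.Tensor(rng.normal(size=(2, 3, 6, 6)).astype(np.float32),
                     requires_grad=True)


def test_conv2d_matches_scipy(rng, x):
    w = rng.normal(size=(4, 3, 3, 3)).astype(np.float32)
    out = F.conv2d(x, nn.Tensor(w), stride=1, padding=1).data
    for b in range(2):
        for co in range(4):
            ref = sum(signal.correlate2d(x.data[b, c], w[co, c], mode="same",
                                         boundary="fill")
                      for c in range(3))
            np.testing.assert_allclose(out[b, co], ref, atol=1e-4)


def test_conv2d_gradients(rng, x):
    w = nn.Tensor(rng.normal(size=(4, 3, 3, 3)).astype(np.float32) * 0.3,
                  requires_grad=True)
    b = nn.Tensor(rng.normal(size=(4,)).astype(np.float32), requires_grad=True)

    def build():
        for t in (x, w, b):
            t.grad = None
        return (F.conv2d(x, w, b, stride=2, padding=1) ** 2.0).sum()

    assert_grad_matches(build, [x, w, b])


def test_conv_transpose_gradients(rng, x):
    w = nn.Tensor(rng.normal(size=(3, 2, 2, 2)).astype(np.float32) * 0.3,
                  requires_grad=True)

    def build():
        x.grad = None
        w.grad = None
        return (F.conv_transpose2d(x, w, None, 2).silu() ** 2.0).sum()

    assert_grad_matches(build, [x, w])


def test_maxpool_matches_scipy_and_grad(rng, x):
    out = F.max_pool2d(x, 5, 1, 2).data
    ref = ndimage.maximum_filter(x.data, size=(1, 1, 5, 5),
                                 mode="constant", cval=-np.inf)
    np.testing.assert_allclose(out, ref, atol=1e-6)
    coeff = rng.normal(size=out.shape).astype(np.float32)

    def build():
        x.grad = None
        return (F.max_pool2d(x, 2, 2) * nn.Tensor(coeff[:, :, :3, :3])).sum()

    assert_grad_matches(build, [x])


def test_batchnorm_train_and_eval(rng, x):
    bn = nn.BatchNorm2d(3)
    y = bn(x)
    mu = y.data.mean(axis=(0, 2, 3))
    sd = y.data.std(axis=(0, 2, 3))
    np.testing.assert_allclose(mu, 0.0, atol=1e-5)
    np.testing.assert_allclose(sd, 1.0, atol=1e-3)

    def build():
        for t in (x, bn.weight, bn.bias):
            t.grad = None
        bn.running_mean[...] = 0
        bn.running_var[...] = 1
        return (bn(x).sigmoid() ** 2.0).sum()

    # train-mode normalization makes the loss nearly invariant to shifts of
    # x, so its gradients are small and float32 finite differences are noisy
    assert_grad_matches(build, [x, bn.weight, bn.bias], tol=5e-2)


def test_bilinear_sample_values_and_grad(rng):
    # hand value: center of a 2x2 map [[1,2],[3,4]] -> 2.5
    fmap = nn.Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]], np.float32),
                     requires_grad=True)
    pos = nn.Tensor(np.array([0.5, 0.5], np.float32).reshape(1, 1, 1, 1, 2),
                    requires_grad=True)
    out = F.bilinear_sample(fmap, pos)
    assert out.data.item() == pytest.approx(2.5)
    # out-of-bounds clamps to the border value
    pos2 = nn.Tensor(np.array([-0.5, 0.0], np.float32).reshape(1, 1, 1, 1, 2))
    assert F.bilinear_sample(fmap, pos2).data.item() == pytest.approx(1.0)

    x = nn.Tensor(rng.normal(size=(2, 3, 6, 6)).astype(np.float32),
                  requires_grad=True)
    p = nn.Tensor(rng.uniform(0.3, 4.5, size=(2, 2, 3, 3, 2)).astype(np.float32),
                  requires_grad=True)

    def build():
        x.grad = None
        p.grad = None
        return (F.bilinear_sample(x, p) ** 2.0).sum()

    assert_grad_matches(build, [x, p])


def test_softmax_reduction_broadcast_grads(rng):
    y = nn.Tensor(rng.normal(size=(3, 5)).astype(np.float32),
                  requires_grad=True)

    def build():
        y.grad = None
        s = y.softmax(1)
        joined = nn.Tensor.concat([s[:, :2], s[:, 2:] * 2.0], axis=1)
        return (joined.log() ** 2.0).mean()

    assert_grad_matches(build, [y])


def test_sgd_momentum_weight_decay_step():
    p = nn.Tensor(np.array([1.0, -2.0], np.float32), requires_grad=True)
    opt = nn.SGD([p], lr=0.1, momentum=0.9, weight_decay=0.1)
    p.grad = np.array([0.5, 0.5], np.float32)
    opt.step()
    # v = g + wd*p ; p -= lr*v
    np.testing.assert_allclose(p.data, [1.0 - 0.1 * 0.6, -2.0 - 0.1 * 0.3],
                               atol=1e-6)
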