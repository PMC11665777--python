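"""Numerical correctness of the autodiff core: finite-difference gradient
checks, resize-operator exactness, and optimiser behaviour."""

import numpy as np
import pytest

from plutonet import nn
from plutonet.losses import dice_loss
from plutonet.nn import (Adam, BatchNorm, Conv2d, Dense, DepthwiseConv2d,
                         Tensor)

RNG = np.random.default_rng(42)


def _numeric_grad(make_loss, param, idx, eps=1e-3):
    orig = param.data[idx]
    param.data[idx] = orig + eps
    lp = make_loss().item()
    param.data[idx] = orig - eps
    lm = make_loss().item()
    param.data[idx] = orig
    return (lp - lm) / (2 * eps)


def _check(make_loss, params, n_probes=3, tol=2e-2):
    loss = make_loss()
    loss.backward()
    grads = [p.grad.copy() for p in params]
    for p, g in zip(params, grads):
        for _ in range(n_probes):
            idx = tuple(int(RNG.integers(0, s)) for s in p.data.shape)
            num = _numeric_grad(make_loss, p, idx)
            assert abs(num - g[idx]) <= tol * max(1.0, abs(num)), \
                f"{p.data.shape}@{idx}: numeric {num} vs autodiff {g[idx]}"


x0 = RNG.normal(0, 1, (2, 8, 8, 5)).astype(np.float32)
target = (RNG.random((2, 8, 8, 3)) > 0.6).astype(np.float32)


def test_conv_bn_resize_gradients_match_finite_differences():
    conv = Conv2d(5, 3, 3, stride=2, rng=RNG)
    bn = BatchNorm(3)

    def loss():
        y = nn.relu(bn(conv(Tensor(x0)), training=True))
        y = nn.resize_bilinear(y, (8, 8))
        return dice_loss(nn.sigmoid(y), target)

    _check(loss, [conv.weight, conv.bias, bn.gamma, bn.beta])


def test_depthwise_and_silu_gradients():
    dw = DepthwiseConv2d(5, 3, stride=2, rng=RNG)

    def loss():
        return nn.silu(dw(Tensor(x0))).square().mean()

    _check(loss, [dw.weight])


def test_dense_and_concat_gradients():
    d1 = Dense(5, 4, rng=RNG)
    d2 = Dense(5, 4, bias=False, rng=RNG)
    z = RNG.normal(0, 1, (6, 5)).astype(np.float32)

    def loss():
        t = Tensor(z)
        y = nn.concat([nn.sigmoid(d1(t)), nn.relu(d2(t))], axis=-1)
        return (y * y).mean()

    _check(loss, [d1.weight, d1.bias, d2.weight])


def test_input_gradient_through_convolution():
    conv = Conv2d(5, 4, 3, rng=RNG)
    xt = Tensor(x0, requires_grad=True)
    (conv(xt).square().sum()).backward()
    g = xt.grad.copy()
    idx = (1, 3, 2, 4)
    eps = 1e-3
    xp = x0.copy(); xp[idx] += eps
    xm = x0.copy(); xm[idx] -= eps
    num = (float((conv(Tensor(xp)).data ** 2).sum())
           - float((conv(Tensor(xm)).data ** 2).sum())) / (2 * eps)
    assert abs(num - g[idx]) <= 2e-2 * max(1.0, abs(num))


def test_batchnorm_training_vs_inference_statistics():
    bn = BatchNorm(4)
    x = RNG.normal(3.0, 2.0, (8, 5, 5, 4)).astype(np.float32)
    y = bn(Tensor(x), training=True)
    # batch statistics: normalised output has ~zero mean and unit variance
    assert np.allclose(y.data.mean(axis=(0, 1, 2)), 0, atol=1e-4)
    assert np.allclose(y.data.var(axis=(0, 1, 2)), 1, atol=1e-2)
    # inference mode uses the (different) running statistics
    y2 = bn(Tensor(x), training=False)
    assert not np.allclose(y.data, y2.data)


def test_resize_matrix_rows_are_convex_combinations():
    for src, dst in [(7, 14), (14, 7), (3, 10), (10, 3)]:
        m = nn._resize_matrix(src, dst)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-6)
        assert (m >= 0).all()


def test_same_padding_matches_output_size_contract():
    for size, k, s in [(8, 3, 1), (8, 3, 2), (7, 5, 2), (9, 1, 1)]:
        x = RNG.normal(0, 1, (1, size, size, 2)).astype(np.float32)
        y = Conv2d(2, 3, k, stride=s, rng=RNG)(Tensor(x))
        assert y.data.shape[1] == -(-size // s)


def test_adam_minimises_a_quadratic():
    p = nn.Parameter(np.array([5.0, -3.0], dtype=np.float32))
    opt = Adam([p], lr=0.1)
    for _ in range(200):
        loss = (p * p).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.abs(p.data).max() < 0.05
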