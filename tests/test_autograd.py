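"""Finite-difference gradient checks and contracts for the tensor backend."""

import numpy as np
import pytest

from uqseg.nn import Tensor
from uqseg.nn import autograd as ag
from uqseg.nn.autograd import dice_loss_op
from uqseg.nn.layers import Conv3dLayer
from uqseg.nn.optim import Adam


def _backprop_weighted(out: Tensor, weights: np.ndarray) -> None:
    """Backward pass of sum(out * weights) without adding a sum op."""
    out.grad = weights.astype(np.float32).copy()
    topo, seen, stack = [], set(), [(out, False)]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node)


def _numeric_grad(f, x0: np.ndarray, weights: np.ndarray,
                  eps: float = 1e-2) -> np.ndarray:
    num = np.zeros_like(x0, dtype=np.float64)
    it = np.nditer(x0, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x0.copy()
        xp[idx] += eps
        xm = x0.copy()
        xm[idx] -= eps
        fp = (f(xp).astype(np.float64) * weights).sum()
        fm = (f(xm).astype(np.float64) * weights).sum()
        num[idx] = (fp - fm) / (2 * eps)
    return num


OPS = {
    "conv3d": None,  # handled separately (needs weights)
    "avg_pool2": ag.avg_pool2,
    "upsample2": ag.upsample2,
    "sigmoid": ag.sigmoid,
    "softmax": ag.softmax_channels,
    "channel_mean": ag.channel_mean,
    "channel_max": ag.channel_max,
    "instance_norm": ag.instance_norm,
}


@pytest.mark.parametrize("name", [k for k, v in OPS.items() if v is not None])
def test_op_gradients_match_finite_differences(name):
    import zlib

    rng = np.random.default_rng(zlib.crc32(name.encode()))
    x0 = rng.standard_normal((2, 3, 4, 4, 4)).astype(np.float32)
    if name == "channel_max":
        # separate the channels so the max is differentiable at eps scale
        x0 += 10.0 * np.arange(3, dtype=np.float32)[None, :, None, None, None]
        x0 = x0.astype(np.float32)
    op = OPS[name]
    x = Tensor(x0, requires_grad=True)
    out = op(x)
    weights = rng.standard_normal(out.shape)
    _backprop_weighted(out, weights)
    num = _numeric_grad(lambda a: op(Tensor(a)).data, x0, weights)
    scale = max(1.0, np.abs(num).max())
    assert np.abs(x.grad - num).max() / scale < 2e-2


def test_conv3d_gradients_match_finite_differences():
    rng = np.random.default_rng(0)
    x0 = rng.standard_normal((2, 3, 4, 4, 4)).astype(np.float32)
    w0 = (rng.standard_normal((2, 3, 3, 3, 3)) * 0.3).astype(np.float32)
    b0 = rng.standard_normal(2).astype(np.float32)
    x, w, b = (Tensor(a, requires_grad=True) for a in (x0, w0, b0))
    out = ag.conv3d(x, w, b, padding=1)
    weights = rng.standard_normal(out.shape)
    _backprop_weighted(out, weights)
    num_x = _numeric_grad(
        lambda a: ag.conv3d(Tensor(a), Tensor(w0), Tensor(b0), 1).data,
        x0, weights)
    num_w = _numeric_grad(
        lambda a: ag.conv3d(Tensor(x0), Tensor(a), Tensor(b0), 1).data,
        w0, weights)
    for got, num in ((x.grad, num_x), (w.grad, num_w)):
        scale = max(1.0, np.abs(num).max())
        assert np.abs(got - num).max() / scale < 2e-2
    assert np.allclose(b.grad, weights.sum(axis=(0, 2, 3, 4)), rtol=1e-4,
                       atol=1e-3)


def test_conv3d_matches_naive_window_loop():
    """Direct triple-loop convolution oracle on a tiny case."""
    rng = np.random.default_rng(1)
    x = rng.standard_normal((1, 2, 4, 4, 4)).astype(np.float32)
    w = rng.standard_normal((3, 2, 3, 3, 3)).astype(np.float32)
    b = rng.standard_normal(3).astype(np.float32)
    out = ag.conv3d(Tensor(x), Tensor(w), Tensor(b), 1).data
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    ref = np.zeros_like(out)
    for o in range(3):
        for d in range(4):
            for h in range(4):
                for v in range(4):
                    patch = xp[0, :, d:d + 3, h:h + 3, v:v + 3]
                    ref[0, o, d, h, v] = (patch * w[o]).sum() + b[o]
    assert np.abs(out - ref).max() < 1e-4


def test_dice_loss_op_gradient():
    rng = np.random.default_rng(2)
    p0 = rng.random((1, 4, 3, 3, 3)).astype(np.float32)
    g = (rng.random((1, 4, 3, 3, 3)) > 0.6).astype(np.float32)
    p = Tensor(p0, requires_grad=True)
    loss = dice_loss_op(p, g)
    loss.backward()
    num = np.zeros_like(p0, dtype=np.float64)
    eps = 1e-3
    it = np.nditer(p0, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        pp = p0.copy()
        pp[idx] += eps
        pm = p0.copy()
        pm[idx] -= eps
        num[idx] = (float(dice_loss_op(Tensor(pp), g).data)
                    - float(dice_loss_op(Tensor(pm), g).data)) / (2 * eps)
    assert np.abs(p.grad - num).max() < 5e-3


def test_dropout_scales_and_masks(rng):
    x = Tensor(np.ones((1, 2, 4, 4, 4), dtype=np.float32), requires_grad=True)
    out = ag.dropout(x, 0.5, np.random.default_rng(0))
    vals = set(np.unique(out.data).tolist())
    assert vals <= {0.0, 2.0}  # inverted dropout at rate 0.5
    assert ag.dropout(x, 0.0, None) is x


def test_pool_upsample_are_adjoint_shapes(rng):
    x = Tensor(rng.standard_normal((1, 2, 8, 8, 8)).astype(np.float32))
    assert ag.avg_pool2(x).shape == (1, 2, 4, 4, 4)
    assert ag.upsample2(ag.avg_pool2(x)).shape == x.shape
    with pytest.raises(ValueError):
        ag.avg_pool2(Tensor(np.zeros((1, 1, 3, 4, 4))))


def test_adam_reduces_quadratic_loss():
    rng = np.random.default_rng(3)
    target = rng.standard_normal((4, 2, 3, 3, 3)).astype(np.float32)
    w = Tensor(np.zeros_like(target), requires_grad=True)
    opt = Adam([w], lr=0.05, betas=(0.5, 0.999))
    losses = []
    for _ in range(50):
        diff = ag.add(w, Tensor(-target))
        sq = ag.mul(diff, diff)
        _backprop_weighted(sq, np.ones(sq.shape))
        losses.append(float((sq.data).sum()))
        opt.step()
        opt.zero_grad()
    assert losses[-1] < 0.05 * losses[0]


def test_conv_layer_requires_odd_kernel():
    with pytest.raises(ValueError):
        Conv3dLayer(2, 2, kernel=2)
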