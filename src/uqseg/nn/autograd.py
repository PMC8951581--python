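"""Minimal reverse-mode autodiff on numpy arrays.

Implements exactly the operations a 3-D encoder–decoder segmentation
network with spatial attention needs: stride-1 3-D convolution (im2col),
factor-2 average pooling and nearest-neighbour upsampling, ReLU, sigmoid,
channel-wise softmax, dropout, channel concatenation / pooling, broadcast
multiply/add, and a soft multi-class Dice loss.  Tensors wrap float32
arrays; gradients are accumulated by closures in topological order.

All convolutions are stride 1 with symmetric zero padding; spatial
resolution changes go through the pooling/upsampling ops only.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from . import _kernels

__all__ = [
    "Tensor",
    "conv3d",
    "avg_pool2",
    "upsample2",
    "relu",
    "sigmoid",
    "instance_norm",
    "softmax_channels",
    "dropout",
    "concat_channels",
    "channel_mean",
    "channel_max",
    "add",
    "mul",
    "dice_loss_op",
]


class Tensor:
    """A node in the computation graph holding a float32 array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple = (),
        _backward: Callable[["Tensor"], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node)


def _needs_grad(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _make(data, parents, backward) -> Tensor:
    if any(_needs_grad(p) for p in parents):
        return Tensor(data, _parents=tuple(parents), _backward=backward)
    return Tensor(data)


# ---------------------------------------------------------------------------
# convolution


def _corr3d(x: np.ndarray, w: np.ndarray, pad: int):
    """Stride-1 cross-correlation of (N,Ci,D,H,W) with (Co,Ci,k,k,k).

    Computed as a sum of per-offset channel matmuls over shifted views of
    the padded input (avoids materialising an im2col matrix).  Returns
    the output and the padded input for reuse in the weight gradient.
    """
    if pad:
        x = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    x = np.ascontiguousarray(x, dtype=np.float32)
    return _kernels.corr3d(x, np.ascontiguousarray(w, dtype=np.float32)), x


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, padding: int) -> Tensor:
    """3-D convolution, stride 1, cubic kernel, symmetric zero padding."""
    out, xp = _corr3d(x.data, w.data, padding)
    if b is not None:
        out = out + b.data[None, :, None, None, None]
    k = w.data.shape[2]

    def backward(node: Tensor) -> None:
        go = np.ascontiguousarray(node.grad, dtype=np.float32)
        if w.requires_grad or w._parents:
            w._accumulate(_kernels.corr3d_dw(xp, go, w.data.shape))
        if b is not None and (b.requires_grad or b._parents):
            b._accumulate(go.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad or x._parents:
            w_flip = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            dx, _ = _corr3d(go, np.ascontiguousarray(w_flip), k - 1 - padding)
            x._accumulate(dx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


# ---------------------------------------------------------------------------
# resolution changes


def avg_pool2(x: Tensor) -> Tensor:
    """2x2x2 average pooling; spatial dims must be even."""
    n, c, d, h, w = x.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"avg_pool2 needs even spatial dims, got {(d, h, w)}")
    r = x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    out = r.mean(axis=(3, 5, 7))

    def backward(node: Tensor) -> None:
        g = node.grad / 8.0
        g = np.repeat(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3), 2, axis=4)
        x._accumulate(g)

    return _make(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour upsampling by a factor of 2 per spatial axis."""
    out = np.repeat(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), 2, axis=4)

    def backward(node: Tensor) -> None:
        n, c, d, h, w = node.grad.shape
        g = node.grad.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        x._accumulate(g.sum(axis=(3, 5, 7)))

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# pointwise nonlinearities


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(node: Tensor) -> None:
        x._accumulate(node.grad * mask)

    return _make(out, (x,), backward)


def leaky_relu(x: Tensor, alpha: float = 0.01) -> Tensor:
    """max(x, alpha*x); the small negative slope prevents dead units."""
    slope = np.where(x.data > 0, 1.0, alpha).astype(np.float32)
    out = x.data * slope

    def backward(node: Tensor) -> None:
        x._accumulate(node.grad * slope)

    return _make(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable two-branch form
    d = x.data
    out = np.where(d >= 0, 1.0 / (1.0 + np.exp(-np.clip(d, -60, 60))),
                   np.exp(np.clip(d, -60, 60)) / (1.0 + np.exp(np.clip(d, -60, 60))))
    out = out.astype(np.float32)

    def backward(node: Tensor) -> None:
        x._accumulate(node.grad * out * (1.0 - out))

    return _make(out, (x,), backward)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 (the class channel)."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=1, keepdims=True)

    def backward(node: Tensor) -> None:
        go = node.grad
        dot = (go * out).sum(axis=1, keepdims=True)
        x._accumulate(out * (go - dot))

    return _make(out.astype(np.float32), (x,), backward)


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalisation over spatial dims (no affine)."""
    axes = (2, 3, 4)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    s = np.sqrt(var + eps)
    y = (x.data - mu) / s

    def backward(node: Tensor) -> None:
        g = node.grad
        gm = g.mean(axis=axes, keepdims=True)
        gym = (g * y).mean(axis=axes, keepdims=True)
        x._accumulate((g - gm - y * gym) / s)

    return _make(y.astype(np.float32), (x,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0. `rng` supplies the mask."""
    if rate == 0.0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(np.float32) / (1.0 - rate)
    out = x.data * keep

    def backward(node: Tensor) -> None:
        x._accumulate(node.grad * keep)

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# channel algebra


def concat_channels(tensors: Sequence[Tensor]) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.shape[1] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(node: Tensor) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                t._accumulate(node.grad[:, lo:hi])

    return _make(out, tuple(tensors), backward)


def channel_mean(x: Tensor) -> Tensor:
    c = x.shape[1]
    out = x.data.mean(axis=1, keepdims=True)

    def backward(node: Tensor) -> None:
        x._accumulate(np.broadcast_to(node.grad / c, x.shape))

    return _make(out, (x,), backward)


def channel_max(x: Tensor) -> Tensor:
    """Max over channels; gradient routes to the first maximal channel."""
    idx = x.data.argmax(axis=1, keepdims=True)
    out = np.take_along_axis(x.data, idx, axis=1)

    def backward(node: Tensor) -> None:
        g = np.zeros_like(x.data)
        np.put_along_axis(g, idx, node.grad, axis=1)
        x._accumulate(g)

    return _make(out, (x,), backward)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(node: Tensor) -> None:
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(node.grad, a.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(node.grad, b.shape))

    return _make(out, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def backward(node: Tensor) -> None:
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(node.grad * b.data, a.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(node.grad * a.data, b.shape))

    return _make(out, (a, b), backward)


# ---------------------------------------------------------------------------
# loss


def dice_loss_op(probs: Tensor, onehot: np.ndarray,
                 foreground: Sequence[int] = (1, 2, 3),
                 eps: float = 1e-5) -> Tensor:
    """Soft Dice loss, one-vs-rest per foreground class, batch-pooled sums.

    Per class c: 1 - (2*sum(p_c*g_c) + eps) / (sum(p_c^2) + sum(g_c^2) + eps);
    the returned loss is the unweighted mean over `foreground` classes.
    """
    p = probs.data
    g = onehot
    fg = list(foreground)
    axes = (0, 2, 3, 4)
    num = 2.0 * (p[:, fg] * g[:, fg]).sum(axis=axes) + eps
    den = (p[:, fg] ** 2).sum(axis=axes) + (g[:, fg] ** 2).sum(axis=axes) + eps
    dice = num / den
    loss = 1.0 - dice.mean()

    def backward(node: Tensor) -> None:
        go = float(node.grad)
        dp = np.zeros_like(p)
        for i, c in enumerate(fg):
            # d dice_c / d p_c = (2 g den - 2 num p) / den^2
            dp[:, c] = (2.0 * g[:, c] * den[i] - 2.0 * num[i] * p[:, c]) / den[i] ** 2
        probs._accumulate((-go / len(fg)) * dp)

    return _make(np.float32(loss), (probs,), backward)
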