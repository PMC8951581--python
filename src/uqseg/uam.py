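"""Uncertainty attention module (UAM): spatial attention from uncertainty maps.

The attention map is

    A(F, U) = sigmoid( conv3( [ conv3(U_resized); AvgPool(F); MaxPool(F) ] ) )

where F is a C-channel feature map, U the 4-channel uncertainty block
resized (trilinearly) to F's spatial grid, the pools run across the
channel axis, [;] is channel concatenation and both convolutions are
3x3x3 with bias.  The refined features are

    O(F, U) = F * A + F

with the single-channel A broadcast across feature channels; the
additive skip keeps an identity path in the gradient.  A module is
inserted after every k-th convolution of the host network (default
k = 5), each insertion site owning its own weights.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, Conv3dLayer, Module
from .nn import autograd as ag
from .segnet import SegNet
from .uncertainty import UncertaintyBlock, MEASURES

__all__ = ["UamParams", "trilinear_resize", "resize_uncertainty",
           "channel_pool", "attention_map", "apply_uam", "plug_uam",
           "uam_param_count"]

_REDUCED_CHANNELS = 4  # conv3(U) keeps the 4 uncertainty channels


class UamParams(Module):
    """Weights of one attention site: the U-reduction conv and the fusion conv."""

    def __init__(self, rng: np.random.Generator | None = None,
                 n_u_channels: int = len(MEASURES)):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.reduce = Conv3dLayer(n_u_channels, _REDUCED_CHANNELS, 3, rng)
        # fusion sees [U'; F_avg; F_max] -> 1 attention channel
        self.fuse = Conv3dLayer(_REDUCED_CHANNELS + 2, 1, 3, rng)

    def conv_layers(self) -> list[Conv3dLayer]:
        return [self.reduce, self.fuse]

    def set_zero(self) -> None:
        """Zero all weights and biases (gives A = sigmoid(0) = 0.5 everywhere)."""
        for p in self.parameters():
            p.data[...] = 0.0


def uam_param_count(n_u_channels: int = len(MEASURES)) -> int:
    """Closed-form parameter count of one attention site."""
    reduce = n_u_channels * 27 * _REDUCED_CHANNELS + _REDUCED_CHANNELS
    fuse = (_REDUCED_CHANNELS + 2) * 27 * 1 + 1
    return reduce + fuse


# ---------------------------------------------------------------------------
# resizing


def _axis_lerp(arr: np.ndarray, axis: int, n_out: int) -> np.ndarray:
    """Linear interpolation along one axis with endpoint alignment."""
    n_in = arr.shape[axis]
    if n_out == n_in:
        return arr
    if n_in == 1:
        reps = [1] * arr.ndim
        reps[axis] = n_out
        return np.tile(arr, reps)
    if n_out == 1:
        pos = np.array([(n_in - 1) / 2.0])
    else:
        pos = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    lo = np.clip(np.floor(pos).astype(int), 0, n_in - 2)
    frac = (pos - lo).astype(np.float32)
    shape = [1] * arr.ndim
    shape[axis] = n_out
    frac = frac.reshape(shape)
    a = np.take(arr, lo, axis=axis)
    b = np.take(arr, lo + 1, axis=axis)
    return a * (1.0 - frac) + b * frac


def trilinear_resize(values: np.ndarray,
                     target_spatial: tuple[int, int, int]) -> np.ndarray:
    """Channel-preserving trilinear resize of a (C, X, Y, Z) array.

    Endpoints are aligned (corner voxels map to corner voxels), so a
    linear intensity ramp resizes to the analytic ramp and a constant
    field stays constant.  Returns a copy when dims already match.
    """
    out = np.asarray(values, dtype=np.float32)
    for ax, n_out in zip((1, 2, 3), target_spatial):
        out = _axis_lerp(out, ax, int(n_out))
    return np.array(out, dtype=np.float32, copy=True)


def resize_uncertainty(block: UncertaintyBlock,
                       target_spatial: tuple[int, int, int]) -> UncertaintyBlock:
    """Trilinearly resize the 4-channel uncertainty block per channel."""
    if any(n <= 0 for n in target_spatial):
        raise ValueError("target dims must be positive")
    return UncertaintyBlock(trilinear_resize(block.values, target_spatial))


# ---------------------------------------------------------------------------
# attention


def channel_pool(F: Tensor | np.ndarray) -> tuple[Tensor, Tensor]:
    """Per-voxel mean and max across feature channels (spatial dims kept)."""
    if isinstance(F, np.ndarray):
        F = Tensor(F)
    return ag.channel_mean(F), ag.channel_max(F)


def _as_batched_tensor(x, name: str) -> Tensor:
    if isinstance(x, np.ndarray):
        x = Tensor(x)
    if x.data.ndim == 4:  # (C, X, Y, Z) -> add batch axis
        x = Tensor(x.data[None]) if not (x.requires_grad or x._parents) else x
    if x.data.ndim != 5:
        raise ValueError(f"{name} must be (C, X, Y, Z) or (N, C, X, Y, Z)")
    return x


def attention_map(F: Tensor | np.ndarray, U: UncertaintyBlock | np.ndarray,
                  params: UamParams) -> Tensor:
    """Single-channel attention map with values strictly in (0, 1)."""
    F = _as_batched_tensor(F, "F")
    u_vals = U.values if isinstance(U, UncertaintyBlock) else np.asarray(U)
    n = F.shape[0]
    if u_vals.ndim == 4:  # one block shared across the batch
        u_res = trilinear_resize(u_vals, F.shape[2:])
        u_batched = np.broadcast_to(u_res[None], (n,) + u_res.shape).copy()
    elif u_vals.ndim == 5:  # per-sample blocks (training crops)
        u_batched = np.stack([trilinear_resize(u, F.shape[2:]) for u in u_vals])
    else:
        raise ValueError("uncertainty block must be (4,X,Y,Z) or (N,4,X,Y,Z)")
    u_t = Tensor(u_batched)
    u_prime = params.reduce(u_t)
    f_avg, f_max = channel_pool(F)
    fused = params.fuse(ag.concat_channels([u_prime, f_avg, f_max]))
    return ag.sigmoid(fused)


def apply_uam(F: Tensor | np.ndarray, U: UncertaintyBlock | np.ndarray,
              params: UamParams) -> Tensor:
    """Refined features O = F * A + F (A broadcast across channels)."""
    F = _as_batched_tensor(F, "F")
    A = attention_map(F, U, params)
    return ag.add(ag.mul(F, A), F)


def plug_uam(network: SegNet, every_k_layers: int = 5,
             seed: int | None = None) -> SegNet:
    """Attach one attention site after every k-th convolution of the network.

    The number of sites is ``n_convs // k`` counting convolutions in
    forward order (classifier head included); each site owns independent
    weights.  The network's ``forward`` then requires an uncertainty
    block.  Returns the same network object, augmented.
    """
    if every_k_layers < 1:
        raise ValueError("every_k_layers must be >= 1")
    seed = network.config.seed + 1 if seed is None else seed
    rng = np.random.default_rng(seed)
    n_sites = network.n_convs // every_k_layers
    network.uam_sites = {s: UamParams(rng) for s in range(1, n_sites + 1)}
    # forward() applies sites at multiples of layers_per_unit
    if network.config.layers_per_unit != every_k_layers:
        network.config = type(network.config)(
            **{**network.config.__dict__, "layers_per_unit": every_k_layers})
    return network
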