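"""Parameterised layers and the module container for the numpy backend."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv3d

__all__ = ["Module", "Conv3dLayer"]


class Module:
    """Base class: recursively collects parameter Tensors."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            params.extend(_collect(value))
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint holds {len(arrays)} arrays, model has {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float32, copy=True)


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    if isinstance(value, dict):
        out = []
        for k in sorted(value):
            out.extend(_collect(value[k]))
        return out
    return []


class Conv3dLayer(Module):
    """Stride-1 cubic convolution with bias, He fan-in initialisation."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same-padding")
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = c_in * kernel**3
        std = float(np.sqrt(2.0 / fan_in))
        self.w = Tensor(rng.normal(0.0, std, size=(c_out, c_in, kernel, kernel, kernel)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.c_in = c_in
        self.c_out = c_out
        self.kernel = kernel
        self.padding = kernel // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, self.padding)
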