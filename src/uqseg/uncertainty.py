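"""Voxel-wise uncertainty maps from Monte-Carlo dropout sample stacks.

Given T softmax samples p_t(c) per voxel, four measures are computed:

* **aleatoric**          (1/T) sum_t sum_c p_t(c) (1 - p_t(c))
* **epistemic**          (1/T) sum_t sum_c (p_t(c) - pbar(c))^2
* **entropy**            -sum_c pbar(c) ln pbar(c)
* **mutual information**  entropy(pbar) - (1/T) sum_t entropy(p_t)

with pbar(c) the across-sample mean.  Aleatoric and entropy reflect data
noise (spread within samples); epistemic and mutual information reflect
model disagreement across samples and vanish when the T samples agree.

By default the t-sums carry a 1/T factor so values estimate the
corresponding expectations and are stable in T; ``normalize_by_t=False``
gives the plain sum over samples instead.  Natural logarithms are used
throughout, so entropy is bounded by ln C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .segnet import ProbabilitySampleStack

__all__ = ["UncertaintyMap", "UncertaintyBlock", "MEASURES",
           "aleatoric", "epistemic", "entropy", "mutual_information",
           "compute_all_measures", "build_uncertainty_block"]

MEASURES: tuple[str, ...] = ("aleatoric", "epistemic", "entropy",
                             "mutual_information")

_P_FLOOR = 1e-12  # probability clamp so p*ln(p) -> 0 at p = 0


@dataclass
class UncertaintyMap:
    values: np.ndarray  # (X, Y, Z) float32
    measure: str
    T_used: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("uncertainty map contains non-finite values")


@dataclass
class UncertaintyBlock:
    """4-channel stack (aleatoric, epistemic, entropy, mutual_information)."""

    values: np.ndarray  # (4, X, Y, Z) float32

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 4 or self.values.shape[0] != len(MEASURES):
            raise ValueError(f"expected (4, X, Y, Z), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("uncertainty block contains non-finite values")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:]


def _entropy_of(p: np.ndarray, class_axis: int) -> np.ndarray:
    pc = np.clip(p, _P_FLOOR, 1.0)
    return -(pc * np.log(pc)).sum(axis=class_axis)


def aleatoric(stack: ProbabilitySampleStack,
              normalize_by_t: bool = True) -> UncertaintyMap:
    """Expected within-sample spread sum_c p(1-p), averaged over the T samples."""
    p = stack.probs
    vals = (p * (1.0 - p)).sum(axis=1).sum(axis=0)
    if normalize_by_t:
        vals = vals / stack.T
    return UncertaintyMap(vals, "aleatoric", stack.T)


def epistemic(stack: ProbabilitySampleStack,
              normalize_by_t: bool = True) -> UncertaintyMap:
    """Across-sample variance of the class probabilities, summed over classes."""
    if stack.T < 2:
        warnings.warn("epistemic uncertainty needs T >= 2 samples; returning zeros",
                      stacklevel=2)
        return UncertaintyMap(np.zeros(stack.probs.shape[2:], dtype=np.float32),
                              "epistemic", stack.T)
    p = stack.probs
    pbar = p.mean(axis=0, keepdims=True)
    vals = ((p - pbar) ** 2).sum(axis=1).sum(axis=0)
    if normalize_by_t:
        vals = vals / stack.T
    return UncertaintyMap(vals, "epistemic", stack.T)


def entropy(stack: ProbabilitySampleStack) -> UncertaintyMap:
    """Entropy of the mean predictive distribution, in nats."""
    return UncertaintyMap(_entropy_of(stack.mean_probs(), 0), "entropy", stack.T)


def mutual_information(stack: ProbabilitySampleStack) -> UncertaintyMap:
    """Predictive entropy minus mean sample entropy (BALD), clamped at 0.

    Non-negative by Jensen's inequality up to float rounding; the clamp
    removes the rounding negatives only.
    """
    if stack.T < 2:
        warnings.warn("mutual information needs T >= 2 samples; returning zeros",
                      stacklevel=2)
        return UncertaintyMap(np.zeros(stack.probs.shape[2:], dtype=np.float32),
                              "mutual_information", stack.T)
    h_mean = _entropy_of(stack.mean_probs(), 0)
    mean_h = _entropy_of(stack.probs, 1).mean(axis=0)
    return UncertaintyMap(np.maximum(h_mean - mean_h, 0.0),
                          "mutual_information", stack.T)


def compute_all_measures(stack: ProbabilitySampleStack,
                         normalize_by_t: bool = True
                         ) -> dict[str, UncertaintyMap]:
    return {
        "aleatoric": aleatoric(stack, normalize_by_t),
        "epistemic": epistemic(stack, normalize_by_t),
        "entropy": entropy(stack),
        "mutual_information": mutual_information(stack),
    }


def _minmax_rescale(chan: np.ndarray) -> np.ndarray:
    lo, hi = float(chan.min()), float(chan.max())
    if hi - lo <= 0:
        return np.zeros_like(chan)  # constant channels carry no signal
    return (chan - lo) / (hi - lo)


def build_uncertainty_block(a: UncertaintyMap, e: UncertaintyMap,
                            h: UncertaintyMap, mi: UncertaintyMap,
                            rescale: bool = True) -> UncertaintyBlock:
    """Stack the four maps channel-wise in the fixed order (a, e, h, mi).

    With ``rescale`` (default) each channel is min–max mapped to [0, 1] so
    the attention module sees scale-free inputs; a constant channel maps
    to all-zero.
    """
    maps = {"aleatoric": a, "epistemic": e, "entropy": h,
            "mutual_information": mi}
    for name, m in maps.items():
        if m.measure != name:
            raise ValueError(f"expected measure {name!r} in position, got "
                             f"{m.measure!r}")
    shapes = {m.values.shape for m in maps.values()}
    if len(shapes) != 1:
        raise ValueError(f"maps disagree on spatial shape: {shapes}")
    ts = {m.T_used for m in maps.values()}
    if len(ts) != 1:
        raise ValueError(f"maps disagree on T_used: {ts}")
    chans = [maps[name].values for name in MEASURES]
    if rescale:
        chans = [_minmax_rescale(c) for c in chans]
    return UncertaintyBlock(np.stack(chans))


def block_from_stack(stack: ProbabilitySampleStack, rescale: bool = True,
                     normalize_by_t: bool = True) -> UncertaintyBlock:
    """Convenience: sample stack -> 4-channel uncertainty block."""
    m = compute_all_measures(stack, normalize_by_t)
    return build_uncertainty_block(m["aleatoric"], m["epistemic"],
                                   m["entropy"], m["mutual_information"],
                                   rescale=rescale)


def save_nifti(obj: UncertaintyMap | UncertaintyBlock, path,
               voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
               ) -> None:
    """Write a map (3-D) or block (4-D, channels-last on disk) as NIfTI."""
    import nibabel as nib

    vals = obj.values if isinstance(obj, (UncertaintyMap, UncertaintyBlock)) \
        else np.asarray(obj)
    if vals.ndim == 4:  # channel axis last for viewer compatibility
        vals = np.moveaxis(vals, 0, -1)
    affine = np.diag(list(voxel_spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(vals, dtype=np.float32), affine),
             str(path))
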