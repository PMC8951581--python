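"""3-D encoder–decoder segmentation network with Monte-Carlo dropout.

A generic residual-free U-style network: a stem convolution, ``depth``
encoder stages (2x average-pool then two 3x3x3 convolutions), a mirrored
decoder with skip concatenations, and a 1x1x1 classifier head emitting
C-class softmax maps.  A dropout layer follows every convolution; at
inference the dropout stays active and the input is forwarded T times,
yielding a stack of softmax samples that downstream modules turn into
voxel-wise uncertainty maps.

The architecture is deliberately configuration-driven (channel widths,
depth, dropout rate) rather than a fixed published topology, so any
encoder–decoder obeying the same contracts could be swapped in.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

from .io import CLASS_TO_CODE, MultimodalVolume
from .nn import Tensor, Conv3dLayer, Module
from .nn import autograd as ag

__all__ = ["SegNetConfig", "SegNet", "ProbabilitySampleStack",
           "SegmentationMap", "build_network", "mc_sample", "predict_labels"]


@dataclass(frozen=True)
class SegNetConfig:
    n_classes: int = 4
    in_channels: int = 4
    base_channels: int = 16
    depth: int = 2                 # number of down/up-sampling stages
    dropout_rate: float = 0.10     # fraction of activations dropped per layer
    layers_per_unit: int = 5       # conv layers per attention unit
    #: "instance" normalises per full input; statistics then differ between
    #: training crops and full-volume inference, so the default is "none"
    norm: str = "none"
    #: negative slope of the hidden-layer leaky ReLU (0 = plain ReLU)
    leaky_slope: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.layers_per_unit < 1:
            raise ValueError("layers_per_unit must be >= 1")
        if self.norm not in ("instance", "none"):
            raise ValueError("norm must be 'instance' or 'none'")


@dataclass
class ProbabilitySampleStack:
    """T softmax sample maps, shape (T, C, X, Y, Z)."""

    probs: np.ndarray
    case_id: str = ""

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.ndim != 5:
            raise ValueError(f"expected (T, C, X, Y, Z), got {self.probs.shape}")
        if self.probs.min() < -1e-6 or self.probs.max() > 1 + 1e-6:
            raise ValueError("probabilities outside [0, 1]")
        sums = self.probs.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-4:
            raise ValueError("per-voxel class probabilities do not sum to 1")

    @property
    def T(self) -> int:
        return self.probs.shape[0]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]

    def mean_probs(self) -> np.ndarray:
        """Across-sample mean predictive distribution, shape (C, X, Y, Z)."""
        return self.probs.mean(axis=0)

    def save(self, path) -> None:
        np.savez_compressed(str(path), probs=self.probs,
                            case_id=np.array(self.case_id))

    @classmethod
    def load(cls, path) -> "ProbabilitySampleStack":
        with np.load(str(path)) as z:
            return cls(z["probs"], case_id=str(z["case_id"]))


@dataclass
class SegmentationMap:
    labels: np.ndarray  # int16 in {0,1,2,4}
    source: str = "baseline"  # "baseline" or "proposed"


class SegNet(Module):
    """Encoder–decoder with dropout after every convolution.

    ``forward`` optionally applies an uncertainty attention module after
    every ``layers_per_unit``-th convolution when attention sites have
    been attached (see :func:`uqseg.uam.plug_uam`).
    """

    def __init__(self, config: SegNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        b = config.base_channels
        self.stem = Conv3dLayer(config.in_channels, b, 3, rng)
        self.enc: list[list[Conv3dLayer]] = []
        ch = b
        for _ in range(config.depth):
            self.enc.append([Conv3dLayer(ch, ch * 2, 3, rng),
                             Conv3dLayer(ch * 2, ch * 2, 3, rng)])
            ch *= 2
        self.dec: list[list[Conv3dLayer]] = []
        for _ in range(config.depth):
            skip = ch // 2
            self.dec.append([Conv3dLayer(ch + skip, skip, 3, rng),
                             Conv3dLayer(skip, skip, 3, rng)])
            ch = skip
        self.head = Conv3dLayer(ch, config.n_classes, 1, rng)
        # attention sites attached by uam.plug_uam: {site_index: module}
        self.uam_sites: dict[int, Module] = {}

    # -- structure ---------------------------------------------------------

    @property
    def n_convs(self) -> int:
        """Total convolution layers in forward order, classifier included."""
        return 1 + 4 * self.config.depth + 1

    def conv_layout(self, spatial: tuple[int, int, int]):
        """(layer, c_in, c_out, kernel, out_spatial) for every convolution.

        Used for closed-form FLOP accounting; attention-site convolutions
        are listed at the resolution of their insertion point.
        """
        k = self.config.layers_per_unit
        layout = []
        idx = 0

        def emit(conv: Conv3dLayer, sp):
            nonlocal idx
            idx += 1
            layout.append((conv, conv.c_in, conv.c_out, conv.kernel, tuple(sp)))
            site = idx // k
            if idx % k == 0 and site in self.uam_sites:
                for sub in self.uam_sites[site].conv_layers():
                    layout.append((sub, sub.c_in, sub.c_out, sub.kernel, tuple(sp)))

        sp = np.array(spatial)
        emit(self.stem, sp)
        for stage in self.enc:
            sp = sp // 2
            for conv in stage:
                emit(conv, sp)
        for stage in self.dec:
            sp = sp * 2
            for conv in stage:
                emit(conv, sp)
        emit(self.head, sp)
        return layout

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray | Tensor, *, rng: np.random.Generator | None = None,
                dropout_active: bool = False, ublock: np.ndarray | None = None,
                return_tensor: bool = False):
        """One forward pass producing (N, C, X, Y, Z) softmax probabilities.

        When ``dropout_active`` every convolution output is passed through
        inverted dropout with fresh masks drawn from ``rng``; this is both
        the training path and the MC-sampling path.  ``ublock`` feeds the
        attached attention sites (required iff sites exist).
        """
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        if x.data.ndim != 5:
            raise ValueError(f"expected (N, C, X, Y, Z) input, got {x.shape}")
        spatial = np.array(x.shape[2:])
        div = 2 ** self.config.depth
        if np.any(spatial % div):
            need = tuple(int((div - s % div) % div) for s in spatial)
            raise ValueError(
                f"spatial dims {tuple(spatial)} not divisible by {div}; "
                f"pad by {need} voxels")
        rate = self.config.dropout_rate if dropout_active else 0.0
        if rate > 0 and rng is None:
            raise ValueError("dropout_active requires an rng")
        if self.uam_sites and ublock is None:
            raise ValueError("network has attention sites; an uncertainty "
                             "block must be supplied")

        from .uam import apply_uam  # deferred: uam imports this module's types

        conv_idx = 0
        k = self.config.layers_per_unit

        def unit(conv: Conv3dLayer, h: Tensor, activate: bool) -> Tensor:
            # hidden convs: conv -> norm -> relu -> dropout; the classifier
            # head (activate=False) emits raw, undropped logits
            nonlocal conv_idx
            h = conv(h)
            if activate:
                if self.config.norm == "instance":
                    h = ag.instance_norm(h)
                h = (ag.leaky_relu(h, self.config.leaky_slope)
                     if self.config.leaky_slope > 0 else ag.relu(h))
                h = ag.dropout(h, rate, rng)
            conv_idx += 1
            site = conv_idx // k
            if conv_idx % k == 0 and site in self.uam_sites:
                h = apply_uam(h, ublock, self.uam_sites[site])
            return h

        h = unit(self.stem, x, True)
        skips = []
        for stage in self.enc:
            skips.append(h)
            h = ag.avg_pool2(h)
            for conv in stage:
                h = unit(conv, h, True)
        for stage in self.dec:
            h = ag.upsample2(h)
            h = ag.concat_channels([skips.pop(), h])
            for conv in stage:
                h = unit(conv, h, True)
        logits = unit(self.head, h, False)
        probs = ag.softmax_channels(logits)
        return probs if return_tensor else probs.data

    def weight_checksum(self) -> str:
        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()


def build_network(config: SegNetConfig) -> SegNet:
    """Build an encoder–decoder; identical (config, seed) gives identical weights."""
    return SegNet(config)


def mc_sample(network: SegNet, volume: MultimodalVolume | np.ndarray,
              T: int, seed: int) -> ProbabilitySampleStack:
    """Draw T stochastic forward passes with dropout active.

    Each pass uses independent dropout masks; with ``dropout_rate == 0``
    the T sample maps are identical.  The whole stack is a pure function
    of (weights, volume, T, seed).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    data = volume.data if isinstance(volume, MultimodalVolume) else np.asarray(volume)
    case_id = volume.case_id if isinstance(volume, MultimodalVolume) else ""
    rng = np.random.default_rng(seed)
    samples = [network.forward(data[None], rng=rng, dropout_active=True)[0]
               for _ in range(T)]
    return ProbabilitySampleStack(np.stack(samples), case_id=case_id)


def predict_labels(stack: ProbabilitySampleStack,
                   source: str = "baseline") -> SegmentationMap:
    """Argmax of the across-sample mean probability, mapped to label codes.

    Ties break toward the lower class index (argmax convention), i.e.
    toward background among equally probable classes.
    """
    mean = stack.mean_probs()
    idx = mean.argmax(axis=0)
    return SegmentationMap(labels=CLASS_TO_CODE[idx], source=source)


def config_to_json(config: SegNetConfig) -> str:
    return json.dumps(asdict(config), sort_keys=True)


def config_from_json(s: str) -> SegNetConfig:
    return SegNetConfig(**json.loads(s))
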