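"""Two-stage Dice-loss training.

Stage 1 trains the baseline encoder–decoder with dropout active.  Stage 2
freezes it, draws T Monte-Carlo samples per training volume, converts
them into 4-channel uncertainty blocks, and trains a second network with
uncertainty attention sites that consume those (precomputed, full-volume)
blocks — every spatial augmentation applied to an image crop is applied
in lockstep to its label and uncertainty-block crops.

Loss: soft Dice, one-vs-rest over the three foreground classes,
1 - (2*sum(p g) + eps) / (sum(p^2) + sum(g^2) + eps) per class with
eps = 1e-5, averaged without class weights.  Optimiser: Adam with
coefficients (0.5, 0.999), L2 weight decay 1e-5, constant learning rate
1e-3, batch size 8 — at full study scale with 96^3 crops and 200 epochs;
the defaults here are those values and desk-scale runs override crop
size and epoch count only.

Augmentation per sample: random crop; independent per-axis flips at
p = 0.5; one rotation uniform in +-10 degrees about a random principal
axis (linear interpolation for image and uncertainty block, nearest
neighbour for labels); per-channel intensity shift uniform in +-0.1 and
scale uniform in [0.9, 1.1] applied to the image only.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import one_hot_labels, LabelMap
from .nn import Adam, Tensor
from .nn.autograd import dice_loss_op
from .phantoms import PhantomCase
from .segnet import (SegNet, SegNetConfig, build_network, mc_sample,
                     config_from_json, config_to_json)
from .uam import plug_uam
from .uncertainty import block_from_stack

__all__ = ["TrainConfig", "AugmentedSample", "Checkpoint", "dice_loss",
           "augment", "train_baseline", "precompute_ublocks",
           "train_proposed", "save_checkpoint", "load_checkpoint"]

DICE_EPS = 1e-5


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 8
    initial_lr: float = 1e-3
    adam_betas: tuple[float, float] = (0.5, 0.999)
    weight_decay: float = 1e-5
    crop_size: tuple[int, int, int] = (96, 96, 96)
    flip_prob: float = 0.5
    rotation_range_deg: float = 10.0
    intensity_shift_range: float = 0.1
    scale_range: tuple[float, float] = (0.9, 1.1)
    T: int = 7
    dropout_rate: float = 0.1
    #: linear learning-rate warmup over this many initial epochs (0 = off)
    warmup_epochs: int = 0
    #: clip gradients to this global L2 norm before each step (0 = off)
    grad_clip_norm: float = 0.0
    #: random-restart rule: a run is deemed non-converged when the
    #: final-epoch training loss stays above ``restart_loss_threshold``,
    #: or when a class floods — its predicted soft mass exceeds
    #: ``restart_flood_factor`` times its target mass (a collapse mode in
    #: which one minority class covers the background while the mean loss
    #: looks fine).  Judged on training statistics only; a class that is
    #: merely under-predicted does not trigger a restart.  0 disables.
    restart_loss_threshold: float = 0.0
    restart_flood_factor: float = 10.0
    max_restarts: int = 2
    #: probability that a training crop is forced to contain tumor voxels.
    #: 0 reproduces plain uniform random cropping; small grids with small
    #: lesions need a positive value for the minority classes to be seen
    #: at all (a large crop of a large brain contains the lesion anyway).
    tumor_crop_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if any(c < 1 for c in self.crop_size):
            raise ValueError("crop_size entries must be positive")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must lie in [0, 1]")


@dataclass
class AugmentedSample:
    image: np.ndarray                 # (4, cx, cy, cz)
    labels: np.ndarray                # (cx, cy, cz) int16
    ublock: np.ndarray | None         # (4, cx, cy, cz) or None (stage 1)
    transform: dict = field(default_factory=dict)


@dataclass
class Checkpoint:
    network: SegNet
    net_config: SegNetConfig
    train_config: TrainConfig
    history: list[dict] = field(default_factory=list)
    stage: str = "baseline"  # "baseline" or "proposed"
    restarts_used: int = 0

    def weight_hash(self) -> str:
        return self.network.weight_checksum()


# ---------------------------------------------------------------------------
# loss


def dice_loss(pred_probs: np.ndarray, target: LabelMap | np.ndarray,
              eps: float = DICE_EPS) -> float:
    """Soft multi-class Dice loss of a (C, ...) or (N, C, ...) prediction.

    The target label volume is one-hot encoded; the loss is the mean of
    the per-foreground-class terms 1 - (2*sum(pg)+eps)/(sum(p^2)+sum(g^2)+eps).
    """
    p = np.asarray(pred_probs, dtype=np.float64)
    tdata = target.data if isinstance(target, LabelMap) else np.asarray(target)
    if p.ndim == tdata.ndim + 1:
        p = p[None]
        tdata = tdata[None]
    g = np.stack([one_hot_labels(t, p.shape[1]) for t in tdata]).astype(np.float64)
    if p.shape != g.shape:
        raise ValueError(f"prediction {p.shape} does not match one-hot "
                         f"target {g.shape}")
    terms = []
    for c in range(1, p.shape[1]):  # foreground classes only
        num = 2.0 * (p[:, c] * g[:, c]).sum() + eps
        den = (p[:, c] ** 2).sum() + (g[:, c] ** 2).sum() + eps
        terms.append(1.0 - num / den)
    return float(np.mean(terms))


# ---------------------------------------------------------------------------
# augmentation


def _random_crop_origin(shape, crop, rng, labels=None,
                        tumor_prob: float = 0.0) -> tuple[int, ...]:
    for s, c in zip(shape, crop):
        if c > s:
            raise ValueError(f"crop {tuple(crop)} larger than volume {tuple(shape)}")
    if labels is not None and tumor_prob > 0 and rng.random() < tumor_prob:
        fg = np.argwhere(labels > 0)
        if len(fg):
            v = fg[rng.integers(len(fg))]
            return tuple(
                int(rng.integers(max(0, x - c + 1), min(s - c, x) + 1))
                for x, s, c in zip(v, shape, crop))
    return tuple(int(rng.integers(0, s - c + 1)) for s, c in zip(shape, crop))


def augment(image: np.ndarray, labels: np.ndarray,
            ublock: np.ndarray | None, config: TrainConfig,
            rng: np.random.Generator | int) -> AugmentedSample:
    """One augmented training sample; deterministic given the rng state.

    Spatial operations (crop, flips, rotation) are applied identically to
    image, labels and uncertainty block; intensity shift/scale touch the
    image channels only.  Labels are resampled with nearest neighbour so
    no interpolated codes appear.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    record: dict = {}
    crop = config.crop_size
    origin = _random_crop_origin(labels.shape, crop, rng, labels,
                                 config.tumor_crop_prob)
    record["crop_origin"] = origin
    sl = tuple(slice(o, o + c) for o, c in zip(origin, crop))
    img = np.array(image[(slice(None),) + sl], dtype=np.float32)
    lab = np.array(labels[sl])
    ub = None if ublock is None else np.array(ublock[(slice(None),) + sl],
                                              dtype=np.float32)

    flips = [bool(rng.random() < config.flip_prob) for _ in range(3)]
    record["flips"] = flips
    for ax, f in enumerate(flips):
        if f:
            img = np.flip(img, axis=ax + 1)
            lab = np.flip(lab, axis=ax)
            if ub is not None:
                ub = np.flip(ub, axis=ax + 1)

    if config.rotation_range_deg > 0:
        angle = float(rng.uniform(-config.rotation_range_deg,
                                  config.rotation_range_deg))
        plane = [(0, 1), (0, 2), (1, 2)][int(rng.integers(3))]
        record["rotation"] = {"angle_deg": angle, "plane": plane}
        img = np.stack([ndimage.rotate(ch, angle, axes=plane, reshape=False,
                                       order=1, mode="nearest") for ch in img])
        lab = ndimage.rotate(lab, angle, axes=plane, reshape=False,
                             order=0, mode="nearest")
        if ub is not None:
            ub = np.stack([ndimage.rotate(ch, angle, axes=plane, reshape=False,
                                          order=1, mode="nearest") for ch in ub])

    if config.intensity_shift_range > 0:
        shifts = rng.uniform(-config.intensity_shift_range,
                             config.intensity_shift_range, size=img.shape[0])
        record["intensity_shift"] = shifts.tolist()
        img = img + shifts[:, None, None, None].astype(np.float32)
    lo, hi = config.scale_range
    if hi > lo:
        scales = rng.uniform(lo, hi, size=img.shape[0])
        record["intensity_scale"] = scales.tolist()
        img = img * scales[:, None, None, None].astype(np.float32)

    return AugmentedSample(image=np.ascontiguousarray(img, dtype=np.float32),
                           labels=np.ascontiguousarray(lab).astype(np.int16),
                           ublock=None if ub is None
                           else np.ascontiguousarray(ub, dtype=np.float32),
                           transform=record)


# ---------------------------------------------------------------------------
# training loops


def _case_arrays(case) -> tuple[np.ndarray, np.ndarray, str]:
    if isinstance(case, PhantomCase):
        return case.image.data, case.labels.data, case.case_id
    vol, lab = case
    return vol.data, lab.data, vol.case_id


def _per_class_stats(probs: np.ndarray, onehot: np.ndarray,
                     eps: float = DICE_EPS):
    """(Dice term, predicted mass, true mass) per foreground class, no grad."""
    terms, pred_mass, true_mass = [], [], []
    for c in range(1, probs.shape[1]):
        pm = float((probs[:, c] ** 2).sum())
        tm = float((onehot[:, c] ** 2).sum())
        num = 2.0 * float((probs[:, c] * onehot[:, c]).sum()) + eps
        terms.append(1.0 - num / (pm + tm + eps))
        pred_mass.append(pm)
        true_mass.append(tm)
    return terms, pred_mass, true_mass


def _clip_global_norm(params, max_norm: float) -> None:
    total = np.sqrt(sum(float((p.grad**2).sum())
                        for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def _flooded(entry: dict, factor: float) -> bool:
    return any(pm > factor * tm + 1.0
               for pm, tm in zip(entry["class_pred_mass"],
                                 entry["class_true_mass"]))


def _train(cohort: Sequence, net: SegNet, config: TrainConfig,
           ublocks: dict[str, np.ndarray] | None, stage: str,
           net_config: SegNetConfig, abort_on_flood: bool = False) -> Checkpoint:
    rng = np.random.default_rng(config.seed)
    params = net.parameters()
    opt = Adam(params, lr=config.initial_lr, betas=config.adam_betas,
               weight_decay=config.weight_decay)
    ckpt = Checkpoint(network=net, net_config=net_config,
                      train_config=config, stage=stage)
    arrays = [_case_arrays(c) for c in cohort]
    if ublocks is not None:
        missing = [cid for _, _, cid in arrays if cid not in ublocks]
        if missing:
            raise ValueError(f"missing uncertainty block(s) for case(s) {missing}")

    for epoch in range(config.epochs):
        t0 = time.time()
        if config.warmup_epochs > 0:
            warm = min(1.0, (epoch + 1) / config.warmup_epochs)
            opt.lr = config.initial_lr * warm
        order = rng.permutation(len(arrays))
        losses = []
        class_terms = []
        for start in range(0, len(order), config.batch_size):
            batch_idx = order[start:start + config.batch_size]
            samples = []
            for i in batch_idx:
                img, lab, cid = arrays[i]
                ub = None if ublocks is None else ublocks[cid]
                samples.append(augment(img, lab, ub, config, rng))
            x = np.stack([s.image for s in samples])
            g = np.stack([one_hot_labels(s.labels, net_config.n_classes)
                          for s in samples])
            ub_batch = (None if ublocks is None
                        else np.stack([s.ublock for s in samples]))
            probs = net.forward(Tensor(x), rng=rng, dropout_active=True,
                                ublock=ub_batch, return_tensor=True)
            loss = dice_loss_op(probs, g, eps=DICE_EPS)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            if config.grad_clip_norm > 0:
                _clip_global_norm(params, config.grad_clip_norm)
            opt.step()
            losses.append(float(loss.data))
            class_terms.append(_per_class_stats(probs.data, g))
        terms, pred_mass, true_mass = (np.mean([c[i] for c in class_terms],
                                               axis=0).tolist()
                                       for i in range(3))
        ckpt.history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                             "class_terms": terms,
                             "class_pred_mass": pred_mass,
                             "class_true_mass": true_mass,
                             "lr": opt.lr,
                             "wall_time_s": time.time() - t0})
        # a class flooding the background is unrecoverable at this scale;
        # stop wasting epochs so the restart logic can try a fresh init
        if (abort_on_flood and epoch >= max(4, config.epochs // 3)
                and _flooded(ckpt.history[-1], config.restart_flood_factor)):
            break
    return ckpt


def _train_with_restarts(cohort, config: TrainConfig, ublocks,
                         stage: str, net_config: SegNetConfig,
                         every_k_layers: int | None = None) -> Checkpoint:
    """Train, restarting from a fresh init if the run did not converge.

    Convergence is judged on the final-epoch *training* loss alone; each
    restart offsets the weight-init seed (the data, augmentation stream
    and optimiser settings are unchanged).
    """
    attempts = config.max_restarts + 1 if config.restart_loss_threshold else 1
    ckpt = None
    for attempt in range(attempts):
        cfg_a = SegNetConfig(**{**asdict(net_config),
                                "seed": net_config.seed + 1000 * attempt})
        net = build_network(cfg_a)
        if stage == "proposed":
            plug_uam(net, every_k_layers or cfg_a.layers_per_unit)
        is_last = attempt == attempts - 1
        ckpt = _train(cohort, net, config, ublocks, stage, cfg_a,
                      abort_on_flood=bool(config.restart_loss_threshold)
                      and not is_last)
        ckpt.restarts_used = attempt
        if not config.restart_loss_threshold or not ckpt.history:
            break
        last = ckpt.history[-1]
        if (last["loss"] <= config.restart_loss_threshold
                and not _flooded(last, config.restart_flood_factor)):
            break
    return ckpt


def train_baseline(cohort: Sequence, net_config: SegNetConfig,
                   config: TrainConfig) -> Checkpoint:
    """Stage 1: train the MC-dropout baseline with Dice loss."""
    if len(cohort) < 1:
        raise ValueError("need at least one training case")
    net_config = SegNetConfig(**{**asdict(net_config),
                                 "dropout_rate": config.dropout_rate})
    return _train_with_restarts(cohort, config, None, "baseline", net_config)


def precompute_ublocks(checkpoint: Checkpoint, cohort: Sequence, T: int,
                       seed: int, cache_dir: Path | str | None = None
                       ) -> dict[str, np.ndarray]:
    """Full-volume uncertainty blocks per case from a frozen stage-1 model.

    Deterministic given (checkpoint weights, case, T, seed); when
    ``cache_dir`` is set, blocks are cached to disk keyed by the weight
    hash so reruns are bit-identical cache hits.
    """
    whash = checkpoint.weight_hash()[:16]
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    blocks: dict[str, np.ndarray] = {}
    for case in cohort:
        img, _, cid = _case_arrays(case)
        key = f"{whash}_{cid}_T{T}_s{seed}"
        if cache is not None:
            f = cache / f"ublock_{key}.npz"
            if f.exists():
                blocks[cid] = np.load(f)["ublock"]
                continue
        cid_key = int(hashlib.sha256(cid.encode()).hexdigest()[:8], 16)
        case_seed = int(np.random.SeedSequence(
            [seed, cid_key]).generate_state(1)[0] % 2**31)
        stack = mc_sample(checkpoint.network, img, T, case_seed)
        blocks[cid] = block_from_stack(stack).values
        if cache is not None:
            np.savez_compressed(cache / f"ublock_{key}.npz", ublock=blocks[cid])
    return blocks


def train_proposed(cohort: Sequence, ublocks: dict[str, np.ndarray],
                   net_config: SegNetConfig, config: TrainConfig,
                   every_k_layers: int | None = None) -> Checkpoint:
    """Stage 2: train the attention-augmented network on images + ublocks."""
    if len(cohort) < 1:
        raise ValueError("need at least one training case")
    net_config = SegNetConfig(**{**asdict(net_config),
                                 "dropout_rate": config.dropout_rate})
    if not all((_case_arrays(c)[2] in ublocks) for c in cohort):
        missing = [cid for _, _, cid in map(_case_arrays, cohort)
                   if cid not in ublocks]
        raise ValueError(f"missing uncertainty block(s) for case(s) {missing}")
    return _train_with_restarts(cohort, config, ublocks, "proposed",
                                net_config, every_k_layers)


# ---------------------------------------------------------------------------
# checkpoint serialization


def save_checkpoint(ckpt: Checkpoint, path: Path | str) -> None:
    """One-file checkpoint: weights plus embedded configs and history."""
    from . import __version__

    meta = {
        "version": __version__,
        "net_config": json.loads(config_to_json(ckpt.net_config)),
        "train_config": asdict(ckpt.train_config),
        "history": ckpt.history,
        "stage": ckpt.stage,
        "n_uam_sites": len(ckpt.network.uam_sites),
        "weight_hash": ckpt.weight_hash(),
    }
    arrays = {f"w{i:04d}": a for i, a in enumerate(ckpt.network.state_arrays())}
    np.savez_compressed(str(path), meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: Path | str) -> Checkpoint:
    with np.load(str(path)) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        arrays = [z[k] for k in sorted(k for k in z.files if k.startswith("w"))]
    net_config = config_from_json(json.dumps(meta["net_config"]))
    tc = dict(meta["train_config"])
    tc["adam_betas"] = tuple(tc["adam_betas"])
    tc["crop_size"] = tuple(tc["crop_size"])
    tc["scale_range"] = tuple(tc["scale_range"])
    train_config = TrainConfig(**tc)
    net = build_network(net_config)
    if meta["n_uam_sites"]:
        plug_uam(net, net_config.layers_per_unit)
    net.load_state_arrays(arrays)
    ckpt = Checkpoint(network=net, net_config=net_config,
                      train_config=train_config, history=meta["history"],
                      stage=meta["stage"])
    if ckpt.weight_hash() != meta["weight_hash"]:
        raise ValueError("checkpoint weight hash mismatch after load")
    return ckpt
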