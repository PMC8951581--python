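"""Region Dice scoring, error–uncertainty diagnostics and model cost accounting.

Dice is computed on the three nested binary regions (ET, TC, WT) as
2|P∩G| / (|P| + |G|); both masks empty scores 1.0 (correctly predicting
absence), exactly one empty scores 0.0.  The error–uncertainty score is
the ROC AUC of a voxel-wise uncertainty map as a ranker of misprediction
(pred != truth): 0.5 means the map carries no information about where the
model errs, 1.0 means perfect separation.  Cost accounting reports exact
parameter counts and convolution FLOPs (2 x multiply-accumulates) at a
given input shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io import LabelMap, Region, region_mask
from .segnet import SegmentationMap, SegNet, mc_sample, predict_labels
from .training import Checkpoint, _case_arrays
from .uncertainty import UncertaintyMap, compute_all_measures

__all__ = ["EvalReport", "dice_score", "error_uncertainty_score",
           "count_costs", "evaluate_model", "sliding_window_probs"]


@dataclass
class EvalReport:
    model_tag: str
    per_case: dict[str, dict[str, float]] = field(default_factory=dict)
    mean_dice: dict[str, float] = field(default_factory=dict)
    error_auc: dict[str, float] = field(default_factory=dict)  # per measure
    params_m: float = 0.0
    flops_g: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.per_case, orient="index")

    def to_dict(self) -> dict:
        return {"model_tag": self.model_tag, "per_case": self.per_case,
                "mean_dice": self.mean_dice, "error_auc": self.error_auc,
                "params_m": self.params_m, "flops_g": self.flops_g}


def _labels_of(x) -> np.ndarray:
    if isinstance(x, SegmentationMap):
        return x.labels
    if isinstance(x, LabelMap):
        return x.data
    return np.asarray(x)


def dice_score(pred, truth, region: Region) -> float:
    """Dice overlap of a prediction and ground truth on one region."""
    p = _labels_of(pred)
    g = _labels_of(truth)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    pm = region_mask(p, region)
    gm = region_mask(g, region)
    np_, ng = int(pm.sum()), int(gm.sum())
    if np_ == 0 and ng == 0:
        return 1.0
    inter = int((pm & gm).sum())
    return 2.0 * inter / (np_ + ng)


def error_uncertainty_score(pred, truth, um: UncertaintyMap | np.ndarray
                            ) -> float:
    """ROC AUC of the uncertainty value as a ranker of voxel misprediction.

    Returns NaN (flagged sentinel) when the AUC is undefined, i.e. when
    every voxel is correct or every voxel is wrong.
    """
    p = _labels_of(pred)
    g = _labels_of(truth)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    u = um.values if isinstance(um, UncertaintyMap) else np.asarray(um)
    if u.shape != p.shape:
        raise ValueError(f"uncertainty map shape {u.shape} != {p.shape}")
    errors = (p != g).ravel().astype(int)
    if errors.min() == errors.max():
        return float("nan")
    return float(roc_auc_score(errors, u.ravel().astype(np.float64)))


def count_costs(network: SegNet, input_spatial: Sequence[int] = (96, 96, 96)
                ) -> tuple[float, float]:
    """(params in millions, conv FLOPs in billions) at the given input shape.

    FLOPs count 2 operations per multiply-accumulate of every convolution
    (attention-site convolutions included at their insertion resolution);
    the parameter count is the exact sum over learnable tensors.
    """
    params = network.n_parameters()
    flops = 0
    for _, c_in, c_out, k, sp in network.conv_layout(tuple(input_spatial)):
        flops += 2 * (k**3) * c_in * c_out * int(np.prod(sp))
    return params / 1e6, flops / 1e9


def sliding_window_probs(network: SegNet, image: np.ndarray, T: int,
                         seed: int, window: tuple[int, int, int] | None = None,
                         overlap: float = 0.5,
                         ublock: np.ndarray | None = None) -> np.ndarray:
    """Mean MC-sample class probabilities over the full volume.

    When ``window`` is unset or covers the volume a single full-volume
    pass per sample is used; otherwise overlapping windows (default 50%)
    are inferred independently and their probabilities mean-blended.
    """
    spatial = image.shape[1:]
    if window is None or all(w >= s for w, s in zip(window, spatial)):
        stack = mc_sample_with_ublock(network, image, T, seed, ublock)
        return stack.mean(axis=0)
    step = [max(1, int(w * (1 - overlap))) for w in window]
    acc = np.zeros((network.config.n_classes,) + spatial, dtype=np.float64)
    cnt = np.zeros(spatial, dtype=np.float64)
    starts = [sorted({min(o, s - w) for o in range(0, s, st)})
              for s, w, st in zip(spatial, window, step)]
    for ox in starts[0]:
        for oy in starts[1]:
            for oz in starts[2]:
                sl = (slice(ox, ox + window[0]), slice(oy, oy + window[1]),
                      slice(oz, oz + window[2]))
                sub_u = None if ublock is None else ublock[(slice(None),) + sl]
                sub = mc_sample_with_ublock(
                    network, image[(slice(None),) + sl], T,
                    seed + ox * 73856093 + oy * 19349663 + oz * 83492791, sub_u)
                acc[(slice(None),) + sl] += sub.mean(axis=0)
                cnt[sl] += 1.0
    return (acc / cnt[None]).astype(np.float32)


def mc_sample_with_ublock(network: SegNet, image: np.ndarray, T: int,
                          seed: int, ublock: np.ndarray | None) -> np.ndarray:
    """T stochastic passes returning the raw (T, C, ...) probability array."""
    if not network.uam_sites:
        return mc_sample(network, image, T, seed).probs
    rng = np.random.default_rng(seed)
    return np.stack([network.forward(image[None], rng=rng, dropout_active=True,
                                     ublock=ublock)[0] for _ in range(T)])


def evaluate_model(checkpoint: Checkpoint, cohort: Sequence,
                   ublocks: dict[str, np.ndarray] | None = None,
                   T: int | None = None, seed: int = 0,
                   input_spatial: Sequence[int] | None = None) -> EvalReport:
    """Full-volume evaluation: per-case and mean region Dice + error AUCs.

    A proposed-model checkpoint requires ``ublocks`` (from the frozen
    stage-1 baseline; ground truth plays no part in them).  Error AUCs
    are computed from the evaluated model's own sample stacks, averaged
    over cases where they are defined.
    """
    net = checkpoint.network
    if net.uam_sites and ublocks is None:
        raise ValueError("proposed-model evaluation requires uncertainty blocks")
    T = T if T is not None else checkpoint.train_config.T
    report = EvalReport(model_tag=checkpoint.stage)
    auc_lists: dict[str, list[float]] = {}
    first_spatial = None
    for case in cohort:
        img, lab, cid = _case_arrays(case)
        first_spatial = first_spatial or img.shape[1:]
        ub = None if ublocks is None else ublocks[cid]
        probs = mc_sample_with_ublock(net, img, T, seed, ub)
        from .segnet import ProbabilitySampleStack
        stack = ProbabilitySampleStack(probs, case_id=cid)
        pred = predict_labels(stack, source=checkpoint.stage)
        row = {f"dice_{r.value}": dice_score(pred, lab, r) for r in Region}
        for name, um in compute_all_measures(stack).items():
            auc = error_uncertainty_score(pred, lab, um)
            row[f"auc_{name}"] = auc
            if np.isfinite(auc):
                auc_lists.setdefault(name, []).append(auc)
        report.per_case[cid] = row
    for r in Region:
        vals = [row[f"dice_{r.value}"] for row in report.per_case.values()]
        report.mean_dice[r.value] = float(np.mean(vals))
    report.error_auc = {k: float(np.mean(v)) for k, v in auc_lists.items()}
    report.params_m, report.flops_g = count_costs(
        net, input_spatial or first_spatial or (96, 96, 96))
    return report
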