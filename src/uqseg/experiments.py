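"""Desk-scale end-to-end experiment: baseline vs. attention-augmented model.

Runs the full two-stage protocol on a synthetic phantom cohort at a size
a single CPU handles in minutes: generate a cohort, train the
MC-dropout baseline, compute full-volume uncertainty blocks with the
frozen baseline, train the attention-augmented network on images plus
blocks, and evaluate both on the held-out cases (region Dice and
voxel-wise error–uncertainty AUCs).

Default problem size: 40 training / 10 test phantoms on 64^3 grids, a
4-channel-base depth-2 network, 24^3 training crops, 15 epochs, T = 7
Monte-Carlo samples, 10% dropout.  These are the package's desk-scale
study conditions; the augmentation and optimiser settings are the
full-scale defaults of :class:`uqseg.training.TrainConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import EvalReport, evaluate_model
from .io import zscore_normalize
from .phantoms import PhantomSpec, generate_cohort
from .segnet import SegNetConfig
from .training import (Checkpoint, TrainConfig, precompute_ublocks,
                       train_baseline, train_proposed)
from .uam import uam_param_count

__all__ = ["DeskScaleResult", "desk_scale_experiment", "replicate_summary"]

DESK_NET = dict(base_channels=4, depth=2)
DESK_TRAIN = dict(epochs=30, batch_size=8, crop_size=(24, 24, 24),
                  tumor_crop_prob=0.5, restart_loss_threshold=0.65)


@dataclass
class DeskScaleResult:
    seed: int
    baseline: EvalReport
    proposed: EvalReport
    baseline_ckpt: Checkpoint
    proposed_ckpt: Checkpoint
    n_train: int
    n_test: int

    def dice_delta(self, region: str = "ET") -> float:
        return self.proposed.mean_dice[region] - self.baseline.mean_dice[region]

    def uam_param_overhead(self) -> dict[str, float]:
        base = self.baseline_ckpt.network.n_parameters()
        prop = self.proposed_ckpt.network.n_parameters()
        n_sites = len(self.proposed_ckpt.network.uam_sites)
        return {
            "baseline_params": float(base),
            "proposed_params": float(prop),
            "added_params": float(prop - base),
            "closed_form_added": float(n_sites * uam_param_count()),
            "overhead_pct": 100.0 * (prop - base) / base,
        }


def desk_scale_experiment(seed: int, n_train: int = 40, n_test: int = 10,
                          epochs: int | None = None,
                          spec: PhantomSpec | None = None,
                          verbose: bool = False) -> DeskScaleResult:
    """One replicate of the two-stage study on a fresh phantom cohort."""
    seed = int(seed) % (2**31)
    spec = spec if spec is not None else PhantomSpec()
    cohort = generate_cohort(spec, n_train + n_test, seed)
    for case in cohort:  # standard per-channel z-scoring, full volume
        case.image.data = zscore_normalize(case.image.data)
    train_cases, test_cases = cohort[:n_train], cohort[n_train:]

    net_cfg = SegNetConfig(seed=seed, **DESK_NET)
    train_kwargs = dict(DESK_TRAIN)
    if epochs is not None:
        train_kwargs["epochs"] = epochs
    tcfg = TrainConfig(seed=seed, **train_kwargs)

    if verbose:
        print(f"[seed {seed}] training baseline ({n_train} cases, "
              f"{tcfg.epochs} epochs)")
    ck_base = train_baseline(train_cases, net_cfg, tcfg)
    rep_base = evaluate_model(ck_base, test_cases, T=tcfg.T, seed=seed + 101)

    if verbose:
        print(f"[seed {seed}] precomputing uncertainty blocks "
              f"({len(cohort)} cases, T={tcfg.T})")
    ublocks = precompute_ublocks(ck_base, cohort, T=tcfg.T, seed=seed + 202)

    if verbose:
        print(f"[seed {seed}] training proposed model")
    ck_prop = train_proposed(train_cases, ublocks, net_cfg, tcfg)
    rep_prop = evaluate_model(ck_prop, test_cases, ublocks=ublocks,
                              T=tcfg.T, seed=seed + 303)

    return DeskScaleResult(seed=seed, baseline=rep_base, proposed=rep_prop,
                           baseline_ckpt=ck_base, proposed_ckpt=ck_prop,
                           n_train=n_train, n_test=n_test)


def replicate_summary(results: list[DeskScaleResult]) -> dict:
    """Aggregate replicates: mean Dice per region/model, AUCs, win counts."""
    out: dict = {"n_replicates": len(results)}
    for region in ("ET", "TC", "WT"):
        out[f"baseline_dice_{region}"] = float(np.mean(
            [r.baseline.mean_dice[region] for r in results]))
        out[f"proposed_dice_{region}"] = float(np.mean(
            [r.proposed.mean_dice[region] for r in results]))
    out["et_wins"] = int(sum(
        r.proposed.mean_dice["ET"] >= r.baseline.mean_dice["ET"]
        for r in results))
    for m in ("entropy", "mutual_information", "aleatoric", "epistemic"):
        vals = [r.baseline.error_auc[m] for r in results
                if m in r.baseline.error_auc]
        out[f"baseline_auc_{m}"] = float(np.mean(vals)) if vals else float("nan")
    out["uam_overhead_pct"] = float(np.mean(
        [r.uam_param_overhead()["overhead_pct"] for r in results]))
    return out
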