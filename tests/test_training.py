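"""Dice loss, augmentation safety, and the two-stage training loops."""

import numpy as np
import pytest

from uqseg.io import one_hot_labels
from uqseg.phantoms import PhantomSpec, generate_cohort
from uqseg.segnet import SegNetConfig, build_network
from uqseg.training import (TrainConfig, augment, dice_loss, load_checkpoint,
                            precompute_ublocks, save_checkpoint,
                            train_baseline, train_proposed)

SMALL_SPEC = PhantomSpec(grid_shape=(32, 32, 32), radius_range_wt=(5.0, 8.0))
SMALL_NET = SegNetConfig(base_channels=4, depth=2, seed=0)
SMALL_TRAIN = dict(batch_size=4, crop_size=(16, 16, 16))


def test_dice_loss_zero_on_perfect_prediction(rng):
    labels = rng.choice([0, 1, 2, 4], size=(6, 6, 6))
    probs = one_hot_labels(labels)
    assert dice_loss(probs, labels) < 1e-4


def test_dice_loss_one_on_disjoint_masks():
    labels = np.zeros((4, 4, 4), dtype=int)
    labels[:2] = 1
    probs = np.zeros((4, 4, 4, 4), dtype=np.float32)
    probs[1, 2:] = 1.0  # predicts class 1 exactly where truth is background
    probs[0, :2] = 1.0
    # foreground classes 2 and 3 are empty in both -> eps keeps them ~0
    per_class_1 = 1.0  # zero overlap
    loss = dice_loss(probs, labels)
    assert abs(loss - per_class_1 / 3) < 1e-3  # mean over the 3 fg classes


def test_dice_loss_half_overlap_arithmetic():
    """p=(1,1,0,0), g=(1,0,1,0) in one class: 1 - 2/(2+2) = 0.5."""
    labels = np.array([1, 0, 1, 0]).reshape(1, 1, 4)
    probs = np.zeros((4, 1, 1, 4), dtype=np.float32)
    probs[1] = np.array([1, 1, 0, 0]).reshape(1, 1, 4)
    probs[0] = 1.0 - probs[1]
    # restrict to the single populated class by checking the class-1 term
    p, g = probs[1].ravel(), (labels == 1).ravel().astype(float)
    term = 1 - (2 * (p * g).sum() + 1e-5) / ((p**2).sum() + (g**2).sum() + 1e-5)
    assert abs(term - 0.5) < 1e-4


def test_dice_loss_empty_class_is_finite(rng):
    labels = np.zeros((4, 4, 4), dtype=int)  # all background
    probs = np.zeros((4, 4, 4, 4), dtype=np.float32)
    probs[0] = 1.0
    loss = dice_loss(probs, labels)
    assert np.isfinite(loss) and loss < 1e-4


def test_augment_deterministic_and_label_safe():
    case = generate_cohort(SMALL_SPEC, 1, seed=3)[0]
    cfg = TrainConfig(crop_size=(16, 16, 16), seed=0)
    a = augment(case.image.data, case.labels.data, None, cfg, rng=42)
    b = augment(case.image.data, case.labels.data, None, cfg, rng=42)
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.labels, b.labels)
    for seed in range(10):
        s = augment(case.image.data, case.labels.data, None, cfg, rng=seed)
        assert set(np.unique(s.labels)) <= {0, 1, 2, 4}
        assert s.image.shape == (4, 16, 16, 16)


def test_augment_degenerate_config_is_pure_crop():
    case = generate_cohort(SMALL_SPEC, 1, seed=3)[0]
    cfg = TrainConfig(crop_size=(16, 16, 16), flip_prob=0.0,
                      rotation_range_deg=0.0, intensity_shift_range=0.0,
                      scale_range=(1.0, 1.0), seed=0)
    s = augment(case.image.data, case.labels.data, None, cfg, rng=7)
    o = s.transform["crop_origin"]
    sl = tuple(slice(a, a + 16) for a in o)
    assert np.array_equal(s.image, case.image.data[(slice(None),) + sl])
    assert np.array_equal(s.labels, case.labels.data[sl])


def test_augment_transforms_ublock_in_lockstep():
    case = generate_cohort(SMALL_SPEC, 1, seed=3)[0]
    cfg = TrainConfig(crop_size=(16, 16, 16), rotation_range_deg=0.0, seed=0)
    ublock = np.stack([case.labels.data.astype(np.float32)] * 4)
    s = augment(case.image.data, case.labels.data, ublock, cfg, rng=11)
    # without rotation, the spatially transformed block equals the labels
    assert np.array_equal(s.ublock[0], s.labels.astype(np.float32))


def test_augment_rejects_oversized_crop():
    case = generate_cohort(SMALL_SPEC, 1, seed=3)[0]
    cfg = TrainConfig(crop_size=(64, 64, 64), seed=0)
    with pytest.raises(ValueError, match="crop"):
        augment(case.image.data, case.labels.data, None, cfg, rng=0)


def test_zero_epochs_checkpoint_equals_initialization():
    cohort = generate_cohort(SMALL_SPEC, 2, seed=1)
    cfg = TrainConfig(epochs=0, **SMALL_TRAIN, seed=0)
    ckpt = train_baseline(cohort, SMALL_NET, cfg)
    fresh = build_network(ckpt.net_config)
    assert ckpt.network.weight_checksum() == fresh.weight_checksum()
    assert ckpt.history == []


def test_initial_dice_loss_in_unit_interval(rng):
    cohort = generate_cohort(SMALL_SPEC, 2, seed=1)
    net = build_network(SMALL_NET)
    probs = net.forward(cohort[0].image.data[None])
    loss = dice_loss(probs[0], cohort[0].labels.data)
    assert 0.0 < loss <= 1.0


def test_baseline_training_reduces_loss():
    cohort = generate_cohort(SMALL_SPEC, 6, seed=4)
    cfg = TrainConfig(epochs=6, **SMALL_TRAIN, seed=0)
    ckpt = train_baseline(cohort, SMALL_NET, cfg)
    losses = [h["loss"] for h in ckpt.history]
    assert losses[-1] < losses[0]


def test_proposed_training_runs_and_adds_uam_params():
    cohort = generate_cohort(SMALL_SPEC, 4, seed=5)
    cfg = TrainConfig(epochs=2, **SMALL_TRAIN, seed=0)
    base = train_baseline(cohort, SMALL_NET, cfg)
    ublocks = precompute_ublocks(base, cohort, T=3, seed=2)
    assert set(ublocks) == {c.case_id for c in cohort}
    for ub in ublocks.values():
        assert ub.shape == (4, 32, 32, 32)
        assert np.all(np.isfinite(ub))
    prop = train_proposed(cohort, ublocks, SMALL_NET, cfg)
    from uqseg.uam import uam_param_count

    extra = prop.network.n_parameters() - base.network.n_parameters()
    assert extra == len(prop.network.uam_sites) * uam_param_count()
    assert prop.history[-1]["loss"] < 1.0


def test_proposed_training_requires_all_ublocks():
    cohort = generate_cohort(SMALL_SPEC, 2, seed=6)
    cfg = TrainConfig(epochs=1, **SMALL_TRAIN, seed=0)
    with pytest.raises(ValueError, match=cohort[0].case_id[:8]):
        train_proposed(cohort, {}, SMALL_NET, cfg)


def test_ublock_precompute_is_deterministic_and_cached(tmp_path):
    cohort = generate_cohort(SMALL_SPEC, 2, seed=7)
    cfg = TrainConfig(epochs=0, **SMALL_TRAIN, seed=0)
    ckpt = train_baseline(cohort, SMALL_NET, cfg)
    a = precompute_ublocks(ckpt, cohort, T=3, seed=9, cache_dir=tmp_path)
    b = precompute_ublocks(ckpt, cohort, T=3, seed=9, cache_dir=tmp_path)
    for cid in a:
        assert np.array_equal(a[cid], b[cid])
    assert len(list(tmp_path.glob("ublock_*.npz"))) == 2


def test_restart_rule_triggers_on_unconverged_loss():
    """An unreachable loss threshold forces the maximum number of restarts."""
    cohort = generate_cohort(SMALL_SPEC, 2, seed=9)
    cfg = TrainConfig(epochs=1, **SMALL_TRAIN, restart_loss_threshold=1e-6,
                      max_restarts=2, seed=0)
    ckpt = train_baseline(cohort, SMALL_NET, cfg)
    assert ckpt.restarts_used == 2
    assert ckpt.net_config.seed == SMALL_NET.seed + 2000  # fresh init per try
    calm = TrainConfig(epochs=1, **SMALL_TRAIN, seed=0)
    assert train_baseline(cohort, SMALL_NET, calm).restarts_used == 0


def test_tumor_biased_crop_contains_lesion():
    case = generate_cohort(SMALL_SPEC, 1, seed=3)[0]
    cfg = TrainConfig(crop_size=(16, 16, 16), tumor_crop_prob=1.0,
                      rotation_range_deg=0.0, seed=0)
    for seed in range(8):
        s = augment(case.image.data, case.labels.data, None, cfg, rng=seed)
        assert (s.labels > 0).any()


def test_checkpoint_round_trip(tmp_path):
    cohort = generate_cohort(SMALL_SPEC, 2, seed=8)
    cfg = TrainConfig(epochs=1, **SMALL_TRAIN, seed=0)
    ckpt = train_baseline(cohort, SMALL_NET, cfg)
    save_checkpoint(ckpt, tmp_path / "ck.npz")
    loaded = load_checkpoint(tmp_path / "ck.npz")
    assert loaded.weight_hash() == ckpt.weight_hash()
    assert loaded.net_config == ckpt.net_config
    assert loaded.train_config == ckpt.train_config
    assert loaded.stage == "baseline"
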