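"""Attention module: resize oracle, pooling, attention contracts, plumbing."""

import numpy as np
import pytest

from uqseg.nn import Tensor
from uqseg.segnet import SegNetConfig, build_network
from uqseg.uam import (UamParams, apply_uam, attention_map, channel_pool,
                       plug_uam, resize_uncertainty, trilinear_resize,
                       uam_param_count)
from uqseg.uncertainty import UncertaintyBlock


def _block(values: np.ndarray) -> UncertaintyBlock:
    return UncertaintyBlock(values.astype(np.float32))


def test_resize_identity_is_bit_exact(rng):
    vals = rng.random((4, 6, 5, 7)).astype(np.float32)
    out = resize_uncertainty(_block(vals), (6, 5, 7))
    assert np.array_equal(out.values, vals)


def test_resize_constant_stays_constant(rng):
    vals = np.full((4, 8, 8, 8), 0.37, dtype=np.float32)
    out = resize_uncertainty(_block(vals), (3, 5, 11))
    assert np.allclose(out.values, 0.37, atol=1e-6)


def test_resize_linear_ramp_matches_analytic_interpolation():
    """Downsampling a linear ramp must reproduce the ramp analytically."""
    n_in, n_out = 16, 8
    ramp = np.broadcast_to(np.arange(n_in, dtype=np.float32),
                           (4, n_in, n_in, n_in)).copy()
    out = resize_uncertainty(_block(ramp), (n_out,) * 3)
    expect = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    assert np.abs(out.values[0, 0, 0] - expect).max() < 1e-5
    with pytest.raises(ValueError):
        resize_uncertainty(_block(ramp), (0, 8, 8))


def test_channel_pool_matches_bruteforce(rng):
    F = rng.standard_normal((1, 5, 3, 4, 2)).astype(np.float32)
    avg, mx = channel_pool(Tensor(F))
    for idx in np.ndindex((3, 4, 2)):
        chans = F[(0, slice(None)) + idx]
        assert np.isclose(avg.data[(0, 0) + idx], chans.mean(), atol=1e-6)
        assert np.isclose(mx.data[(0, 0) + idx], chans.max(), atol=1e-6)


def test_channel_pool_single_channel_identity(rng):
    F = rng.standard_normal((1, 1, 3, 3, 3)).astype(np.float32)
    avg, mx = channel_pool(Tensor(F))
    assert np.allclose(avg.data, F) and np.allclose(mx.data, F)


def test_zero_params_give_half_attention_and_1p5_scaling(rng):
    params = UamParams()
    params.set_zero()
    F = rng.standard_normal((1, 6, 8, 8, 8)).astype(np.float32)
    U = rng.random((4, 4, 4, 4)).astype(np.float32)
    A = attention_map(F, _block(U), params)
    assert np.allclose(A.data, 0.5, atol=1e-7)
    O = apply_uam(F, _block(U), params)
    assert np.allclose(O.data, 1.5 * F, atol=1e-5)


def test_attention_strictly_in_unit_interval(rng):
    params = UamParams(np.random.default_rng(0))
    F = 5.0 * rng.standard_normal((1, 3, 8, 8, 8)).astype(np.float32)
    U = rng.random((4, 8, 8, 8)).astype(np.float32)
    A = attention_map(F, _block(U), params).data
    assert A.shape == (1, 1, 8, 8, 8)
    assert A.min() > 0.0 and A.max() < 1.0


def test_attention_matches_direct_convolution_oracle(rng):
    """Hand-rolled conv + concat + sigmoid on a 4^3 input."""
    params = UamParams(np.random.default_rng(5))
    F = rng.standard_normal((1, 3, 4, 4, 4)).astype(np.float32)
    U = rng.random((4, 4, 4, 4)).astype(np.float32)
    got = attention_map(F, _block(U), params).data[0, 0]

    def conv_naive(x, w, b):
        cin, d, h, v = x.shape
        co = w.shape[0]
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        out = np.zeros((co, d, h, v), dtype=np.float64)
        for o in range(co):
            for i in range(d):
                for j in range(h):
                    for l in range(v):
                        out[o, i, j, l] = (
                            xp[:, i:i + 3, j:j + 3, l:l + 3] * w[o]).sum() + b[o]
        return out

    u_prime = conv_naive(U, params.reduce.w.data, params.reduce.b.data)
    favg = F[0].mean(axis=0, keepdims=True)
    fmax = F[0].max(axis=0, keepdims=True)
    cat = np.concatenate([u_prime, favg, fmax])
    fused = conv_naive(cat, params.fuse.w.data, params.fuse.b.data)[0]
    want = 1.0 / (1.0 + np.exp(-fused))
    assert np.abs(got - want).max() < 1e-5


def test_apply_uam_zero_features_absorb(rng):
    params = UamParams(np.random.default_rng(1))
    F = np.zeros((1, 3, 8, 8, 8), dtype=np.float32)
    U = rng.random((4, 8, 8, 8)).astype(np.float32)
    assert np.all(apply_uam(F, _block(U), params).data == 0.0)


def test_apply_uam_matches_elementwise_oracle_and_keeps_shape(rng):
    params = UamParams(np.random.default_rng(2))
    F = rng.standard_normal((1, 5, 8, 8, 8)).astype(np.float32)
    U = rng.random((4, 8, 8, 8)).astype(np.float32)
    A = attention_map(F, _block(U), params).data
    O = apply_uam(F, _block(U), params).data
    assert O.shape == F.shape
    for c in range(5):
        assert np.allclose(O[0, c], F[0, c] * A[0, 0] + F[0, c], atol=1e-6)


def test_gradient_of_refined_features_has_identity_component():
    """The additive skip contributes dO/dF = I + (attention terms)."""
    rng0 = np.random.default_rng(3)
    params = UamParams(rng0)
    F0 = rng0.standard_normal((1, 2, 4, 4, 4)).astype(np.float32)
    U = rng0.random((4, 4, 4, 4)).astype(np.float32)
    eps = 1e-2
    idx = (0, 1, 2, 3, 1)
    Fp = F0.copy()
    Fp[idx] += eps
    Fm = F0.copy()
    Fm[idx] -= eps
    dO = (apply_uam(Fp, _block(U), params).data[idx]
          - apply_uam(Fm, _block(U), params).data[idx]) / (2 * eps)
    A_here = attention_map(F0, _block(U), params).data[0, 0, idx[2], idx[3], idx[4]]
    # dO/dF at the same voxel = 1 + A + F * dA/dF; the identity+gate part
    # dominates because dA/dF is bounded by the sigmoid slope
    assert dO > 1.0
    assert abs(dO - (1.0 + A_here)) < 0.5


def test_plug_uam_site_count_and_param_delta():
    cfg = SegNetConfig(base_channels=4, depth=2, seed=0)  # 10 convolutions
    base = build_network(cfg)
    n_base = base.n_parameters()
    net = plug_uam(build_network(cfg), every_k_layers=5)
    assert len(net.uam_sites) == 2
    assert net.n_parameters() - n_base == 2 * uam_param_count()
    net3 = plug_uam(build_network(cfg), every_k_layers=3)
    assert len(net3.uam_sites) == 3
    with pytest.raises(ValueError):
        plug_uam(build_network(cfg), every_k_layers=0)


def test_augmented_forward_with_zero_sites_scales_features(rng):
    """Zero-weight attention sites leave a finite, deterministic forward."""
    cfg = SegNetConfig(base_channels=4, depth=1, dropout_rate=0.0, seed=0)
    net = plug_uam(build_network(cfg), every_k_layers=5)
    for site in net.uam_sites.values():
        site.set_zero()
    x = rng.random((1, 4, 8, 8, 8)).astype(np.float32)
    U = rng.random((4, 8, 8, 8)).astype(np.float32)
    out = net.forward(x, ublock=U)
    assert np.all(np.isfinite(out))
    assert np.array_equal(out, net.forward(x, ublock=U))
    with pytest.raises(ValueError, match="uncertainty"):
        net.forward(x)  # sites attached but no block supplied


def test_uam_param_count_closed_form():
    p = UamParams()
    assert p.n_parameters() == uam_param_count() == (4 * 27 * 4 + 4) + (6 * 27 + 1)
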