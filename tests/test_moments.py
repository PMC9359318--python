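"""Moment propagation: closed forms, sampling oracles, structural invariants."""

import numpy as np
import pytest

import vdpnet as v
from vdpnet.gaussian import GaussianActivation, RandomParameter
from vdpnet.moments import (
    IDENTITY,
    RELU,
    deterministic_forward,
    mc_oracle,
    propagate_network,
    propagate_residual,
)


def act(mean, cov, mode="full", layout=None):
    return GaussianActivation(np.asarray(mean, float), np.asarray(cov, float), mode, layout)


# ----------------------------------------------------------------------
# exact scalar / small cases
# ----------------------------------------------------------------------


def test_first_conv_scalar_product_of_constant_and_gaussian():
    # z = x*w with x=3, w ~ N(2, 0.5): mean 6, variance 9 * 0.5
    kernel = RandomParameter(np.full((1, 1, 1, 1), 2.0), np.full((1, 1, 1, 1), 0.5))
    out = v.propagate_conv_first(np.array([[[3.0]]]), kernel)
    assert out.mean.ravel()[0] == pytest.approx(6.0, abs=1e-12)
    assert out.cov[0, 0] == pytest.approx(4.5, abs=1e-12)


def test_first_conv_zero_variance_matches_deterministic_convolution():
    rng = np.random.default_rng(1)
    x = rng.random((2, 5, 5))
    kernel = RandomParameter(rng.standard_normal((3, 2, 3, 3)), np.zeros((3, 2, 3, 3)))
    out = v.propagate_conv_first(x, kernel)
    assert np.all(out.cov == 0.0)
    det = deterministic_forward([{"type": "conv", "kernel": kernel}], x)
    assert np.array_equal(out.mean, det)


def test_fc_scalar_product_of_independent_gaussians():
    # w ~ N(2, 0.5), b ~ N(3, 1): var = 0.5*1 + 4*1 + 9*0.5 = 9
    b = act([3.0], [[1.0]])
    out = v.propagate_fc(b, RandomParameter(np.array([2.0]), np.array([0.5]), role="fc-weight"))
    assert out.mean[0] == pytest.approx(6.0, abs=1e-12)
    assert out.cov[0, 0] == pytest.approx(9.0, abs=1e-12)


def test_relu_taylor_masks_negative_mean_coordinates():
    out = v.propagate_activation(act([2.0, -3.0], [0.01, 0.04], "diagonal"), RELU)
    assert np.allclose(out.mean, [2.0, 0.0], atol=1e-15)
    assert np.allclose(out.cov, [0.01, 0.0], atol=1e-15)


def test_identity_activation_leaves_moments_unchanged():
    a = act([1.0, -2.0], [[0.3, 0.1], [0.1, 0.2]])
    out = v.propagate_activation(a, IDENTITY)
    assert np.array_equal(out.mean, a.mean)
    assert np.array_equal(out.cov, a.cov)


def test_softmax_symmetric_two_class_case():
    out = v.propagate_softmax(act([0.0, 0.0], np.eye(2)))
    assert np.allclose(out.mean, [0.5, 0.5], atol=1e-12)
    assert np.allclose(out.cov, [[0.125, -0.125], [-0.125, 0.125]], atol=1e-12)


def test_batchnorm_scalar_affine_map():
    out = v.propagate_batchnorm(act([4.0], [[2.0]]), 1.0, 3.0, 2.0, 0.5, eps=1.0)
    assert out.mean[0] == pytest.approx(3.5, abs=1e-12)
    assert out.cov[0, 0] == pytest.approx(2.0, abs=1e-12)


def test_batchnorm_inverse_normalization_is_identity():
    a = act([1.0, -0.5, 2.0], [0.2, 0.1, 0.3], "diagonal")
    mu_b, var_b, eps = np.array([0.5, 0.1, -0.2]), np.array([2.0, 1.0, 0.5]), 1e-3
    gamma = np.sqrt(var_b + eps)
    out = v.propagate_batchnorm(a, mu_b, var_b, gamma, mu_b, eps=eps)
    assert np.allclose(out.mean, a.mean, atol=1e-12)
    assert np.allclose(out.cov, a.cov, atol=1e-12)


def test_batchnorm_requires_positive_variance_plus_eps():
    with pytest.raises(FloatingPointError):
        v.propagate_batchnorm(act([1.0], [[1.0]]), 0.0, -1.0, 1.0, 0.0, eps=0.5)


def test_maxpool_gathers_covariance_at_argmax():
    a = act(np.array([1.0, 5.0, 2.0, 4.0]).reshape(1, 1, 4), [0.1, 0.2, 0.3, 0.4], "diagonal")
    out = v.propagate_maxpool(a, (1, 2))
    assert np.allclose(out.mean.ravel(), [5.0, 4.0])
    assert np.allclose(out.cov, [0.2, 0.4])


def test_maxpool_tie_keeps_first_index_row_major():
    a = act(np.full((1, 2, 2), 3.0), np.array([0.1, 0.2, 0.3, 0.4]), "diagonal")
    out = v.propagate_maxpool(a, 2)
    assert out.cov[0] == pytest.approx(0.1)


def test_maxpool_zero_covariance_stays_zero_and_guards_window():
    a = act(np.arange(16.0).reshape(1, 4, 4), np.zeros(16), "diagonal")
    assert np.all(v.propagate_maxpool(a, 2).cov == 0.0)
    with pytest.raises(ValueError):
        v.propagate_maxpool(a, 5)


def test_flatten_builds_block_diagonal_and_rejects_mixed_modes():
    p1 = act([1.0, 2.0], [[0.5, 0.2], [0.2, 0.5]])
    p2 = act([3.0, 4.0], [[0.1, 0.0], [0.0, 0.1]])
    out = v.propagate_flatten([p1, p2])
    assert out.cov.shape == (4, 4)
    assert np.all(out.cov[:2, 2:] == 0.0) and np.all(out.cov[2:, :2] == 0.0)
    assert np.allclose(out.cov[:2, :2], p1.cov) and np.allclose(out.cov[2:, 2:], p2.cov)
    single = v.propagate_flatten([p1])
    assert np.array_equal(single.cov, p1.cov)
    with pytest.raises(ValueError):
        v.propagate_flatten([p1, act([0.0], [0.1], "diagonal")])


def test_residual_identity_and_linear_block():
    a = act([1.5], [[0.2]])
    out = propagate_residual(a, lambda z: act([0.0], [[0.0]]))
    assert np.allclose(out.mean, a.mean) and np.allclose(out.cov, a.cov, atol=1e-8)

    def linear_block(z):  # F(x) = 1*x, so J = 2 and cov -> 4 * 0.2
        return act(z.mean.copy(), [[0.0]])

    out = propagate_residual(a, linear_block)
    assert out.mean[0] == pytest.approx(3.0, abs=1e-8)
    assert out.cov[0, 0] == pytest.approx(0.8, rel=1e-6)


def test_conv_inner_1x1_reduces_to_fc_scalar_case():
    a = act(np.array([[[3.0]]]), np.array([[1.0]]), layout=(1, 1, 1))
    kernel = RandomParameter(np.full((1, 1, 1, 1), 2.0), np.full((1, 1, 1, 1), 0.5))
    out = v.propagate_conv_inner(a, kernel)
    assert out.mean.ravel()[0] == pytest.approx(6.0, abs=1e-12)
    assert out.cov[0, 0] == pytest.approx(9.0, abs=1e-12)


def test_conv_inner_deterministic_limit():
    rng = np.random.default_rng(3)
    mean = rng.random((2, 4, 4))
    a = GaussianActivation(mean, np.zeros((32, 32)), "full")
    kernel = RandomParameter(rng.standard_normal((3, 2, 3, 3)), np.zeros((3, 2, 3, 3)))
    out = v.propagate_conv_inner(a, kernel)
    assert np.all(out.cov == 0.0)
    det = deterministic_forward([{"type": "conv", "kernel": kernel}], mean)
    assert np.array_equal(out.mean, det)


def test_conv_shape_mismatch_raises():
    kernel = RandomParameter(np.zeros((1, 3, 3, 3)), np.zeros((1, 3, 3, 3)))
    with pytest.raises(ValueError):
        v.propagate_conv_first(np.zeros((1, 6, 6)), kernel)


# ----------------------------------------------------------------------
# sampling oracles
# ----------------------------------------------------------------------


def _rel_err(a, b):
    return np.abs(a - b).max() / max(np.abs(b).max(), 1e-300)


def test_first_conv_full_covariance_matches_sampling_oracle():
    rng = np.random.default_rng(0)
    x = rng.random((1, 6, 6))
    kernel = RandomParameter(
        rng.standard_normal((2, 1, 3, 3)) * 0.5, rng.random((2, 1, 3, 3)) * 0.1 + 0.01
    )
    ana = v.propagate_conv_first(x, kernel)
    em, ec = mc_oracle([{"type": "conv", "kernel": kernel}], x, 30000, seed=1)
    assert _rel_err(em, ana.flat_mean()) < 0.01
    assert _rel_err(ec, ana.cov) < 0.05


def test_fc_full_covariance_matches_sampling_oracle():
    rng = np.random.default_rng(2)
    mu = rng.random(3) + 0.5
    sigma = 0.05 * np.eye(3) + 0.01
    b = GaussianActivation(mu, 0.5 * (sigma + sigma.T), "full")
    w = RandomParameter(rng.standard_normal((2, 3)), rng.random((2, 3)) * 0.05, role="fc-weight")
    ana = v.propagate_fc(b, w)
    em, ec = mc_oracle([{"type": "fc", "weights": w}], b, 100000, seed=3)
    assert _rel_err(em, ana.mean) < 0.01
    assert _rel_err(ec, ana.cov) < 0.05


def test_conv_inner_full_covariance_matches_sampling_oracle():
    rng = np.random.default_rng(4)
    mu = rng.random((1, 4, 4)) + 0.5
    base = rng.standard_normal((16, 16)) * 0.02
    cov = base @ base.T + 0.01 * np.eye(16)
    a = GaussianActivation(mu, cov, "full")
    kernel = RandomParameter(
        rng.standard_normal((2, 1, 3, 3)) * 0.4, rng.random((2, 1, 3, 3)) * 0.02
    )
    ana = v.propagate_conv_inner(a, kernel, padding=1)
    em, ec = mc_oracle([{"type": "conv", "kernel": kernel, "padding": 1}], a, 100000, seed=5)
    assert _rel_err(em, ana.flat_mean()) < 0.01
    assert _rel_err(ec, ana.cov) < 0.05


def test_relu_taylor_is_near_exact_away_from_the_kink():
    # means >= 3 sigma from zero: linearization error is negligible
    rng = np.random.default_rng(6)
    mu = rng.random(5) + 1.0
    cov = np.diag(rng.random(5) * 0.01)
    a = GaussianActivation(mu, cov, "full")
    ana = v.propagate_activation(a, RELU)
    draws = rng.multivariate_normal(mu, cov, size=200000)
    emp = np.cov(np.maximum(draws, 0.0), rowvar=False)
    assert _rel_err(emp, ana.cov) < 0.02


def test_residual_block_matches_sampling_oracle_at_small_variance():
    rng = np.random.default_rng(8)
    mu = rng.random(4) + 0.5
    cov = np.diag(rng.random(4) * 1e-3)
    a = GaussianActivation(mu, cov, "full")
    w = rng.standard_normal((4, 4)) * 0.3

    def branch(z):
        return GaussianActivation(np.tanh(w @ z.flat_mean()), np.zeros((4, 4)), "full")

    ana = propagate_residual(a, branch)
    draws = rng.multivariate_normal(mu, cov, size=200000)
    outs = draws + np.tanh(draws @ w.T)
    assert _rel_err(np.cov(outs, rowvar=False), ana.cov) < 0.05
    assert _rel_err(outs.mean(axis=0), ana.mean) < 0.01


def test_mc_oracle_contract():
    kernel = RandomParameter(np.ones((1, 1, 2, 2)), np.zeros((1, 1, 2, 2)))
    layers = [{"type": "conv", "kernel": kernel}]
    x = np.ones((1, 3, 3))
    with pytest.raises(ValueError):
        mc_oracle(layers, x, 1, seed=0)
    m1, c1 = mc_oracle(layers, x, 50, seed=9)
    m2, c2 = mc_oracle(layers, x, 50, seed=9)
    assert np.array_equal(m1, m2) and np.array_equal(c1, c2)
    assert np.all(c1 == 0.0)  # zero-variance weights: no output spread


# ----------------------------------------------------------------------
# structural invariants
# ----------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(5))
def test_full_mode_chain_produces_psd_symmetric_covariance(seed, reference_chain):
    layers, _ = reference_chain
    rng = np.random.default_rng(100 + seed)
    x = rng.random((1, 8, 8))
    out = propagate_network(layers, x, "full")
    assert np.allclose(out.cov, out.cov.T, atol=1e-12)
    eig = np.linalg.eigvalsh(out.cov)
    assert eig.min() >= -1e-8 * max(eig.max(), 1e-30)


def test_softmax_covariance_rows_sum_to_zero_identity():
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = rng.integers(2, 6)
        base = rng.standard_normal((n, n))
        d = GaussianActivation(rng.standard_normal(n), base @ base.T + 1e-6 * np.eye(n), "full")
        out = v.propagate_softmax(d)
        assert abs(out.cov.sum()) <= 1e-8 * np.trace(out.cov)


def test_diagonal_mode_equals_full_diagonal_for_non_mixing_transforms():
    rng = np.random.default_rng(12)
    mean = rng.random((2, 4, 4))
    diag = rng.random(32) * 0.1
    a_full = GaussianActivation(mean, np.diag(diag), "full")
    a_diag = GaussianActivation(mean, diag.copy(), "diagonal")

    f1 = v.propagate_activation(a_full, RELU)
    d1 = v.propagate_activation(a_diag, RELU)
    assert np.array_equal(np.diag(f1.cov), d1.cov)

    f2 = v.propagate_maxpool(a_full, 2)
    d2 = v.propagate_maxpool(a_diag, 2)
    assert np.array_equal(np.diag(f2.cov), d2.cov)

    f3 = v.propagate_batchnorm(a_full, 0.2, 1.3, 1.1, 0.0)
    d3 = v.propagate_batchnorm(a_diag, 0.2, 1.3, 1.1, 0.0)
    assert np.array_equal(np.diag(f3.cov), d3.cov)

    f4 = v.propagate_flatten([a_full, a_full])
    d4 = v.propagate_flatten([a_diag, a_diag])
    assert np.array_equal(np.diag(f4.cov), d4.cov)


def test_deterministic_limit_zero_everywhere(reference_chain):
    layers, x = reference_chain
    zeroed = []
    for layer in layers:
        layer = dict(layer)
        for key in ("kernel", "weights"):
            if key in layer:
                p = layer[key]
                layer[key] = RandomParameter(p.mean, np.zeros_like(p.variance), p.role)
        zeroed.append(layer)
    out = propagate_network(zeroed, x, "full")
    assert np.all(out.cov == 0.0)
    det = deterministic_forward(zeroed, x)
    assert np.array_equal(out.mean.ravel(), det.ravel())
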