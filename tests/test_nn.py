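"""Correctness of the NumPy network engine: finite-difference gradient
checks per layer, loss oracles, optimizer behavior, initialization."""

import numpy as np
import pytest

import _oracles as orc
import rcunet.nn.layers as L
from rcunet.nn import (Adam, BatchNorm2d, Conv2d, ConvTranspose2d, MaxPool2d,
                       ReLU, Sequential, Sigmoid, batch_loss, batch_loss_grad,
                       cross_entropy, init_weights)
from rcunet.nn.init import ConfigurationError


@pytest.fixture
def f64():
    """Run the engine in float64 for finite-difference precision."""
    L.set_default_dtype(np.float64)
    yield
    L.set_default_dtype(np.float32)


def _numeric_grad_check(module, x, rng, n_coords=8, h=1e-6, tol=1e-6):
    """Central-difference check of parameter and input gradients against the
    layer's backward pass, using sum(out * R) as a scalar head."""
    module.train()
    r = rng.standard_normal(module(x).shape)

    def loss():
        return float((module(x) * r).sum())

    module.zero_grad()
    base = module(x)
    gx = module.backward(r.copy())

    for name, p in module.named_parameters():
        for _ in range(n_coords):
            idx = tuple(rng.integers(s) for s in p.data.shape)
            orig = p.data[idx]
            p.data[idx] = orig + h
            lp = loss()
            p.data[idx] = orig - h
            lm = loss()
            p.data[idx] = orig
            num = (lp - lm) / (2 * h)
            assert abs(num - p.grad[idx]) <= tol * (1 + abs(num)), \
                f"{name}{idx}: numeric {num} vs analytic {p.grad[idx]}"
    # input gradient at a few coordinates
    for _ in range(n_coords):
        idx = tuple(rng.integers(s) for s in x.shape)
        orig = x[idx]
        x[idx] = orig + h
        module.zero_grad()
        lp = loss()
        x[idx] = orig - h
        lm = loss()
        x[idx] = orig
        num = (lp - lm) / (2 * h)
        assert abs(num - gx[idx]) <= tol * (1 + abs(num))


@pytest.mark.parametrize("make,layer_in", [
    (lambda: Conv2d(3, 5, 3), (2, 3, 6, 6)),
    (lambda: Conv2d(4, 2, 1), (2, 4, 5, 5)),
    (lambda: ConvTranspose2d(3, 4), (2, 3, 4, 4)),
    (lambda: BatchNorm2d(3), (4, 3, 5, 5)),
    (lambda: MaxPool2d(), (2, 3, 6, 6)),
    (lambda: Sigmoid(), (2, 2, 4, 4)),
    (lambda: Sequential(Conv2d(2, 3, 3), BatchNorm2d(3), ReLU(),
                        Conv2d(3, 2, 3)), (2, 2, 6, 6)),
])
def test_layer_gradients_match_finite_differences(f64, make, layer_in):
    rng = np.random.default_rng(7)
    module = make()
    for p in module.parameters():
        p.data[...] = rng.standard_normal(p.data.shape) * 0.5
    # shift input away from ReLU/maxpool kinks for stable differences
    x = rng.standard_normal(layer_in) + 0.05
    _numeric_grad_check(module, x, rng)


class TestLosses:
    def test_single_pixel_half_probability(self):
        assert cross_entropy(np.array([[1.0]]), np.array([[0.5]])) == \
            pytest.approx(np.log(2), abs=1e-12)

    def test_perfect_prediction_is_bounded_by_clamp(self, rng):
        y = (rng.random((16, 16)) > 0.5).astype(float)
        loss = cross_entropy(y, y)
        assert 0 <= loss <= y.size * 1.2e-7

    def test_matches_per_pixel_summation_oracle(self, rng):
        for _ in range(20):
            y = (rng.random((4, 4)) > 0.5).astype(float)
            p = rng.random((4, 4))
            expected = orc.oracle_cross_entropy_sum(y, p)
            assert cross_entropy(y, p) == pytest.approx(expected, rel=1e-12)

    def test_batch_is_mean_of_per_image_sums(self, rng):
        y = (rng.random((2, 4, 4)) > 0.5).astype(float)
        p = rng.random((2, 4, 4))
        expected = (cross_entropy(y[0], p[0]) + cross_entropy(y[1], p[1])) / 2
        assert batch_loss(y, p) == pytest.approx(expected, rel=1e-12)

    def test_identical_copies_equal_single_image_loss(self, rng):
        y = (rng.random((4, 4)) > 0.5).astype(float)
        p = rng.random((4, 4))
        stacked_y = np.stack([y] * 5)
        stacked_p = np.stack([p] * 5)
        assert batch_loss(stacked_y, stacked_p) == \
            pytest.approx(cross_entropy(y, p), rel=1e-12)

    def test_shape_mismatch_and_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.zeros((2, 2)), np.zeros((3, 2)))
        with pytest.raises(ValueError):
            batch_loss(np.zeros((0, 2, 2)), np.zeros((0, 2, 2)))

    def test_loss_gradient_matches_finite_differences(self, rng):
        y = (rng.random((2, 3, 3)) > 0.5).astype(float)
        p = rng.uniform(0.05, 0.95, (2, 3, 3))
        g = batch_loss_grad(y, p)
        h = 1e-7
        for idx in [(0, 1, 2), (1, 0, 0), (1, 2, 2)]:
            pp = p.copy()
            pp[idx] += h
            pm = p.copy()
            pm[idx] -= h
            num = (batch_loss(y, pp) - batch_loss(y, pm)) / (2 * h)
            assert g[idx] == pytest.approx(num, rel=1e-5)


class TestAdam:
    def test_step_size_bounded_by_learning_rate(self, rng):
        # |step| <= ~lr per coordinate once moments warm up; assert the
        # loose 10x bound on the very first step
        p = L.Parameter(rng.standard_normal((4, 4)))
        before = p.data.copy()
        opt = Adam([p], lr=1e-3)
        p.grad[...] = rng.standard_normal((4, 4)) * 100
        opt.step()
        assert np.abs(p.data - before).max() <= 10 * 1e-3

    def test_zero_lr_freezes_weights(self, rng):
        p = L.Parameter(rng.standard_normal((3, 3)))
        before = p.data.copy()
        opt = Adam([p], lr=0.0)
        p.grad[...] = rng.standard_normal((3, 3))
        opt.step()
        np.testing.assert_array_equal(p.data, before)

    def test_invalid_decay_rates_rejected(self):
        with pytest.raises(ValueError):
            Adam([], beta1=1.0)


class TestHeNormal:
    def test_empirical_variance_matches_two_over_fan_in(self):
        conv = Conv2d(64, 64, 3)  # ~36k weight draws
        init_weights(conv, "he_normal", seed=3)
        target = 2.0 / (3 * 3 * 64)
        assert conv.weight.data.var() == pytest.approx(target, rel=0.10)
        assert abs(conv.weight.data.mean()) < 0.001

    def test_biases_zero_and_seed_reproducible(self):
        a = Conv2d(8, 8, 3)
        b = Conv2d(8, 8, 3)
        init_weights(a, seed=5)
        init_weights(b, seed=5)
        np.testing.assert_array_equal(a.weight.data, b.weight.data)
        assert np.all(a.bias.data == 0.0)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ConfigurationError):
            init_weights(Conv2d(2, 2), "glorot", seed=0)


def test_state_dict_roundtrip(tiny_rcunet, rng):
    init_weights(tiny_rcunet, seed=1)
    state = tiny_rcunet.state_dict()
    init_weights(tiny_rcunet, seed=2)
    tiny_rcunet.load_state_dict(state)
    for name, p in tiny_rcunet.named_parameters():
        np.testing.assert_array_equal(p.data, state[name])
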