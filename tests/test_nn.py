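"""Neural-network primitives: oracles, identities, gradient checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from glucospec import nn


def loop_conv2d(x, k, stride):
    """Nested-loop cross-correlation oracle."""
    kh, kw = k.shape
    ho = (x.shape[0] - kh) // stride + 1
    wo = (x.shape[1] - kw) // stride + 1
    out = np.zeros((ho, wo))
    for p in range(ho):
        for q in range(wo):
            for m in range(kh):
                for n in range(kw):
                    out[p, q] += x[p * stride + m, q * stride + n] * k[m, n]
    return out


class TestConv2d:
    def test_hand_example(self):
        out = nn.conv2d([[1, 2], [3, 4]], [[1, 0], [0, 1]])
        assert out.shape == (1, 1) and out[0, 0] == 5

    def test_identity_kernel(self, rng):
        x = rng.standard_normal((5, 7))
        assert np.array_equal(nn.conv2d(x, [[1.0]]), x)

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            x = rng.standard_normal((8, 8))
            k = rng.standard_normal((4, 4))
            assert np.max(np.abs(nn.conv2d(x, k, stride=2) - loop_conv2d(x, k, 2))) <= 1e-10

    def test_empty_output_errors(self):
        with pytest.raises(ValueError):
            nn.conv2d(np.ones((2, 2)), np.ones((3, 3)))


class TestRelu:
    def test_example(self):
        assert np.array_equal(nn.relu([-1, 0, 2]), [0, 0, 2])

    @settings(deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, (8,), elements=st.floats(-100, 100)))
    def test_idempotent_and_nonnegative(self, x):
        once = nn.relu(x)
        assert np.array_equal(nn.relu(once), once)
        assert np.all(once >= 0)


class TestMaxPool:
    def test_examples(self):
        assert nn.max_pool(np.array([[1, 2], [3, 4]]))[0, 0] == 4
        const = nn.max_pool(np.full((6, 6), 2.5))
        assert const.shape == (3, 3) and np.all(const == 2.5)

    def test_commutes_with_relu(self, rng):
        x = rng.standard_normal((6, 8))
        assert np.array_equal(nn.max_pool(nn.relu(x)), nn.relu(nn.max_pool(x)))


class TestBatchNorm:
    def test_two_point_batch_is_fixed(self):
        out = nn.batch_norm(np.array([-1.0, 1.0]), eps=1e-15)
        assert np.allclose(out, [-1, 1], atol=1e-6)

    def test_normalization_property(self, rng):
        x = rng.standard_normal((64, 5)) * 7 + 3
        out = nn.batch_norm(x, eps=1e-12)
        assert np.all(np.abs(out.mean(axis=0)) <= 1e-6)
        assert np.all(np.abs(out.var(axis=0) - 1) <= 1e-4)

    def test_constant_batch_no_nan(self):
        out = nn.batch_norm(np.full(8, 4.2), eps=1.0)
        assert np.all(out == 0)

    def test_batch_of_one_rejected(self):
        with pytest.raises(ValueError):
            nn.batch_norm(np.array([1.0]))


class TestSoftmax:
    def test_uniform(self):
        assert np.allclose(nn.softmax([0.0, 0.0]), [0.5, 0.5])

    def test_shift_invariance(self, rng):
        z = rng.standard_normal(5)
        assert np.allclose(nn.softmax(z), nn.softmax(z + 123.4), atol=1e-12)

    def test_extreme_logits_sum_to_one(self, rng):
        for _ in range(100):
            z = rng.uniform(-1e4, 1e4, size=3)
            assert abs(nn.softmax(z).sum() - 1.0) <= 1e-9


class TestModifiedCELoss:
    def test_reduces_to_bce(self, rng):
        p = rng.uniform(1e-6, 1 - 1e-6, size=1000)
        x = rng.integers(0, 2, size=1000).astype(float)
        ours = nn.modified_ce_loss(p, x, t=1.0, eta=0.0, reduce="none")
        bce = -x * np.log(p) - (1 - x) * np.log1p(-p)
        assert np.max(np.abs(ours - bce)) <= 1e-12

    def test_confident_correct_goes_to_zero(self):
        assert nn.modified_ce_loss(1 - 1e-9, 1.0, t=1.0, eta=2.0) < 1e-6

    def test_hand_value(self):
        val = nn.modified_ce_loss(0.9, 1.0, t=1.0, eta=2.0)
        assert val == pytest.approx(-(0.1**2) * np.log(0.9), rel=1e-9)
        assert val == pytest.approx(1.0536e-3, rel=1e-3)

    def test_focusing_downweights_easy_samples(self):
        """Focal weighting shrinks the easy/hard loss ratio >= 100x vs BCE."""
        easy, hard = 0.99, 0.55
        f = lambda p: nn.modified_ce_loss(p, 1.0, t=1.0, eta=2.0)
        b = lambda p: nn.modified_ce_loss(p, 1.0, t=1.0, eta=0.0)
        assert f(easy) / f(hard) <= (b(easy) / b(hard)) / 100.0

    def test_grad_matches_finite_difference(self, rng):
        for _ in range(20):
            p = rng.uniform(0.05, 0.95)
            x = float(rng.integers(0, 2))
            g = nn.modified_ce_loss_grad(p, x, t=0.75, eta=2.0)
            eps = 1e-7
            num = (
                nn.modified_ce_loss(p + eps, x, 0.75, 2.0)
                - nn.modified_ce_loss(p - eps, x, 0.75, 2.0)
            ) / (2 * eps)
            assert g == pytest.approx(num, rel=1e-5)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            nn.modified_ce_loss(1.2, 1.0)


class TestBiLSTM:
    def _layer(self, shared=True, seed=0):
        rng = np.random.default_rng(seed)
        layer = nn.BiLSTMLayer(3, 4, rng)
        if shared:
            layer.bwd.params = {k: v.copy() for k, v in layer.fwd.params.items()}
        return layer

    def test_direction_reversal_symmetry(self, rng):
        layer = self._layer(shared=True)
        x = rng.standard_normal((5, 2, 3))
        out = layer.forward(x, train=False)
        layer.params["w5"], layer.params["w6"] = layer.params["w6"], layer.params["w5"]
        out_rev = layer.forward(x[::-1], train=False)
        assert np.allclose(out_rev, out[::-1], atol=1e-12)

    def test_zero_backward_weight_is_forward_lstm(self, rng):
        layer = self._layer(shared=False, seed=3)
        layer.params["w5"] = np.ones(4)
        layer.params["w6"] = np.zeros(4)
        x = rng.standard_normal((6, 2, 3))
        assert np.allclose(layer.forward(x, train=False), layer.fwd.forward(x), atol=1e-12)

    def test_output_bound(self, rng):
        layer = self._layer(shared=False, seed=5)
        w5 = rng.standard_normal(4)
        w6 = rng.standard_normal(4)
        layer.params["w5"], layer.params["w6"] = w5, w6
        x = rng.standard_normal((7, 3, 3)) * 5
        out = layer.forward(x, train=False)
        bound = np.abs(w5) + np.abs(w6)
        assert np.all(np.abs(out) < bound + 1e-12)

    def test_functional_wrapper_validates_dims(self, rng):
        layer = self._layer()
        with pytest.raises(ValueError, match="feature dimension"):
            nn.bilstm(rng.standard_normal((4, 2, 7)), layer)
        with pytest.raises(ValueError, match="empty"):
            nn.bilstm(np.zeros((0, 2, 3)), layer)


def _num_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


class TestBackpropGradients:
    """Finite-difference checks of every layer's backward pass."""

    def _check(self, layer, x, rng, params=True, tol=1e-5):
        r = rng.standard_normal(layer.forward(x.copy(), train=False).shape)
        loss = lambda: float(np.sum(layer.forward(x, train=False) * r))
        layer.forward(x, train=False)
        dx = layer.backward(r)
        assert np.allclose(dx, _num_grad(loss, x), atol=tol)
        if params:
            for layer_obj in nn._flatten_layers([layer]):
                for name, p in layer_obj.params.items():
                    num = _num_grad(loss, p)
                    layer.forward(x, train=False)
                    layer.backward(r)
                    assert np.allclose(layer_obj.grads[name], num, atol=tol), name

    def test_conv(self, rng):
        layer = nn.Conv2D(2, 3, k=3, stride=2, rng=rng)
        self._check(layer, rng.standard_normal((2, 2, 7, 7)), rng)

    def test_dense(self, rng):
        self._check(nn.Dense(4, 3, rng), rng.standard_normal((5, 4)), rng)

    def test_maxpool(self, rng):
        self._check(nn.MaxPool2D(2), rng.standard_normal((2, 2, 5, 6)), rng, params=False)

    def test_batchnorm_train_mode(self, rng):
        layer = nn.BatchNorm2D(3)
        x = rng.standard_normal((4, 3, 3, 3))
        r = rng.standard_normal(layer.forward(x.copy(), train=True).shape)

        def loss():
            return float(np.sum(layer.forward(x, train=True) * r))

        layer.forward(x, train=True)
        dx = layer.backward(r)
        assert np.allclose(dx, _num_grad(loss, x), atol=1e-5)

    def test_lstm(self, rng):
        self._check(nn.LSTM(3, 4, rng), rng.standard_normal((4, 2, 3)), rng)

    def test_bilstm(self, rng):
        self._check(nn.BiLSTMLayer(3, 4, rng), rng.standard_normal((4, 2, 3)), rng)

    def test_attention(self, rng):
        self._check(nn.Attention(4, rng), rng.standard_normal((5, 2, 4)), rng)
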