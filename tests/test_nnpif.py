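"""The two-stage scoring network: forward symmetry, exact gradients,
training loop determinism and serialization."""

import numpy as np
import pytest

from cafold.encoding import ENCODING_DIM, encode_conformation
from cafold.nnpif import (
    GLOBAL_HIDDEN,
    PAIR_HIDDEN,
    PAIR_OUT,
    NNPIFModel,
    backward,
    evaluate_error,
    forward,
    init_model,
    train_epochs,
)

WEIGHT_NAMES = ("W1", "b1", "W2", "b2", "V1", "c1", "V2", "c2")


def loss_finite_diff(model, X, q, eps=1e-6):
    """Central finite differences of (O − q)² for every weight."""
    out = {}
    for name in WEIGHT_NAMES:
        W = getattr(model, name)
        G = np.zeros_like(W)
        it = np.nditer(W, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            orig = W[idx]
            W[idx] = orig + eps
            lp = (forward(model, X)[0] - q) ** 2
            W[idx] = orig - eps
            lm = (forward(model, X)[0] - q) ** 2
            W[idx] = orig
            G[idx] = (lp - lm) / (2 * eps)
            it.iternext()
        out[name] = G
    return out


class TestInitModel:
    def test_deterministic_and_seed_sensitive(self):
        a = init_model(20, 7)
        b = init_model(20, 7)
        c = init_model(20, 8)
        assert np.array_equal(a.W1, b.W1)
        assert not np.array_equal(a.W1, c.W1)

    def test_layer_shapes(self):
        m = init_model(33, 0)
        assert m.W1.shape == (33, PAIR_HIDDEN)
        assert m.W2.shape == (PAIR_HIDDEN, PAIR_OUT)
        assert m.V1.shape == (PAIR_OUT, GLOBAL_HIDDEN)
        assert m.V2.shape == (GLOBAL_HIDDEN, 1)

    def test_invalid_dim_rejected(self):
        with pytest.raises(ValueError):
            init_model(0, 0)


class TestForward:
    def test_permutation_invariance(self, native_trace):
        m = init_model(ENCODING_DIM, 0)
        enc = encode_conformation(native_trace)
        O1, _ = forward(m, enc.X)
        rng = np.random.default_rng(0)
        O2, _ = forward(m, enc.X[rng.permutation(len(enc.X))])
        assert O1 == pytest.approx(O2, abs=1e-12)

    def test_hand_computed_two_pair_example(self):
        din = 2
        m = init_model(din, 0)
        for name in WEIGHT_NAMES:
            getattr(m, name)[...] = 0.0
        m.W1[0, 0] = 1.0   # h1[0] = tanh(x[0])
        m.W2[0, 0] = 1.0   # xout[0] = tanh(h1[0])
        m.V1[0, 0] = 1.0   # hG[0] = tanh(S[0])
        m.V2[0, 0] = 2.0   # O = 2 hG[0]
        X = np.array([[0.5, 9.9], [-0.25, 1.1]])
        s = m.K * (np.tanh(np.tanh(0.5)) + np.tanh(np.tanh(-0.25)))
        expected = 2.0 * np.tanh(s)
        O, _ = forward(m, X)
        assert O == pytest.approx(expected, abs=1e-12)

    def test_empty_encoding_scores_zero_vector(self):
        m = init_model(10, 3)
        O, _ = forward(m, np.zeros((0, 10)))
        expected = float(
            (np.tanh(np.zeros(3) @ m.V1 + m.c1) @ m.V2 + m.c2)[0])
        assert O == pytest.approx(expected)

    def test_dimension_mismatch_rejected(self):
        m = init_model(10, 0)
        with pytest.raises(ValueError):
            forward(m, np.zeros((4, 11)))

    def test_rigid_motion_leaves_score_unchanged(self, native_trace):
        from .conftest import random_rigid_motion
        m = init_model(ENCODING_DIM, 1)
        O1, _ = forward(m, encode_conformation(native_trace))
        moved = native_trace.with_coords(
            random_rigid_motion(native_trace.coords, 4))
        O2, _ = forward(m, encode_conformation(moved))
        assert O1 == pytest.approx(O2, abs=1e-9)


class TestBackward:
    def test_matches_finite_differences_on_random_instances(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(100):
            din = int(rng.integers(4, 12))
            m = init_model(din, int(rng.integers(10**6)))
            for name in WEIGHT_NAMES:
                getattr(m, name)[...] *= 8.0
            X = rng.normal(size=(int(rng.integers(1, 8)), din))
            q = float(rng.uniform(-1, 1))
            O, cache = forward(m, X)
            g = backward(m, cache, q)
            fd = loss_finite_diff(m, X, q)
            for name in WEIGHT_NAMES:
                denom = np.maximum(1.0, np.maximum(np.abs(fd[name]),
                                                   np.abs(g[name])))
                worst = max(worst, float(
                    (np.abs(fd[name] - g[name]) / denom).max()))
        assert worst < 1e-5

    def test_zero_gradient_at_exact_prediction(self):
        m = init_model(6, 0)
        X = np.random.default_rng(0).normal(size=(3, 6))
        O, cache = forward(m, X)
        g = backward(m, cache, target=O)
        assert all(np.allclose(g[n], 0.0) for n in WEIGHT_NAMES)

    def test_batch_gradient_additivity(self):
        rng = np.random.default_rng(1)
        m = init_model(5, 2)
        Xa, Xb = rng.normal(size=(2, 5)), rng.normal(size=(4, 5))
        _, ca = forward(m, Xa)
        _, cb = forward(m, Xb)
        ga = backward(m, ca, 0.3)
        gb = backward(m, cb, -0.7)
        for name in WEIGHT_NAMES:
            assert np.allclose(ga[name] + gb[name], ga[name] + gb[name])
        # (additivity is by construction; assert the summed batch loss
        # gradient equals the sum of per-example gradients numerically)
        summed = {n: ga[n] + gb[n] for n in WEIGHT_NAMES}
        fd_a = loss_finite_diff(m, Xa, 0.3, eps=1e-5)
        fd_b = loss_finite_diff(m, Xb, -0.7, eps=1e-5)
        for name in WEIGHT_NAMES:
            assert np.allclose(summed[name], fd_a[name] + fd_b[name],
                               atol=1e-6)


class TestTraining:
    def make_examples(self, n=12, din=8, seed=0):
        rng = np.random.default_rng(seed)
        return [
            (rng.normal(size=(rng.integers(2, 6), din)),
             float(rng.uniform(-1, 1)))
            for _ in range(n)
        ]

    def test_zero_learning_rate_is_identity(self):
        m = init_model(8, 0)
        ex = self.make_examples()
        m2, _ = train_epochs(m, ex, lr=0.0, epochs=5)
        for name in WEIGHT_NAMES:
            assert np.array_equal(getattr(m, name), getattr(m2, name))

    def test_separable_set_error_decreases(self):
        # +1 examples activate one input block, −1 examples another
        rng = np.random.default_rng(0)
        ex = []
        for k in range(10):
            X = np.zeros((30, 8))
            block = slice(0, 4) if k % 2 else slice(4, 8)
            X[:, block] = rng.uniform(0.5, 1.0, size=(30, 4))
            ex.append((X, 1.0 if k % 2 else -1.0))
        m = init_model(8, 0)
        _, hist = train_epochs(m, ex, lr=0.05, epochs=10, seed=0)
        assert hist[-1] < hist[0]
        _, long_hist = train_epochs(m, ex, lr=0.05, epochs=300, seed=0)
        assert long_hist[-1] < 0.01 * long_hist[0]

    def test_fixed_seed_bit_identical(self):
        m = init_model(8, 0)
        ex = self.make_examples()
        a, ha = train_epochs(m, ex, lr=0.01, epochs=3, seed=5)
        b, hb = train_epochs(m, ex, lr=0.01, epochs=3, seed=5)
        assert ha == hb
        for name in WEIGHT_NAMES:
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            train_epochs(init_model(8, 0), [], lr=0.1)


class TestEvaluate:
    def test_zero_error_on_own_predictions(self):
        m = init_model(8, 0)
        ex = [(x, forward(m, x)[0]) for x, _ in
              TestTraining().make_examples(6)]
        assert evaluate_error(m, ex) == pytest.approx(0.0, abs=1e-24)

    def test_equals_hand_average(self):
        m = init_model(8, 1)
        ex = TestTraining().make_examples(5, seed=3)
        hand = np.mean([(forward(m, x)[0] - q) ** 2 for x, q in ex])
        assert evaluate_error(m, ex) == pytest.approx(hand)

    def test_side_effect_free(self):
        m = init_model(8, 1)
        ex = TestTraining().make_examples(5, seed=3)
        assert evaluate_error(m, ex) == evaluate_error(m, ex)


class TestSerialization:
    def test_bit_exact_round_trip(self, tmp_path):
        m = init_model(ENCODING_DIM, 9)
        p = tmp_path / "model.json"
        m.save(p)
        back = NNPIFModel.load(p)
        for name in WEIGHT_NAMES:
            assert np.array_equal(getattr(m, name), getattr(back, name))
        assert back.K == m.K and back.seed == m.seed
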