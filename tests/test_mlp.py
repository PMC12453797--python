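"""From-scratch MLP: initialization, forward/backward, training, prediction."""

import numpy as np
import pytest

from learnstate import (
    TrainConfig,
    backward,
    forward,
    init_mlp,
    predict,
    predict_proba,
    train_mlp,
)
from learnstate.mlp import loss_value


def finite_difference_grads(model, X, y, h=1e-5):
    """Central-difference oracle for every weight and bias entry."""
    grads_w = [np.zeros_like(w) for w in model.weights]
    grads_b = [np.zeros_like(b) for b in model.biases]
    for arrs, grads in ((model.weights, grads_w), (model.biases, grads_b)):
        for arr, g in zip(arrs, grads):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + h
                lp = loss_value(model, forward(model, X).output, y)
                arr[idx] = orig - h
                lm = loss_value(model, forward(model, X).output, y)
                arr[idx] = orig
                g[idx] = (lp - lm) / (2 * h)
    return grads_w, grads_b


def max_relative_error(analytic, numeric):
    worst = 0.0
    for a, n in zip(analytic, numeric):
        denom = np.maximum(np.maximum(np.abs(a), np.abs(n)), 1e-8)
        worst = max(worst, float((np.abs(a - n) / denom).max()))
    return worst


class TestInit:
    def test_reported_architecture_shapes(self):
        # 14 inputs, two hidden layers of 78, 3-state softmax head
        m = init_mlp((14, 78, 78, 3), seed=0)
        assert [w.shape for w in m.weights] == [(78, 14), (78, 78), (3, 78)]

    def test_deterministic_under_seed(self):
        a = init_mlp((4, 5, 3), seed=9)
        b = init_mlp((4, 5, 3), seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a.weights, b.weights))

    def test_biases_start_at_zero(self):
        m = init_mlp((6, 7, 3), seed=1)
        assert all(not b.any() for b in m.biases)

    def test_invalid_size_raises(self):
        with pytest.raises(ValueError):
            init_mlp((4, 0, 3))


class TestForward:
    def test_zero_weights_give_uniform_softmax(self):
        m = init_mlp((5, 4, 3), seed=0)
        for w in m.weights:
            w[:] = 0.0
        out = forward(m, np.random.default_rng(0).normal(size=(6, 5))).output
        assert np.allclose(out, 1.0 / 3.0)

    def test_keep_prob_one_train_equals_eval(self):
        m = init_mlp((4, 6, 3), seed=2, keep_prob=1.0)
        X = np.random.default_rng(1).normal(size=(5, 4))
        rng = np.random.default_rng(0)
        assert np.allclose(
            forward(m, X, mode="train", rng=rng).output, forward(m, X).output
        )

    def test_relu_zeroes_negative_preactivations(self):
        m = init_mlp((3, 3, 3), seed=0)
        m.weights[0] = np.eye(3)
        m.biases[0][:] = 0.0
        fp = forward(m, -np.abs(np.random.default_rng(0).normal(size=(4, 3))))
        assert not fp.activations[1].any()

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            forward(init_mlp((4, 5, 3), seed=0), np.zeros((2, 7)))

    def test_inverted_dropout_preserves_expectation(self):
        # the 1/P scaling makes the *pre-activation* expectation match the
        # eval pass; downstream nonlinearities see an unbiased input
        m = init_mlp((4, 6, 3), seed=3, keep_prob=0.6)
        X = np.random.default_rng(2).normal(size=(2, 4))
        rng = np.random.default_rng(0)
        avg = np.mean(
            [
                forward(m, X, mode="train", rng=rng).pre_activations[0]
                for _ in range(10_000)
            ],
            axis=0,
        )
        ref = forward(m, X).pre_activations[0]
        assert np.allclose(avg, ref, rtol=0.02, atol=0.02)


class TestBackward:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        m = init_mlp((5, 7, 3), seed=1)
        X = rng.normal(size=(4, 5))
        y = rng.integers(0, 3, size=4)
        fp = forward(m, X)
        gw, gb = backward(m, X, y, fp)
        nw, nb = finite_difference_grads(m, X, y)
        assert max_relative_error(gw + gb, nw + nb) < 1e-5

    def test_zero_input_batch_zeroes_input_gradients(self):
        m = init_mlp((4, 5, 3), seed=0)
        X = np.zeros((3, 4))
        y = np.array([0, 1, 2])
        fp = forward(m, X)
        gw, _ = backward(m, X, y, fp)
        assert not gw[0].any()

    def test_duplicated_batch_leaves_mean_gradient_unchanged(self):
        rng = np.random.default_rng(4)
        m = init_mlp((3, 6, 3), seed=2)
        X = rng.normal(size=(4, 3))
        y = rng.integers(0, 3, size=4)
        g1w, g1b = backward(m, X, y, forward(m, X))
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        g2w, g2b = backward(m, X2, y2, forward(m, X2))
        assert all(np.allclose(a, b, atol=1e-12) for a, b in zip(g1w + g1b, g2w + g2b))

    def test_stale_activations_raise(self):
        m = init_mlp((3, 4, 3), seed=0)
        fp = forward(m, np.zeros((2, 3)))
        with pytest.raises(ValueError):
            backward(m, np.zeros((5, 3)), np.zeros(5, dtype=int), fp)


class TestTrainMlp:
    def test_xor_is_learned_from_most_initializations(self):
        # plain GD on the 2-8-2 net solves XOR for >= 80 % of seeds
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0, 1, 1, 0])
        wins = 0
        for seed in range(10):
            m = init_mlp((2, 8, 2), seed=seed)
            cfg = TrainConfig(
                learning_rate=0.5, max_iter=5000, stop_threshold=1e-9, batch_size=4, seed=seed
            )
            m, _ = train_mlp(m, X, y, cfg)
            wins += int((predict(m, X) == y).all())
        assert wins >= 8

    def test_infinite_threshold_stops_after_one_iteration(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        y = np.random.default_rng(1).integers(0, 3, size=10)
        m = init_mlp((3, 4, 3), seed=0)
        _, history = train_mlp(
            m, X, y, TrainConfig(learning_rate=0.1, max_iter=50, stop_threshold=np.inf, batch_size=5)
        )
        assert len(history) == 1

    def test_zero_learning_rate_changes_nothing(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        y = np.random.default_rng(1).integers(0, 3, size=8)
        m = init_mlp((3, 4, 3), seed=0)
        trained, history = train_mlp(
            m, X, y, TrainConfig(learning_rate=0.0, max_iter=5, stop_threshold=1e-12, batch_size=4)
        )
        assert all(np.array_equal(a, b) for a, b in zip(m.weights, trained.weights))
        assert len(set(history)) == 1

    def test_divergence_aborts_with_diagnostic(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4)) * 100
        y = rng.integers(0, 3, size=20)
        m = init_mlp((4, 16, 3), seed=0)
        with pytest.raises(FloatingPointError, match="diverged"):
            train_mlp(m, X, y, TrainConfig(learning_rate=1e6, max_iter=50, batch_size=10))

    def test_loss_non_increasing_on_separable_data(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(-2, 0.3, size=(30, 2)), rng.normal(2, 0.3, size=(30, 2))])
        y = np.r_[np.zeros(30, dtype=int), np.ones(30, dtype=int)]
        m = init_mlp((2, 8, 2), seed=0)
        _, history = train_mlp(
            m, X, y,
            TrainConfig(learning_rate=0.01, max_iter=100, stop_threshold=1e-12, batch_size=60),
        )
        diffs = np.diff(history)
        assert np.all(diffs <= 1e-8)


class TestPredict:
    def test_zero_weight_tie_breaks_to_lowest_class(self):
        m = init_mlp((4, 5, 3), seed=0)
        for w in m.weights:
            w[:] = 0.0
        X = np.random.default_rng(0).normal(size=(7, 4))
        assert np.all(predict(m, X) == 0)

    def test_proba_rows_sum_to_one(self):
        m = init_mlp((4, 5, 3), seed=1)
        p = predict_proba(m, np.random.default_rng(0).normal(size=(9, 4)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_predict_agrees_with_argmax_of_proba(self):
        m = init_mlp((4, 5, 3), seed=2)
        X = np.random.default_rng(3).normal(size=(11, 4))
        assert np.array_equal(predict(m, X), predict_proba(m, X).argmax(axis=1))


def test_gradient_oracle_across_random_architectures():
    """Finite-difference equivalence over 20 random small architectures."""
    rng = np.random.default_rng(2024)
    for _ in range(20):
        n_hidden = int(rng.integers(1, 4))
        sizes = (
            int(rng.integers(2, 6)),
            *[int(rng.integers(3, 8)) for _ in range(n_hidden)],
            3,
        )
        m = init_mlp(sizes, seed=int(rng.integers(0, 1000)))
        for b in m.biases:  # move off exact ReLU kinks (non-differentiable points)
            b[:] = rng.normal(0.0, 0.1, size=b.shape)
        X = rng.normal(size=(4, sizes[0]))
        y = rng.integers(0, 3, size=4)
        fp = forward(m, X)
        gw, gb = backward(m, X, y, fp)
        nw, nb = finite_difference_grads(m, X, y)
        assert max_relative_error(gw + gb, nw + nb) < 1e-5
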