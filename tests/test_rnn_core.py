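import numpy as np
import pytest

from sledamage.cohort_select import LabeledSequence, ModelDataset
from sledamage.errors import ConfigurationError, DataError
from sledamage.rnn_core import (
    ModelWeights,
    TrainConfig,
    bce_loss,
    forward,
    gradients_bptt,
    init_weights,
    sgd_train,
)


def zero_weights(p, n):
    return ModelWeights(W_r=np.zeros((n, n)), W_i=np.zeros((n, p)), W_o=np.zeros(n))


class TestInitWeights:
    def test_deterministic_given_seed(self):
        cfg = TrainConfig(seed=9)
        a = init_weights(4, 7, cfg)
        b = init_weights(4, 7, cfg)
        assert np.array_equal(a.W_r, b.W_r)
        assert np.array_equal(a.W_i, b.W_i)
        assert np.array_equal(a.W_o, b.W_o)

    def test_zero_scales_give_zero_weights(self):
        w = init_weights(3, 2, TrainConfig(init_scale=0.0, spectral_radius=0.0))
        assert not w.W_r.any() and not w.W_i.any() and not w.W_o.any()

    def test_minimal_shape(self):
        w = init_weights(1, 1, TrainConfig(seed=0))
        assert w.W_r.shape == (1, 1) and w.W_i.shape == (1, 1) and w.W_o.shape == (1,)

    def test_recurrent_spectral_radius(self):
        w = init_weights(3, 40, TrainConfig(seed=2, spectral_radius=0.95))
        radius = max(abs(np.linalg.eigvals(w.W_r)))
        assert radius == pytest.approx(0.95, rel=1e-9)

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(ConfigurationError):
            init_weights(0, 5, TrainConfig())

    def test_json_round_trip(self, tmp_path):
        w = init_weights(3, 4, TrainConfig(seed=1))
        path = tmp_path / "w.json"
        w.to_json(path)
        again = ModelWeights.from_json(path)
        assert np.array_equal(w.W_r, again.W_r)
        assert np.array_equal(w.W_i, again.W_i)
        assert np.array_equal(w.W_o, again.W_o)


class TestForward:
    def test_zero_weights_score_half(self):
        w = zero_weights(3, 5)
        H, y, score = forward(w, np.random.default_rng(0).normal(size=(4, 3)))
        assert np.allclose(y, 0.5)
        assert score == 0.5
        assert H.shape == (4, 5)

    def test_hand_computed_single_step(self):
        # n=1: h = tanh(1*1) = 0.76159..., y = logistic(h) = 0.68165...
        w = ModelWeights(
            W_r=np.zeros((1, 1)), W_i=np.array([[1.0, 0.0]]), W_o=np.array([1.0])
        )
        _, _, score = forward(w, np.array([[1.0, 0.0]]))
        assert np.tanh(1.0) == pytest.approx(0.7615942)
        assert score == pytest.approx(1 / (1 + np.exp(-np.tanh(1.0))))
        assert score == pytest.approx(0.6816997, abs=1e-6)

    def test_no_recurrence_equals_independent_static_network(self):
        """With W_r = 0 the final score is a one-hidden-layer net on x_T."""
        from sledamage.baselines import FfnnScorer  # independently coded forward

        rng = np.random.default_rng(4)
        n, p = 6, 4
        w = ModelWeights(
            W_r=np.zeros((n, n)),
            W_i=rng.normal(size=(n, p)),
            W_o=rng.normal(size=n),
        )
        static = FfnnScorer(W1=w.W_i, w2=w.W_o)
        for _ in range(10):
            X = rng.normal(size=(rng.integers(1, 7), p))
            _, _, score = forward(w, X)
            assert score == pytest.approx(float(static(X[-1:])[0]))

    def test_width_mismatch_raises(self):
        with pytest.raises(DataError):
            forward(zero_weights(3, 2), np.zeros((2, 5)))

    def test_score_in_open_unit_interval(self):
        rng = np.random.default_rng(1)
        w = init_weights(3, 8, TrainConfig(seed=1))
        for _ in range(5):
            _, y, score = forward(w, rng.normal(size=(rng.integers(1, 9), 3)))
            assert 0.0 < score < 1.0
            assert np.all((y > 0) & (y < 1))


class TestBceLoss:
    def test_half_score_gives_ln2_both_labels(self):
        assert bce_loss(0.5, 1) == pytest.approx(np.log(2))
        assert bce_loss(0.5, 0) == pytest.approx(np.log(2))

    def test_monotone_toward_label(self):
        assert bce_loss(0.9, 1) < bce_loss(0.6, 1) < bce_loss(0.4, 1)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.1])
    def test_domain_error(self, bad):
        with pytest.raises(DataError):
            bce_loss(bad, 1)


def finite_difference_grads(weights, X, label, eps=1e-5):
    """Central-difference gradient of the final-step BCE loss."""

    def loss_of(w):
        _, _, score = forward(w, X)
        return bce_loss(score, label)

    grads = []
    for name in ("W_r", "W_i", "W_o"):
        base = getattr(weights, name)
        g = np.zeros_like(base)
        it = np.nditer(base, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            w_plus = weights.copy()
            getattr(w_plus, name)[idx] += eps
            w_minus = weights.copy()
            getattr(w_minus, name)[idx] -= eps
            g[idx] = (loss_of(w_plus) - loss_of(w_minus)) / (2 * eps)
        grads.append(g)
    return tuple(grads)


class TestGradientsBptt:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        T, n, p = rng.integers(1, 7), rng.integers(1, 6), rng.integers(1, 5)
        w = ModelWeights(
            W_r=rng.normal(0, 0.5, (n, n)),
            W_i=rng.normal(0, 0.5, (n, p)),
            W_o=rng.normal(0, 0.5, n),
        )
        X = rng.normal(size=(T, p))
        label = int(rng.integers(0, 2))
        analytic = gradients_bptt(w, X, label)
        numeric = finite_difference_grads(w, X, label)
        for a, g in zip(analytic, numeric):
            denom = np.maximum(np.abs(g), 1e-8)
            assert np.max(np.abs(a - g) / denom) < 1e-4

    def test_zero_weights_zero_output_gradient(self):
        w = zero_weights(3, 4)
        g_Wr, g_Wi, g_Wo = gradients_bptt(w, np.ones((3, 3)), 1)
        assert not g_Wo.any()  # h_T = 0 forces (y - label) * h_T = 0

    def test_length_one_sequence_has_zero_recurrent_gradient(self):
        rng = np.random.default_rng(0)
        w = ModelWeights(
            W_r=rng.normal(size=(4, 4)),
            W_i=rng.normal(size=(4, 2)),
            W_o=rng.normal(size=4),
        )
        g_Wr, _, _ = gradients_bptt(w, rng.normal(size=(1, 2)), 0)
        assert np.allclose(g_Wr, 0.0)  # h_0 = 0 enters W_r exactly once


class TestSgdTrain:
    def test_separable_data_early_stops(self, separable_dataset):
        weights, history = sgd_train(
            separable_dataset, TrainConfig(n_hidden=8, max_epochs=200, seed=0)
        )
        assert history.stop_reason == "early_stop"
        assert history.train_auc[-1] > 0.95

    def test_zero_epochs_returns_initial_weights(self, separable_dataset):
        cfg = TrainConfig(n_hidden=5, max_epochs=0, seed=3)
        weights, history = sgd_train(separable_dataset, cfg)
        init = init_weights(separable_dataset.n_features, 5, cfg)
        assert np.array_equal(weights.W_r, init.W_r)
        assert history.n_epochs == 0
        assert history.stop_reason == "max_epochs"

    def test_single_class_raises(self):
        seqs = [LabeledSequence("a", np.ones((2, 2)), 1),
                LabeledSequence("b", np.zeros((3, 2)), 1)]
        with pytest.raises(DataError):
            sgd_train(ModelDataset(seqs, ["x", "y"], {}), TrainConfig(max_epochs=1))

    def test_fully_deterministic(self, separable_dataset):
        cfg = TrainConfig(n_hidden=6, max_epochs=5, seed=11,
                          early_stop_train_auc=1.0)
        w1, h1 = sgd_train(separable_dataset, cfg)
        w2, h2 = sgd_train(separable_dataset, cfg)
        assert np.array_equal(w1.W_r, w2.W_r)
        assert np.array_equal(w1.W_i, w2.W_i)
        assert np.array_equal(w1.W_o, w2.W_o)
        assert h1.loss == h2.loss and h1.train_auc == h2.train_auc

    def test_history_lengths_consistent(self, separable_dataset):
        _, h = sgd_train(separable_dataset, TrainConfig(n_hidden=4, max_epochs=3,
                                                        early_stop_train_auc=1.0, seed=1))
        assert len(h.loss) == len(h.train_auc) == h.n_epochs == 3
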