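import numpy as np
import pytest

from adlsense.adl_labels import ClassWeights
from adlsense.adl_model import (
    AdlNetConfig,
    AdlNetwork,
    OUTPUT_STEPS,
    build_adl_network,
    masked_balanced_bce,
    pool_labels_to_output_grid,
    predict_session,
    train_adl,
)
from adlsense.features import FeatureSequence


def _cw(n=12):
    return ClassWeights(np.ones(n), np.ones(n))


def _feats(matrix, start=0.0):
    F = matrix.shape[1]
    return FeatureSequence(start, 3.0, matrix, [f"f{i}" for i in range(F)])


class TestArchitecture:
    @pytest.mark.parametrize("F", [1, 5, 12, 64])
    def test_shape_contract_200xF_to_100x12(self, F, rng):
        model = build_adl_network(AdlNetConfig(lstm_units=8), F, seed=0)
        out = model.forward(rng.random((2, 200, F)))
        assert out.shape == (2, OUTPUT_STEPS, 12)

    def test_outputs_in_unit_interval(self, rng):
        model = build_adl_network(AdlNetConfig(lstm_units=8), 4, seed=0)
        out = model.forward(rng.random((1, 200, 4)))
        assert out.min() > 0.0 and out.max() < 1.0

    def test_baseline_has_no_temporal_context(self, rng):
        """With kernel-1 convolutions only, permuting time steps within pool
        bins permutes the outputs identically."""
        model = build_adl_network(AdlNetConfig(use_lstm=False), 4, seed=0)
        x = rng.random((1, 200, 4))
        out = model.forward(x)
        # swap the two halves of every pool bin: pooled max is unchanged
        xs = x.reshape(1, 100, 2, 4)[:, :, ::-1, :].reshape(1, 200, 4)
        np.testing.assert_allclose(model.forward(xs), out, atol=1e-12)

    def test_feature_mismatch_raises(self, rng):
        model = build_adl_network(AdlNetConfig(), 4, seed=0)
        with pytest.raises(ValueError, match="features"):
            model.forward(rng.random((1, 200, 5)))


class TestLabelPooling:
    def test_both_rows_labeled(self):
        Y = np.ones((2, 12))
        w = np.ones(2)
        Yp, wp = pool_labels_to_output_grid(Y, w)
        assert Yp.shape == (1, 12) and (Yp == 1).all() and wp[0] == 1.0

    def test_half_labeled_gives_half_weight(self):
        Y = np.zeros((2, 12))
        Y[0, 3] = 1.0
        w = np.array([1.0, 0.0])
        Yp, wp = pool_labels_to_output_grid(Y, w)
        assert Yp[0, 3] == 1.0 and wp[0] == 0.5

    def test_unlabeled_pair_gives_zero_weight(self):
        Yp, wp = pool_labels_to_output_grid(np.zeros((2, 12)), np.zeros(2))
        assert wp[0] == 0.0

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            pool_labels_to_output_grid(np.zeros((3, 12)), np.zeros(3))


class TestMaskedLoss:
    def test_all_zero_weights_give_zero_loss(self, rng):
        p = rng.random((100, 12))
        Y = (rng.random((100, 12)) < 0.5).astype(float)
        assert masked_balanced_bce(p, Y, np.zeros(100), _cw()) == 0.0

    def test_perfect_predictions_near_zero(self):
        Y = np.eye(12)[np.arange(100) % 12]
        loss = masked_balanced_bce(Y, Y, np.ones(100), _cw())
        assert loss <= 12 * -np.log(1 - 1e-7) + 1e-12

    def test_zero_weight_steps_do_not_affect_loss(self, rng):
        p = rng.random((100, 12))
        Y = (rng.random((100, 12)) < 0.5).astype(float)
        w = (rng.random(100) < 0.6).astype(float)
        base = masked_balanced_bce(p, Y, w, _cw())
        p2 = p.copy()
        p2[w == 0] = rng.random((int((w == 0).sum()), 12))
        assert masked_balanced_bce(p2, Y, w, _cw()) == base  # bit-identical

    def test_single_step_single_class_ln2_over_12(self):
        p = np.array([[0.5]])
        Y = np.array([[1.0]])
        cw = ClassWeights(np.array([1.0]), np.array([1.0]))
        loss = masked_balanced_bce(p, Y, np.array([1.0]), cw)
        assert loss == pytest.approx(np.log(2) / 12, abs=1e-9)

    def test_nan_inputs_rejected(self):
        p = np.full((2, 12), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            masked_balanced_bce(p, np.zeros((2, 12)), np.ones(2), _cw())

    def test_gradient_vanishes_at_zero_weight_steps(self, rng):
        """Finite differences: dloss/dp = 0 wherever w = 0."""
        from adlsense.adl_model import _loss_grad

        p = rng.uniform(0.1, 0.9, size=(10, 12))
        Y = (rng.random((10, 12)) < 0.5).astype(float)
        w = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0], dtype=float)
        g = _loss_grad(p, Y, w, _cw())
        assert (g[w == 0] == 0).all()
        eps = 1e-6
        for t in (1, 3):
            p2 = p.copy()
            p2[t, 4] += eps
            fd = (masked_balanced_bce(p2, Y, w, _cw()) - masked_balanced_bce(p, Y, w, _cw())) / eps
            assert fd == 0.0
        # and is nonzero (and matches) at a weighted step
        p2 = p.copy()
        p2[0, 4] += eps
        fd = (masked_balanced_bce(p2, Y, w, _cw()) - masked_balanced_bce(p, Y, w, _cw())) / eps
        assert fd == pytest.approx(g[0, 4], rel=1e-4)


class TestTraining:
    def _windows(self, rng, n=6, F=4):
        out = []
        for _ in range(n):
            X = rng.random((200, F))
            Y = np.zeros((200, 12))
            Y[:, 0] = (X[:, 0] > 0.5).astype(float)
            out.append((_feats(X), Y, np.ones(200)))
        return out

    def test_loss_decreases_on_separable_data(self, rng):
        wins = self._windows(rng)
        model = AdlNetwork(AdlNetConfig(lstm_units=8, learning_rate=3e-3), 4, seed=0)
        hist = train_adl(model, wins, _cw(), epochs=15, batch_size=4, seed=0)
        assert hist[-1] < hist[0]

    def test_zero_epochs_leaves_model_unchanged(self, rng):
        wins = self._windows(rng)
        model = AdlNetwork(AdlNetConfig(lstm_units=8), 4, seed=0)
        before = [p.copy() for layer, name in model.parameters() for p in [layer.params[name]]]
        train_adl(model, wins, _cw(), epochs=0, batch_size=4, seed=0)
        after = [layer.params[name] for layer, name in model.parameters()]
        for a, b in zip(before, after):
            np.testing.assert_array_equal(a, b)

    def test_same_seed_reproduces_final_loss(self, rng):
        wins = self._windows(rng)
        h1 = train_adl(AdlNetwork(AdlNetConfig(lstm_units=8), 4, seed=1), wins, _cw(),
                       epochs=3, batch_size=4, seed=7)
        h2 = train_adl(AdlNetwork(AdlNetConfig(lstm_units=8), 4, seed=1), wins, _cw(),
                       epochs=3, batch_size=4, seed=7)
        assert h1 == h2

    def test_fully_unlabeled_training_set_rejected(self, rng):
        wins = [(w[0], w[1], np.zeros(200)) for w in self._windows(rng)]
        model = AdlNetwork(AdlNetConfig(lstm_units=8), 4, seed=0)
        with pytest.raises(ValueError, match="unlabeled"):
            train_adl(model, wins, _cw(), epochs=1, seed=0)


class TestPredictSession:
    def test_single_window_pass_through(self, rng):
        model = build_adl_network(AdlNetConfig(lstm_units=8), 3, seed=0)
        feats = _feats(rng.random((200, 3)))
        times, probs = predict_session(model, [feats])
        direct = model.predict(feats.matrix[None])[0]
        np.testing.assert_allclose(probs, direct)
        assert len(times) == OUTPUT_STEPS

    def test_overlapping_windows_average(self, rng):
        model = build_adl_network(AdlNetConfig(lstm_units=8), 3, seed=0)
        f1 = _feats(rng.random((200, 3)), start=0.0)
        f2 = _feats(rng.random((200, 3)), start=120.0)
        _, probs = predict_session(model, [f1, f2])
        p1 = model.predict(f1.matrix[None])[0]
        p2 = model.predict(f2.matrix[None])[0]
        # steps 120/6=20 .. 99 of window 1 overlap steps 0 .. 79 of window 2
        np.testing.assert_allclose(probs[20:100], (p1[20:] + p2[:80]) / 2, atol=1e-12)
        np.testing.assert_allclose(probs[:20], p1[:20], atol=1e-12)

    def test_empty_session_warns(self):
        model = build_adl_network(AdlNetConfig(lstm_units=8), 3, seed=0)
        with pytest.warns(UserWarning, match="shorter"):
            times, probs = predict_session(model, [])
        assert len(times) == 0 and probs.shape == (0, 12)


class TestHyperparamSearch:
    def test_single_trial_returns_its_config(self, rng):
        from adlsense.adl_model import hyperparam_search

        wins = TestTraining()._windows(rng, n=4)
        folds = [([0, 1, 2], [3])]
        cfg, log = hyperparam_search(wins, _cw(), folds, n_features=4,
                                     n_trials=1, epochs=1, seed=0)
        assert len(log) == 1
        assert cfg.lstm_units == log[0]["params"]["lstm_units"]

    def test_best_trial_is_min_of_log(self, rng):
        from adlsense.adl_model import hyperparam_search

        wins = TestTraining()._windows(rng, n=4)
        folds = [([0, 1], [2, 3])]
        cfg, log = hyperparam_search(wins, _cw(), folds, n_features=4,
                                     n_trials=3, epochs=1, seed=0)
        best = min(log, key=lambda t: t["val_loss"])
        assert cfg.lstm_units == best["params"]["lstm_units"]

    def test_zero_trials_rejected(self, rng):
        from adlsense.adl_model import hyperparam_search

        with pytest.raises(ValueError):
            hyperparam_search([], _cw(), [], n_features=4, n_trials=0)
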