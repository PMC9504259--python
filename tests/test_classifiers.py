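import numpy as np
import pytest

from emgfusion.classifiers import (
    CnnConfig,
    LstmConfig,
    load_model,
    predict_cnn_scores,
    predict_lstm_scores,
    save_model,
    train_cnn,
    train_lstm,
)


def toy_images(rng, n_per_class=20, size=16, planes=3):
    """Two trivially separable classes: dark noise vs bright noise."""
    dark = rng.random((n_per_class, size, size, planes)) * 0.3
    bright = 0.7 + rng.random((n_per_class, size, size, planes)) * 0.3
    x = np.concatenate([dark, bright])
    y = ["dark"] * n_per_class + ["bright"] * n_per_class
    return x, y


def toy_sequences(rng, n_per_class=15, width=20):
    a = [rng.normal(0.0, 0.05, size=(5, width)) for _ in range(n_per_class)]
    b = [rng.normal(1.0, 0.05, size=(5, width)) for _ in range(n_per_class)]
    return a + b, ["a"] * n_per_class + ["b"] * n_per_class


CNN_TOY = dict(n_classes=2, input_shape=(16, 16, 3), width=4, batch_size=10,
               initial_lr=0.01, max_epochs=10, seed=0)


class TestCnn:
    def test_separable_fixture_reaches_perfect_training_accuracy(self, rng):
        x, y = toy_images(rng)
        model = train_cnn(x, y, CnnConfig(**CNN_TOY))
        assert model.history["train_acc"].iloc[-1] == 1.0
        assert np.all(np.isfinite(model.history["loss"]))

    def test_held_out_generalization_and_score_validity(self, rng):
        x, y = toy_images(rng)
        model = train_cnn(x, y, CnnConfig(**CNN_TOY))
        xt, yt = toy_images(np.random.default_rng(99), n_per_class=5)
        scores = predict_cnn_scores(model, xt)
        assert scores.shape == (10, 2)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-6)
        pred = [model.classes_[i] for i in scores.argmax(axis=1)]
        assert pred == yt

    def test_same_seed_reproduces_final_loss(self, rng):
        x, y = toy_images(rng, n_per_class=8)
        cfg = CnnConfig(**{**CNN_TOY, "max_epochs": 3})
        a = train_cnn(x, y, cfg)
        b = train_cnn(x, y, cfg)
        assert a.history["loss"].iloc[-1] == b.history["loss"].iloc[-1]
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    @pytest.mark.parametrize("m", [1, 2, 8])
    def test_plane_contract_for_per_channel_images(self, rng, m):
        planes = 3 * m
        x = rng.random((8, 16, 16, planes))
        y = [0, 1] * 4
        cfg = CnnConfig(**{**CNN_TOY, "input_shape": (16, 16, planes), "max_epochs": 1})
        model = train_cnn(x, y, cfg)
        assert predict_cnn_scores(model, x).shape == (8, 2)

    def test_shape_mismatch_rejected(self, rng):
        x, y = toy_images(rng, n_per_class=5)
        model = train_cnn(x, y, CnnConfig(**{**CNN_TOY, "max_epochs": 1}))
        with pytest.raises(ValueError):
            predict_cnn_scores(model, rng.random((2, 32, 32, 3)))

    def test_missing_class_rejected(self, rng):
        x, _ = toy_images(rng, n_per_class=5)
        with pytest.raises(ValueError, match="class"):
            train_cnn(x, ["only"] * 10, CnnConfig(**CNN_TOY))

    def test_loss_decreases_on_separable_data(self, rng):
        x, y = toy_images(rng)
        model = train_cnn(x, y, CnnConfig(**CNN_TOY))
        losses = model.history["loss"].to_numpy()
        assert losses[-1] < losses[0]


LSTM_TOY = dict(n_classes=2, hidden_units=12, batch_size=10, initial_lr=0.02,
                max_epochs=15, seed=0)


class TestLstm:
    def test_separable_fixture_reaches_perfect_training_accuracy(self, rng):
        seqs, y = toy_sequences(rng)
        model = train_lstm(seqs, y, LstmConfig(**LSTM_TOY))
        assert model.history["train_acc"].iloc[-1] == 1.0

    def test_determinism(self, rng):
        seqs, y = toy_sequences(rng, n_per_class=6)
        cfg = LstmConfig(**{**LSTM_TOY, "max_epochs": 3})
        a = train_lstm(seqs, y, cfg)
        b = train_lstm(seqs, y, cfg)
        assert a.history["loss"].iloc[-1] == b.history["loss"].iloc[-1]

    def test_mixed_sequence_widths_accepted(self, rng):
        # both printed geometries (5 x 72 and 5 x 18) in one training set
        seqs = [rng.normal(0, 0.05, (5, 72)) for _ in range(6)]
        seqs += [rng.normal(1, 0.05, (5, 18)) for _ in range(6)]
        y = [0] * 6 + [1] * 6
        model = train_lstm(seqs, y, LstmConfig(**{**LSTM_TOY, "max_epochs": 5}))
        scores = predict_lstm_scores(model, seqs)
        assert scores.shape == (12, 2)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-6)

    def test_wrong_feature_count_rejected(self, rng):
        with pytest.raises(ValueError, match="feature rows|input"):
            train_lstm([rng.random((4, 20))], [0], LstmConfig(**LSTM_TOY))

    def test_order_preserved_in_predictions(self, rng):
        seqs, y = toy_sequences(rng)
        model = train_lstm(seqs, y, LstmConfig(**LSTM_TOY))
        scores = predict_lstm_scores(model, seqs)
        pred = [model.classes_[i] for i in scores.argmax(axis=1)]
        assert pred == y

    def test_unidirectional_variant_trains(self, rng):
        seqs, y = toy_sequences(rng, n_per_class=6)
        cfg = LstmConfig(**{**LSTM_TOY, "bidirectional": False, "max_epochs": 10})
        model = train_lstm(seqs, y, cfg)
        assert model.history["train_acc"].iloc[-1] == 1.0


class TestFiniteLosses:
    def test_losses_finite_across_seeds(self, rng):
        x, y = toy_images(rng, n_per_class=6)
        seqs, ys = toy_sequences(rng, n_per_class=6)
        for seed in (0, 1, 2):
            c = train_cnn(x, y, CnnConfig(**{**CNN_TOY, "max_epochs": 3, "seed": seed}))
            l = train_lstm(seqs, ys, LstmConfig(**{**LSTM_TOY, "max_epochs": 3, "seed": seed}))
            assert np.all(np.isfinite(c.history["loss"]))
            assert np.all(np.isfinite(l.history["loss"]))


class TestCheckpoints:
    def test_cnn_roundtrip(self, tmp_path, rng):
        x, y = toy_images(rng, n_per_class=5)
        model = train_cnn(x, y, CnnConfig(**{**CNN_TOY, "max_epochs": 2}))
        save_model(model, tmp_path / "cnn.npz")
        back = load_model(tmp_path / "cnn.npz")
        np.testing.assert_array_equal(
            predict_cnn_scores(back, x), predict_cnn_scores(model, x)
        )
        assert back.classes_ == model.classes_
        assert back.config.seed == model.config.seed

    def test_lstm_roundtrip(self, tmp_path, rng):
        seqs, y = toy_sequences(rng, n_per_class=5)
        model = train_lstm(seqs, y, LstmConfig(**{**LSTM_TOY, "max_epochs": 2}))
        save_model(model, tmp_path / "lstm.npz")
        back = load_model(tmp_path / "lstm.npz")
        np.testing.assert_array_equal(
            predict_lstm_scores(back, seqs), predict_lstm_scores(model, seqs)
        )
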