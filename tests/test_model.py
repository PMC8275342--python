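"""Architecture tokens, network construction, loss and training contracts."""

import numpy as np
import pytest

from editnas import (ArchitectureTokens, ModelConfig, build_model,
                     load_checkpoint, multitask_bce, predict, save_checkpoint,
                     train)
from editnas.exceptions import ArchitectureError, DimensionError
from editnas.model import N_OP_CHOICES, OP_NAMES

RNG = np.random.default_rng(3)


def random_batch(n=4):
    X = np.zeros((n, 4, 60))
    idx = RNG.integers(0, 4, size=(n, 60))
    for i in range(n):
        X[i, idx[i], np.arange(60)] = 1.0
    return X


def all_op_tokens():
    """Eight layers cycling through every op, with a few residuals set."""
    ops = tuple(list(range(1, 8)) + [4])
    residuals = []
    for t in range(8):
        row = [0] * t
        if t >= 2:
            row[0] = 1  # skip from layer 1
        residuals.append(tuple(row))
    return ArchitectureTokens(ops=ops, residuals=tuple(residuals))


class TestArchitectureTokens:
    def test_token_shape_validation(self):
        with pytest.raises(ArchitectureError):
            ArchitectureTokens(ops=(1, 2), residuals=((),))
        with pytest.raises(ArchitectureError):
            ArchitectureTokens(ops=(0,), residuals=((),))
        with pytest.raises(ArchitectureError):
            ArchitectureTokens(ops=(1, 2), residuals=((), (2,)))

    def test_residual_row_lengths(self):
        tok = all_op_tokens()
        assert [len(r) for r in tok.residuals] == list(range(8))

    def test_json_round_trip(self):
        tok = all_op_tokens()
        assert ArchitectureTokens.from_json(tok.to_json()) == tok

    def test_op_name_table_complete(self):
        assert sorted(OP_NAMES) == list(range(1, N_OP_CHOICES + 1))


class TestBuildAndForward:
    def test_degenerate_identity_architecture(self):
        model = build_model(ArchitectureTokens.all_identity())
        out = predict(model, random_batch(3))
        assert out.shape == (3, 6)

    def test_every_op_preserves_geometry_and_range(self):
        model = build_model(all_op_tokens())
        out = predict(model, random_batch(5))
        assert out.shape == (5, 6)
        assert np.all(out > 0) and np.all(out < 1)

    def test_width_scaling_filters(self):
        cfg = ModelConfig(width_scale=6)
        model = build_model(ArchitectureTokens(ops=(4,), residuals=((),)), cfg)
        assert model.params["conv0_w"].data.shape == (192, 192, 8)
        assert model.params["stem_w"].data.shape == (192, 4, 8)

    def test_wrong_geometry_rejected(self):
        model = build_model(ArchitectureTokens.all_identity())
        with pytest.raises(DimensionError):
            predict(model, np.zeros((2, 4, 59)))

    def test_inference_deterministic(self):
        model = build_model(all_op_tokens(), ModelConfig(dropout=0.4))
        X = random_batch(2)
        assert np.array_equal(predict(model, X), predict(model, X))


class TestMultitaskBCE:
    def test_fair_coin_entropy(self):
        p = np.full((1, 6), 0.5)
        assert multitask_bce(p, p) == pytest.approx(6 * np.log(2))

    def test_perfect_confident_prediction(self):
        y = np.array([[0, 1, 0, 1, 1, 0]], dtype=float)
        assert multitask_bce(y, y) == pytest.approx(0.0, abs=1e-5)

    def test_single_task_value(self):
        pred = np.array([[0.8, 0.5, 0.5, 0.5, 0.5, 0.5]])
        target = np.array([[1.0, 0.5, 0.5, 0.5, 0.5, 0.5]])
        delta = multitask_bce(pred, target) - 5 * np.log(2)
        assert delta == pytest.approx(-np.log(0.8), rel=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            multitask_bce(np.zeros((2, 6)), np.zeros((3, 6)))


class TestTraining:
    def _xy(self, n=96, seed=0):
        rng = np.random.default_rng(seed)
        X = random_batch(n)
        # learnable soft targets driven by base identity at a fixed position
        y0 = 0.2 + 0.6 * X[:, 0, 20]
        Y = np.column_stack([y0] * 6)
        Y[:, 5] = np.clip(Y[:, 3] + Y[:, 4], 0, 1)
        return X, Y

    def test_loss_decreases_on_learnable_data(self):
        X, Y = self._xy()
        cfg = ModelConfig(max_epochs=8, early_stop_patience=100, dropout=0.0,
                          learning_rate=5e-3, batch_size=32, seed=1)
        tokens = ArchitectureTokens(ops=(1,), residuals=((),))
        trained = train(build_model(tokens, cfg), (X, Y), (X, Y), cfg)
        losses = [e["train_loss"] for e in trained.training_log]
        assert losses[-1] < losses[0]

    def test_patience_arithmetic(self):
        """Validation loss that only worsens stops after patience+1 epochs."""
        X, Y = self._xy(64)
        # validation labels are anti-correlated noise: val loss will not improve
        cfg = ModelConfig(max_epochs=200, early_stop_patience=3, dropout=0.0,
                          learning_rate=5e-2, batch_size=64, seed=2)
        tokens = ArchitectureTokens(ops=(7,), residuals=((),))
        Yv = 1.0 - Y
        trained = train(build_model(tokens, cfg), (X, Y), (X, Yv), cfg)
        log = trained.training_log
        best = int(np.argmin([e["val_loss"] for e in log])) + 1
        assert len(log) == best + 3  # stopped exactly `patience` epochs later

    def test_training_deterministic(self):
        X, Y = self._xy(64)
        cfg = ModelConfig(max_epochs=3, dropout=0.2, learning_rate=1e-3,
                          batch_size=32, seed=11)
        tokens = ArchitectureTokens(ops=(1, 5), residuals=((), (1,)))
        log1 = train(build_model(tokens, cfg), (X, Y), (X, Y), cfg).training_log
        log2 = train(build_model(tokens, cfg), (X, Y), (X, Y), cfg).training_log
        assert log1 == log2

    def test_best_epoch_weights_restored(self):
        X, Y = self._xy(64)
        cfg = ModelConfig(max_epochs=10, early_stop_patience=100, dropout=0.0,
                          learning_rate=5e-3, batch_size=32, seed=4)
        tokens = ArchitectureTokens(ops=(1,), residuals=((),))
        trained = train(build_model(tokens, cfg), (X, Y), (X, Y), cfg)
        best_val = min(e["val_loss"] for e in trained.training_log)
        refit_val = multitask_bce(predict(trained, X), Y)
        assert refit_val == pytest.approx(best_val, rel=1e-6)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, tiny_trained_model):
        X = random_batch(4)
        path = tmp_path / "ckpt.json"
        save_checkpoint(tiny_trained_model, path)
        loaded = load_checkpoint(path)
        assert np.allclose(predict(loaded, X), predict(tiny_trained_model, X))
        assert loaded.tokens == tiny_trained_model.tokens
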