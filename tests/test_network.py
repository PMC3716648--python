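import math

import numpy as np
import pytest

from conftest import make_design
from icuglyc.errors import ConfigError, NumericalError, SchemaError
from icuglyc.network import (NetworkModel, TrainConfig, forward, init_network,
                             load_model, loss_and_grad, model_digest,
                             predict_set, save_model, train)


def finite_difference_grads(model, Xs, Ys, eps=1e-6):
    """Central-difference gradient of the scaled-space MSE."""
    grads = {}
    for name, arr in model.params().items():
        g = np.zeros_like(arr)
        flat = arr.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            lp, _ = loss_and_grad(model, Xs, Ys)
            flat[i] = orig - eps
            lm, _ = loss_and_grad(model, Xs, Ys)
            flat[i] = orig
            g.ravel()[i] = (lp - lm) / (2 * eps)
        grads[name] = g
    return grads


def max_relative_gap(analytic, numeric):
    gaps = []
    for k in analytic:
        a, b = analytic[k].ravel(), numeric[k].ravel()
        gaps.append(np.max(np.abs(a - b) / np.maximum(np.abs(a) + np.abs(b), 1e-3)))
    return max(gaps)


class TestInit:
    def test_same_seed_identical_weights(self):
        m1 = init_network(5, 3, seed=9)
        m2 = init_network(5, 3, seed=9)
        np.testing.assert_array_equal(m1.W1, m2.W1)
        np.testing.assert_array_equal(m1.W2, m2.W2)

    def test_shapes_single_hidden_unit(self):
        m = init_network(4, 1, seed=0)
        assert m.W1.shape == (4, 1) and m.W2.shape == (1, 15)

    def test_fan_in_scaling_bounds_weights(self):
        m = init_network(9, 16, seed=2)
        assert np.abs(m.W1).max() <= 1.0 / math.sqrt(9)
        assert np.abs(m.W2).max() <= 1.0 / math.sqrt(16)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ConfigError):
            init_network(0, 3, seed=0)


class TestForward:
    def test_zero_weights_output_is_target_center(self):
        m = init_network(2, 3, seed=0, n_outputs=4)
        m.W1[:] = 0; m.b1[:] = 0; m.W2[:] = 0; m.b2[:] = 0
        m.y_center, m.y_scale = 120.0, 10.0
        out = forward(m, np.array([5.0, -3.0]))
        np.testing.assert_array_equal(out, np.full(4, 120.0))

    def test_hand_computed_single_hidden_unit(self):
        m = NetworkModel(
            n_inputs=2, n_hidden=1, n_outputs=2, hidden_activation="tanh",
            W1=np.array([[0.3], [-0.2]]), b1=np.array([0.1]),
            W2=np.array([[0.5, -1.0]]), b2=np.array([0.2, 0.0]),
            x_center=np.zeros(2), x_scale=np.ones(2),
            y_center=100.0, y_scale=10.0,
        )
        h = math.tanh(0.3 * 1.0 - 0.2 * (-1.0) + 0.1)
        expected = np.array([10.0 * (0.5 * h + 0.2) + 100.0,
                             10.0 * (-1.0 * h) + 100.0])
        np.testing.assert_allclose(forward(m, np.array([1.0, -1.0])),
                                   expected, atol=1e-10)

    def test_outputs_always_within_device_range(self):
        rng = np.random.default_rng(3)
        m = init_network(4, 6, seed=3, n_outputs=15)
        m.W2 *= 100.0
        m.y_center, m.y_scale = 200.0, 500.0
        out = forward(m, rng.normal(size=(20, 4)))
        assert out.min() >= 40.0 and out.max() <= 400.0

    def test_dimension_mismatch_rejected(self):
        m = init_network(3, 2, seed=0)
        with pytest.raises(SchemaError):
            forward(m, np.ones(5))


class TestGradients:
    @pytest.mark.parametrize("activation", ["tanh", "logistic"])
    def test_backprop_matches_finite_differences(self, activation):
        rng = np.random.default_rng(11)
        m = init_network(3, 4, seed=11, n_outputs=5, hidden_activation=activation)
        Xs = rng.normal(size=(6, 3))
        Ys = rng.normal(size=(6, 5))
        _, analytic = loss_and_grad(m, Xs, Ys)
        numeric = finite_difference_grads(m, Xs, Ys)
        assert max_relative_gap(analytic, numeric) < 1e-5


class TestTrain:
    def test_zero_epochs_leaves_weights_at_initialization(self):
        rng = np.random.default_rng(0)
        d = make_design(rng.normal(size=(30, 2)),
                        100 + rng.normal(size=(30, 3)))
        m = init_network(2, 3, seed=1, n_outputs=3)
        W1_before = m.W1.copy()
        trained, history = train(m, d, TrainConfig(max_epochs=0))
        np.testing.assert_array_equal(trained.W1, W1_before)
        assert history["train_mse"] == []

    def test_full_batch_no_momentum_training_mse_non_increasing(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 3))
        Y = 100 + 10 * X[:, :1] + rng.normal(0, 1, size=(50, 1))
        d = make_design(X, Y)
        m = init_network(3, 4, seed=5, n_outputs=1)
        _, history = train(m, d, TrainConfig(
            batch_mode="full-batch", momentum=0.0, learning_rate=0.005,
            max_epochs=200, early_stop_patience=0, validation_fraction=0.0))
        mse = history["train_mse"]
        assert all(b <= a + 1e-12 for a, b in zip(mse, mse[1:]))

    def test_full_batch_reaches_ols_mse_on_linear_data(self):
        rng = np.random.default_rng(0)
        n = 1000
        X = rng.normal(size=(n, 3))
        Y = (100 + (X @ np.array([2.0, -1.0, 0.5])) * 10
             + rng.normal(0, 5, size=n))[:, None]
        d = make_design(X, Y)
        A = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(A, Y, rcond=None)
        ols_mse = float(np.mean((Y - A @ beta) ** 2))
        m = init_network(3, 4, seed=1, n_outputs=1)
        trained, history = train(m, d, TrainConfig(
            batch_mode="full-batch", momentum=0.0, learning_rate=0.1,
            max_epochs=6000, early_stop_patience=0, validation_fraction=0.0))
        nn_mse = history["train_mse"][-1] * trained.y_scale ** 2
        assert abs(nn_mse - ols_mse) / ols_mse < 0.01

    def test_rescaling_inputs_and_targets_rescales_forecasts(self):
        rng = np.random.default_rng(8)
        n = 60
        X = np.column_stack([90 + 5 * np.sin(np.arange(n) / 5.0),
                             rng.normal(size=n)])
        Y = 90 + 5 * np.cos(np.arange(n) / 5.0)[:, None] + np.zeros((n, 2))
        cfg = TrainConfig(max_epochs=30, early_stop_patience=0, seed=4)
        d1 = make_design(X, Y)
        m1, _ = train(init_network(2, 3, seed=4, n_outputs=2), d1, cfg)
        X2, Y2 = X.copy(), 2.0 * Y
        X2[:, 0] *= 2.0  # the glucose-valued input column
        d2 = make_design(X2, Y2)
        m2, _ = train(init_network(2, 3, seed=4, n_outputs=2), d2, cfg)
        p1 = predict_set(m1, d1).predicted
        p2 = predict_set(m2, d2).predicted
        np.testing.assert_allclose(p2, 2.0 * p1, rtol=1e-6)

    def test_divergence_aborts_with_epoch(self):
        rng = np.random.default_rng(2)
        d = make_design(rng.normal(size=(40, 2)),
                        100 + 50 * rng.normal(size=(40, 1)))
        m = init_network(2, 4, seed=2, n_outputs=1)
        with pytest.raises(NumericalError, match="epoch"):
            train(m, d, TrainConfig(batch_mode="full-batch", learning_rate=50.0,
                                    momentum=0.9, max_epochs=200,
                                    early_stop_patience=0))


class TestPredictSet:
    def test_single_row_design(self):
        rng = np.random.default_rng(1)
        d = make_design(rng.normal(size=(21, 2)), 100 + rng.normal(size=(21, 15)))
        m, _ = train(init_network(2, 3, seed=1), d,
                     TrainConfig(max_epochs=2, early_stop_patience=0))
        one = make_design(rng.normal(size=(1, 2)), 100 + rng.normal(size=(1, 15)))
        ps = predict_set(m, one)
        assert ps.predicted.shape == (1, 15) and ps.actual.shape == (1, 15)

    def test_schema_mismatch_names_columns(self):
        rng = np.random.default_rng(1)
        d = make_design(rng.normal(size=(21, 2)), 100 + rng.normal(size=(21, 3)))
        m, _ = train(init_network(2, 3, seed=1, n_outputs=3), d,
                     TrainConfig(max_epochs=1, early_stop_patience=0))
        other = make_design(rng.normal(size=(5, 2)), 100 + rng.normal(size=(5, 3)))
        other.X.columns = ["x0", "zz"]
        with pytest.raises(SchemaError, match="zz"):
            predict_set(m, other)


def test_model_persistence_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    d = make_design(rng.normal(size=(25, 3)), 100 + rng.normal(size=(25, 4)))
    m, _ = train(init_network(3, 5, seed=6, n_outputs=4), d,
                 TrainConfig(max_epochs=3, early_stop_patience=0))
    path = tmp_path / "model.json"
    save_model(m, path)
    back = load_model(path)
    assert model_digest(back) == model_digest(m)
    assert back.input_names == m.input_names
    x = rng.normal(size=3)
    np.testing.assert_array_equal(forward(back, x), forward(m, x))
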