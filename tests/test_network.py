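"""Base-learner network: scaling, forward rule, objective, training."""

import math

import numpy as np
import pytest

from ennscore import (
    FeatureDataset,
    FeatureScaler,
    NetworkModel,
    SchemaError,
    TrainConfig,
    UsageError,
    fit_scaler,
    forward,
    linear_output,
    objective,
    sigmoid,
    train_network,
)
from conftest import make_dataset


def manual_net(W1, w2, n_parent_features=None, subset=None, names=None):
    """Hand-assembled network with an identity scaler."""
    W1 = np.asarray(W1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    d = W1.shape[0] - 1
    subset = np.arange(d) if subset is None else np.asarray(subset)
    return NetworkModel(
        input_weights=W1,
        output_weights=w2,
        feature_subset=subset,
        feature_names=names or [f"X.f{i + 1}" for i in subset],
        scaler=FeatureScaler(mins=np.zeros(d), ranges=np.ones(d)),
    )


class TestActivations:
    def test_sigmoid_range_and_midpoint(self):
        assert sigmoid(0.0) == 0.5
        u = np.linspace(-30, 30, 101)
        s = sigmoid(u)
        assert np.all((s > 0) & (s < 1))
        assert np.all(np.diff(s) > 0)

    def test_output_is_identity(self):
        x = np.array([-2.5, 0.0, 7.1])
        assert np.array_equal(linear_output(x), x)


class TestScaler:
    def test_three_point_column(self):
        sc = fit_scaler(np.array([[2.0], [4.0], [6.0]]))
        assert np.allclose(sc.transform(np.array([[2.0], [4.0], [6.0]])).ravel(),
                           [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        sc = fit_scaler(np.array([[5.0], [5.0], [5.0]]))
        assert np.allclose(sc.transform(np.array([[5.0]])), 0.0)
        assert sc.ranges[0] == 1.0

    def test_random_column_order_statistics(self, rng):
        col = rng.normal(size=(40, 1))
        sc = fit_scaler(col)
        scaled = sc.transform(col).ravel()
        assert scaled.min() == 0.0 and scaled.max() == 1.0
        assert np.array_equal(np.argsort(scaled), np.argsort(col.ravel()))

    def test_out_of_range_extrapolates_without_clipping(self):
        sc = fit_scaler(np.array([[0.0], [10.0]]))
        assert sc.transform(np.array([[20.0]]))[0, 0] == 2.0
        assert sc.transform(np.array([[-10.0]]))[0, 0] == -1.0


class TestForward:
    def test_zero_weights_give_zero(self):
        net = manual_net(np.zeros((3, 2)), np.zeros(3))
        assert forward(net, [1.0, 2.0]) == 0.0

    def test_output_bias_passes_through_unit_activation(self):
        net = manual_net(np.zeros((3, 2)), [3.25, 0.0, 0.0])
        assert forward(net, [9.0, -4.0]) == 3.25

    def test_hand_set_two_by_two_matches_symbolic_evaluation(self):
        # |p|=2 inputs, H=2 sigmoid units; weights chosen by hand.
        W1 = np.array([[0.1, -0.2],   # biases w_{0,h}
                       [0.5, 0.3],    # w_{1,h}
                       [-0.4, 0.6]])  # w_{2,h}
        w2 = np.array([0.25, 1.5, -0.75])  # w_{0,o}, w_{1,o}, w_{2,o}
        x = [0.8, -0.3]

        def S(u):
            return math.exp(u) / (1.0 + math.exp(u))

        a1 = 0.1 + 0.5 * 0.8 + (-0.4) * (-0.3)
        a2 = -0.2 + 0.3 * 0.8 + 0.6 * (-0.3)
        expected = 0.25 + 1.5 * S(a1) + (-0.75) * S(a2)
        net = manual_net(W1, w2)
        assert forward(net, x) == pytest.approx(expected, abs=1e-12)

    def test_missing_feature_raises(self, toy_ds):
        cfg = TrainConfig(epochs=5, seed=0)
        net = train_network(toy_ds, [0, 1], hidden=3, cfg=cfg)
        bad = make_dataset(n=5, block_sizes={"G": 2})
        with pytest.raises(SchemaError):
            net.predict(bad)


class TestObjective:
    def test_perfect_fit_without_decay_is_zero(self):
        ds = make_dataset(n=4, block_sizes={"X": 1}, y=np.full(4, 1.5))
        net = manual_net(np.zeros((2, 2)), [1.5, 0.0, 0.0])
        net.config = TrainConfig(weight_decay=0.0)
        # the output bias reproduces the constant target exactly; lambda=0
        assert objective(net, ds) == pytest.approx(0.0, abs=1e-12)

    def test_zero_weight_net_with_decay(self):
        ds = make_dataset(n=6, block_sizes={"X": 2})
        net = manual_net(np.zeros((3, 3)), np.zeros(4))
        net.config = TrainConfig(weight_decay=0.7)
        assert objective(net, ds) == pytest.approx(float(ds.y @ ds.y), rel=1e-12)

    def test_matches_two_term_recomputation(self, rng):
        ds = make_dataset(n=25, seed=3)
        net = train_network(ds, [0, 2, 5], hidden=4, cfg=TrainConfig(epochs=20, seed=1))
        lam = net.config.weight_decay
        resid = ds.y - net.predict_matrix(ds.X)
        brute = sum(r * r for r in resid) + lam * (
            sum(w * w for w in net.input_weights.ravel())
            + sum(w * w for w in net.output_weights)
        )
        assert objective(net, ds) == pytest.approx(brute, abs=1e-10)

    def test_objective_decomposition(self):
        ds = make_dataset(n=20, seed=9)
        net = train_network(ds, [1, 3], hidden=5, cfg=TrainConfig(epochs=30, seed=2))
        lam = net.config.weight_decay
        norm2 = float(np.sum(net.input_weights**2) + np.sum(net.output_weights**2))
        resid = ds.y - net.predict_matrix(ds.X)
        assert objective(net, ds) - lam * norm2 == pytest.approx(float(resid @ resid), abs=1e-10)


class TestTraining:
    def test_training_reduces_objective_on_linear_toy(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(-1, 1, 50)
        ds = FeatureDataset(
            ids=[f"c{i}" for i in range(50)], affinities=x,
            features=x[:, None], feature_names=["X.f1"],
        )
        cfg = TrainConfig(epochs=200, seed=11)
        net = train_network(ds, [0], hidden=5, cfg=cfg)
        # objective at the random init, recomputed with an untrained clone
        rng_init = np.random.default_rng(cfg.seed)
        w0 = rng_init.uniform(-0.7, 0.7, size=2 * 4 + 5)
        init_net = manual_net(w0[:8].reshape(2, 4), w0[8:])
        init_net.scaler = net.scaler
        init_net.config = cfg
        assert objective(net, ds) < objective(init_net, ds)

    def test_zero_target_triggers_early_stop(self):
        ds = make_dataset(n=20, block_sizes={"X": 2}, y=np.zeros(20))
        cfg = TrainConfig(epochs=3000, weight_decay=0.0, seed=4)
        net = train_network(ds, [0, 1], hidden=3, cfg=cfg)
        assert objective(net, ds, targets=np.zeros(20)) < cfg.abstol

    def test_beats_constant_predictor_on_smooth_nonlinear_toy(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(-1.5, 1.5, 200)
        y = np.sin(3 * x) + x**2
        ds = FeatureDataset(
            ids=[f"c{i}" for i in range(200)], affinities=y,
            features=x[:, None], feature_names=["X.f1"],
        )
        net = train_network(ds, [0], hidden=10,
                            cfg=TrainConfig(epochs=500, weight_decay=1e-4, seed=6))
        train_rmse = float(np.sqrt(np.mean((y - net.predict_matrix(ds.X)) ** 2)))
        assert train_rmse < 0.5 * np.std(y)

    def test_retraining_is_bit_identical(self, toy_ds):
        cfg = TrainConfig(epochs=60, seed=77)
        a = train_network(toy_ds, [0, 3, 6], hidden=6, cfg=cfg)
        b = train_network(toy_ds, [0, 3, 6], hidden=6, cfg=cfg)
        assert np.array_equal(a.input_weights, b.input_weights)
        assert np.array_equal(a.output_weights, b.output_weights)

    def test_serialization_round_trip(self, toy_ds, tmp_path):
        net = train_network(toy_ds, [1, 2], hidden=4, cfg=TrainConfig(epochs=10, seed=3))
        p = tmp_path / "net.json"
        net.save(p)
        back = NetworkModel.load(p)
        assert np.array_equal(back.input_weights, net.input_weights)
        assert np.array_equal(back.output_weights, net.output_weights)
        assert back.feature_names == net.feature_names
        assert np.array_equal(back.predict(toy_ds), net.predict(toy_ds))

    def test_invalid_arguments(self, toy_ds):
        with pytest.raises(UsageError):
            train_network(toy_ds, [], hidden=4)
        with pytest.raises(UsageError):
            train_network(toy_ds, [0], hidden=1)
        with pytest.raises(UsageError):
            TrainConfig(epochs=0)
        with pytest.raises(UsageError):
            TrainConfig(abstol=0.0)
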