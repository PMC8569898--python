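"""Network initialization, gradients, training behavior, prediction."""

import numpy as np
import pytest

from keraopt.ann import (
    MLPModel,
    NetworkSpec,
    TrainConfig,
    initialize_network,
    loss_and_gradients,
    predict_network,
    train_network,
)
from keraopt.design import DesignMatrix, Factor, ResponseTable


def make_design(X, names=None):
    X = np.atleast_2d(X)
    names = names or [f"f{j}" for j in range(X.shape[1])]
    return DesignMatrix(factors=[Factor(n) for n in names], coded=X)


class TestInitialization:
    def test_seed_determinism(self):
        spec = NetworkSpec(3, (4, 5))
        a = initialize_network(spec, 7)
        b = initialize_network(spec, 7)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)
        c = initialize_network(spec, 8)
        assert any(not np.array_equal(wa, wc) for wa, wc in zip(a.weights, c.weights))

    def test_parameter_count(self):
        assert NetworkSpec(3, (4, 5)).n_parameters == 3 * 4 + 4 + 4 * 5 + 5 + 5 * 1 + 1
        assert NetworkSpec(2, (3,)).n_parameters == 2 * 3 + 3 + 3 + 1

    def test_invalid_widths(self):
        with pytest.raises(ValueError):
            NetworkSpec(3, (0, 5))


class TestGradients:
    @pytest.mark.parametrize(
        "spec",
        [NetworkSpec(3, (4, 5)), NetworkSpec(2, (3,)), NetworkSpec(1, (2, 2))],
        ids=["4x5", "3", "2x2"],
    )
    @pytest.mark.parametrize("lam", [0.0, 0.05])
    def test_backprop_matches_central_differences(self, spec, lam, rng):
        net = initialize_network(spec, 123)
        # non-trivial weights and biases
        for layer in range(len(net.weights)):
            net.weights[layer] = rng.normal(size=net.weights[layer].shape)
            net.biases[layer] = rng.normal(size=net.biases[layer].shape)
        X = rng.normal(size=(9, spec.input_size))
        t = rng.normal(size=(9, 1))
        _, dW, db = loss_and_gradients(net, X, t, lam)
        eps = 1e-6

        def loss_at():
            return loss_and_gradients(net, X, t, lam)[0]

        for layer in range(len(net.weights)):
            for arr, grad in ((net.weights[layer], dW[layer]), (net.biases[layer], db[layer])):
                flat = arr.ravel()
                gflat = np.asarray(grad).ravel()
                for idx in range(flat.size):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    hi = loss_at()
                    flat[idx] = orig - eps
                    lo = loss_at()
                    flat[idx] = orig
                    assert gflat[idx] == pytest.approx((hi - lo) / (2 * eps), abs=1e-6)


class TestTraining:
    def test_fixture_holdback_split_sizes(self, rccd):
        design, responses, _ = rccd
        cfg = TrainConfig(tours=5, restarts=1, seed=0)
        net, metrics = train_network(NetworkSpec(3), design, responses, cfg)
        assert metrics["training"].n == 22
        assert metrics["validation"].n == 18
        assert metrics["overall"].n == 40

    def test_random_holdback_fraction(self, rng):
        X = rng.normal(size=(40, 2))
        d = make_design(X)
        r = ResponseTable(response=rng.normal(size=40))
        cfg = TrainConfig(tours=5, restarts=1, holdback_fraction=0.45, seed=3)
        _, metrics = train_network(NetworkSpec(2), d, r, cfg)
        assert metrics["validation"].n == 18

    def test_learns_noise_free_linear_function(self, rng):
        X = rng.uniform(-1, 1, size=(40, 1))
        d = make_design(X)
        r = ResponseTable(response=2.0 * X.ravel())
        cfg = TrainConfig(tours=15_000, learning_rate=0.1, penalty_lambda=0.0,
                          restarts=2, seed=5)
        net, metrics = train_network(NetworkSpec(1, (2,)), d, r, cfg)
        assert metrics["validation"].r2 > 0.999

    def test_recovers_network_generated_function_majority_of_seeds(self, rng):
        # noise-free data from a random net of the same architecture must be
        # learnable on held-out points for most starting seeds
        spec = NetworkSpec(3, (4, 5))
        wins = 0
        for seed in range(5):
            teacher = initialize_network(spec, 100 + seed)
            X = rng.uniform(-1.5, 1.5, size=(40, 3))
            y = teacher.forward(X).ravel()
            d = make_design(X)
            r = ResponseTable(response=y)
            cfg = TrainConfig(tours=6000, penalty_lambda=0.0, restarts=2, seed=seed)
            _, metrics = train_network(spec, d, r, cfg)
            if metrics["validation"].r2 > 0.99:
                wins += 1
        assert wins >= 3

    def test_training_reduces_penalized_loss(self, rccd):
        design, responses, _ = rccd
        cfg = TrainConfig(tours=200, restarts=1, seed=0)
        net, _ = train_network(NetworkSpec(3), design, responses, cfg)
        assert net.history[-1] < net.history[0]

    def test_weight_penalty_monotonically_shrinks_weights(self, rng):
        X = rng.uniform(-1, 1, size=(30, 2))
        d = make_design(X)
        r = ResponseTable(response=np.sin(X[:, 0]) + X[:, 1] ** 2)
        norms = []
        for lam in (0.0, 0.01, 0.1, 1.0):
            cfg = TrainConfig(tours=2000, penalty_lambda=lam, restarts=1, seed=9)
            net, _ = train_network(NetworkSpec(2, (3,)), d, r, cfg)
            norms.append(sum(float(np.sum(w**2)) for w in net.weights))
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_divergence_raises(self, rng):
        X = rng.uniform(-1, 1, size=(20, 2))
        d = make_design(X)
        r = ResponseTable(response=rng.normal(size=20))
        cfg = TrainConfig(tours=500, learning_rate=50.0, restarts=1, seed=0)
        with pytest.raises(FloatingPointError, match="learning_rate"):
            train_network(NetworkSpec(2, (3,)), d, r, cfg)

    def test_invalid_holdback(self):
        with pytest.raises(ValueError):
            TrainConfig(holdback_fraction=0.0)


class TestPrediction:
    def test_deterministic_and_factor_checked(self, rccd):
        design, responses, _ = rccd
        cfg = TrainConfig(tours=50, restarts=1, seed=0)
        net, _ = train_network(NetworkSpec(3), design, responses, cfg)
        p1 = predict_network(net, design)
        p2 = predict_network(net, design)
        np.testing.assert_array_equal(p1, p2)
        other = make_design(design.coded, names=["x", "y", "z"])
        with pytest.raises(ValueError, match="factors"):
            predict_network(net, other)

    def test_zero_weights_predict_descaled_bias(self):
        spec = NetworkSpec(2, (3,))
        net = initialize_network(spec, 0)
        for layer in range(len(net.weights)):
            net.weights[layer][:] = 0.0
            net.biases[layer][:] = 0.0
        net.biases[-1][:] = 0.5
        net.y_mean, net.y_sd = 100.0, 10.0
        d = make_design(np.random.default_rng(0).normal(size=(5, 2)))
        pred = predict_network(net, d)
        np.testing.assert_allclose(pred, 100.0 + 10.0 * 0.5)

    def test_serialization_round_trip(self, rccd):
        design, responses, _ = rccd
        cfg = TrainConfig(tours=20, restarts=1, seed=0)
        net, _ = train_network(NetworkSpec(3), design, responses, cfg)
        clone = MLPModel.from_json(net.to_json())
        np.testing.assert_allclose(predict_network(clone, design), predict_network(net, design))
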