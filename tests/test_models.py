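"""RF, SVM, the numpy 1-D CNN and PSO under the shared fit/predict contract."""

import dataclasses

import numpy as np
import pytest

from leafspec.models import (CNNConfig, PSOConfig, cnn_fit,
                             cnn_parameter_count, pso_cnn_fit, pso_optimize,
                             rf_fit, svm_fit)
from leafspec.models.cnn import CNN1DRegressor


class TestRandomForest:
    def test_constant_response_predicted_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 5))
        b = rf_fit(X, np.full(30, 2.5), seed=1)
        np.testing.assert_allclose(b.predict(X), 2.5, atol=1e-12)

    def test_monotone_single_feature_signal_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.random((200, 15))
        y = 3.0 * X[:, 4] + 0.05 * rng.standard_normal(200)
        Xte = rng.random((100, 15))
        yte = 3.0 * Xte[:, 4]
        b = rf_fit(X, y, seed=2)
        pred = b.predict(Xte)
        ss = 1 - np.sum((pred - yte) ** 2) / np.sum((yte - yte.mean()) ** 2)
        assert ss >= 0.9

    def test_depth_constraint_honoured(self):
        rng = np.random.default_rng(2)
        X = rng.random((300, 5))
        y = rng.random(300)
        b = rf_fit(X, y, seed=3)
        assert all(est.tree_.max_depth <= 8 for est in b.model.estimators_)
        assert b.model.min_samples_leaf == 3
        assert len(b.model.estimators_) == 300

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            rf_fit(np.ones((4, 2)), np.ones(4))


class TestSVM:
    def test_grid_has_stated_exponent_counts(self):
        assert len(list(range(-5, 10))) == 15     # C exponents -5..9
        assert len(list(range(-15, 2))) == 17     # gamma exponents -15..1

    def test_sine_of_one_feature_learned(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-2, 2, (300, 3))
        y = np.sin(2.0 * X[:, 0]) + 0.02 * rng.standard_normal(300)
        b = svm_fit(X, y, seed=4)
        Xte = rng.uniform(-2, 2, (150, 3))
        yte = np.sin(2.0 * Xte[:, 0])
        pred = b.predict(Xte)
        r2 = 1 - np.sum((pred - yte) ** 2) / np.sum((yte - yte.mean()) ** 2)
        assert r2 >= 0.85
        # selected gamma strictly inside the searched exponent range
        assert 2.0 ** -15 < b.hyperparameters["gamma"] < 2.0 ** 1

    def test_feature_scaling_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.random((60, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + 0.05 * rng.standard_normal(60)
        b1 = svm_fit(X, y, seed=6)
        X2 = X.copy()
        X2[:, 1] *= 10.0
        b2 = svm_fit(X2, y, seed=6)
        assert b1.hyperparameters["C"] == b2.hyperparameters["C"]
        assert b1.hyperparameters["gamma"] == b2.hyperparameters["gamma"]
        Xq = rng.random((10, 4))
        Xq2 = Xq.copy()
        Xq2[:, 1] *= 10.0
        np.testing.assert_allclose(b1.predict(Xq), b2.predict(Xq2), atol=1e-8)

    def test_zero_variance_response_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            svm_fit(np.random.default_rng(0).random((20, 3)), np.ones(20))


class TestCNN:
    def test_memorizes_tiny_training_set(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((5, 15))
        y = rng.standard_normal(5)
        cfg = CNNConfig(seed=1, dropout=0.0, l2_lambda=0.0, max_iterations=2000,
                        early_stop_patience=0, lr_decay_factor=1.0,
                        validation_fraction=0.0)
        net = CNN1DRegressor(cfg).fit(X, y)
        assert np.sqrt(np.mean((net.predict(X) - y) ** 2)) <= 0.02

    def test_parameter_count_matches_closed_form(self):
        cfg = CNNConfig(seed=0)
        net = CNN1DRegressor(cfg)
        net.params = net._init_params(15, np.random.default_rng(0))
        # independent hand arithmetic for p=15, size-2 stride-1 pools:
        # conv1 8*(3)+8; conv2 8*(8*3)+8; pooled length 15->14->13 so
        # fc 8*13*32+32; out 32+1
        expected = (8 * 3 + 8) + (8 * 24 + 8) + (104 * 32 + 32) + 33
        assert net.n_parameters() == expected == cnn_parameter_count(15, cfg)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((4, 11))
        y = rng.standard_normal(4)
        net = CNN1DRegressor(CNNConfig(seed=2, dropout=0.0, l2_lambda=0.0))
        net.params = net._init_params(11, np.random.default_rng(2))
        pred, cache = net._forward(X)
        grads = net._backward(2.0 * (pred - y) / len(y), cache)

        def loss():
            p, _ = net._forward(X)
            return float(np.mean((p - y) ** 2))

        for key in ("W1", "W2", "W3", "W4", "b1", "b3"):
            flat = net.params[key].ravel()
            for idx in [0, flat.size // 2, flat.size - 1]:
                orig = flat[idx]
                flat[idx] = orig + 1e-6
                lp = loss()
                flat[idx] = orig - 1e-6
                lm = loss()
                flat[idx] = orig
                num = (lp - lm) / 2e-6
                assert abs(num - grads[key].ravel()[idx]) < 1e-6

    def test_training_loss_converges(self, selected_features):
        d = selected_features
        b = cnn_fit(d["Xtr"], d["ytr"], CNNConfig(seed=3), n_restarts=1)
        hist = b.history["train_rmse"]
        assert hist[-1] < hist[10]

    def test_same_seed_reproduces_predictions(self, selected_features):
        d = selected_features
        cfg = CNNConfig(seed=4, max_iterations=60)
        p1 = cnn_fit(d["Xtr"], d["ytr"], cfg, n_restarts=2).predict(d["Xte"])
        p2 = cnn_fit(d["Xtr"], d["ytr"], cfg, n_restarts=2).predict(d["Xte"])
        np.testing.assert_array_equal(p1, p2)

    def test_too_short_input_raises(self):
        with pytest.raises(ValueError, match="too short"):
            CNN1DRegressor(CNNConfig(seed=0)).fit(
                np.ones((10, 2)), np.ones(10))

    def test_non_finite_loss_aborts_with_diagnostics(self):
        # an absurd learning rate overflows the weights within a few steps;
        # training must abort loudly rather than return a silent NaN model
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 12))
        y = rng.standard_normal(20)
        cfg = CNNConfig(seed=5, learning_rate=1e150, max_iterations=5,
                        validation_fraction=0.0, dropout=0.0)
        with pytest.raises(FloatingPointError, match="non-finite"):
            with np.errstate(all="ignore"):
                CNN1DRegressor(cfg).fit(X, y)


class TestPSO:
    def test_sphere_function_minimized_across_seed_battery(self):
        target = np.array([0.3, 0.62, 0.18])
        hits = 0
        for seed in range(10):
            cfg = PSOConfig(swarm_size=20, iterations=15,
                            lower=np.zeros(3), upper=np.ones(3), seed=seed)
            res = pso_optimize(lambda x, j, it: float(((x - target) ** 2).sum()),
                               cfg)
            hits += res.best_fitness <= 1e-3
        assert hits >= 9

    def test_positions_remain_within_bounds(self):
        cfg = PSOConfig(swarm_size=8, iterations=10,
                        lower=np.array([-1.0, 0.0]), upper=np.array([1.0, 2.0]),
                        seed=0)
        res = pso_optimize(lambda x, j, it: float((x ** 2).sum()), cfg)
        assert np.all(res.positions_visited >= cfg.lower - 1e-12)
        assert np.all(res.positions_visited <= cfg.upper + 1e-12)

    def test_gbest_trace_non_increasing(self):
        cfg = PSOConfig(swarm_size=6, iterations=12, lower=np.zeros(2),
                        upper=np.ones(2), seed=1)
        res = pso_optimize(lambda x, j, it: float((x ** 2).sum()), cfg)
        assert np.all(np.diff(res.gbest_trace) <= 1e-15)

    def test_warm_start_row_used(self):
        x0 = np.array([0.5, 0.5])
        cfg = PSOConfig(swarm_size=5, iterations=1, lower=np.zeros(2),
                        upper=np.ones(2), seed=2, x0=x0)
        seen = []
        pso_optimize(lambda x, j, it: seen.append((j, x.copy())) or 0.0, cfg)
        np.testing.assert_allclose(seen[0][1], x0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="lower < upper"):
            PSOConfig(lower=np.ones(2), upper=np.zeros(2))


class TestPSOCNN:
    @pytest.fixture(scope="class")
    def small_search(self, selected_features):
        d = selected_features
        cnn_cfg = CNNConfig(seed=11, max_iterations=80, early_stop_patience=30)
        pso_cfg = PSOConfig(swarm_size=4, iterations=3)
        bundle = pso_cnn_fit(d["Xtr"], d["ytr"], cnn_config=cnn_cfg,
                             pso_config=pso_cfg, seed=99)
        return d, cnn_cfg, pso_cfg, bundle

    def test_fitness_matrix_shape_matches_config(self, small_search):
        _, _, pso_cfg, bundle = small_search
        assert bundle.metadata["fitness_matrix_shape"] == [3, 4]

    def test_best_fitness_not_worse_than_baseline_particle(self, small_search):
        _, _, _, bundle = small_search
        assert (bundle.metadata["pso_best_fitness"]
                <= bundle.metadata["baseline_fitness"] + 1e-12)

    def test_hyperparameters_within_search_bounds(self, small_search):
        _, _, _, bundle = small_search
        assert 5e-4 <= bundle.hyperparameters["learning_rate"] <= 1e-2
        assert 16 <= bundle.hyperparameters["batch_size"] <= 512
        assert 1e-4 <= bundle.hyperparameters["l2_lambda"] <= 1e-1

    def test_default_fitness_never_reads_test_targets(self, selected_features):
        # leakage guard: without paper_mode the eval_set argument is ignored
        d = selected_features
        cnn_cfg = CNNConfig(seed=12, max_iterations=40, early_stop_patience=20)
        pso_cfg = PSOConfig(swarm_size=3, iterations=2)
        b1 = pso_cnn_fit(d["Xtr"], d["ytr"], eval_set=None,
                         cnn_config=cnn_cfg, pso_config=pso_cfg, seed=5)
        garbage = (d["Xte"], np.full_like(d["yte"], 99.0))
        b2 = pso_cnn_fit(d["Xtr"], d["ytr"], eval_set=garbage,
                         cnn_config=cnn_cfg, pso_config=pso_cfg, seed=5)
        np.testing.assert_array_equal(b1.predict(d["Xte"]), b2.predict(d["Xte"]))
        assert b1.metadata["fitness_on"] == "inner_validation"

    def test_paper_mode_flagged_in_metadata(self, selected_features):
        d = selected_features
        cnn_cfg = CNNConfig(seed=13, max_iterations=30, early_stop_patience=15)
        pso_cfg = PSOConfig(swarm_size=2, iterations=2)
        b = pso_cnn_fit(d["Xtr"], d["ytr"], eval_set=(d["Xte"], d["yte"]),
                        cnn_config=cnn_cfg, pso_config=pso_cfg,
                        paper_mode=True, seed=6)
        assert b.metadata["paper_mode"] is True
        assert b.metadata["fitness_on"] == "test"


def test_bundle_rejects_wrong_feature_dimension(selected_features):
    d = selected_features
    b = rf_fit(d["Xtr"], d["ytr"], seed=0)
    with pytest.raises(ValueError, match="features"):
        b.predict(d["Xte"][:, :3])
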