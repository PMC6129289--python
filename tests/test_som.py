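import numpy as np
import pytest

from somcoding import TrainConfig
from somcoding.som import (
    MinMaxScaler,
    OutputLayer,
    SomGrid,
    SomModel,
    bmu,
    forward_train,
    gradients,
    loss,
    predict,
    sigma_t,
    sigmoid,
    som_init,
    train,
)


def tiny_model(seed=0, m=4, rows=2, cols=2, positive_out=False, bias=0.0):
    rng = np.random.default_rng(seed)
    W = rng.normal(0, 1, size=(rows * cols, m))
    if positive_out:
        Wout = rng.uniform(0.05, 0.3, size=(rows * cols, 2))
    else:
        Wout = rng.uniform(-0.5, 0.5, size=(rows * cols, 2))
    grid = SomGrid(rows, cols, W)
    out = OutputLayer(Wout, np.full(2, bias))
    cfg = TrainConfig(rows=rows, cols=cols, seed=seed, scale=False)
    return SomModel(grid=grid, out=out, config=cfg)


class TestGrid:
    def test_manhattan_distance_properties(self):
        g = SomGrid(3, 4, np.zeros((12, 2)))
        D = g.distance_matrix()
        assert np.all(np.diag(D) == 0)
        np.testing.assert_array_equal(D, D.T)
        # triangle inequality over all unit triples
        assert np.all(D[:, None, :] <= D[:, :, None] + D[None, :, :] + 1e-12)
        assert g.radius == 3 + 4 - 2

    def test_bmu_identity_and_tie_break(self):
        W = np.array([[0.0, 0], [1, 1], [2, 2]])
        g = SomGrid(1, 3, W)
        assert bmu(W[1][None], g.weights)[0] == 1
        # equidistant between units 0 and 1 -> lowest index wins
        assert bmu(np.array([[0.5, 0.5]]), g.weights)[0] == 0


class TestSomInit:
    def test_single_point_converges_to_it(self):
        x = np.array([[3.0, -2.0, 1.0]])
        g = som_init(x, 3, 3, epochs=40, seed=0)
        assert np.abs(g.weights - x).max() < 0.05

    def test_quantization_error_decreases(self):
        rng = np.random.default_rng(1)
        centers = rng.normal(0, 5, size=(9, 6))
        X = np.repeat(centers, 20, axis=0) + rng.normal(0, 0.1, size=(180, 6))
        def qe(grid):
            from scipy.spatial.distance import cdist
            return cdist(X, grid.weights, "sqeuclidean").min(axis=1).mean()
        early = som_init(X, 3, 3, epochs=1, seed=2)
        late = som_init(X, 3, 3, epochs=20, seed=2)
        assert qe(late) < qe(early)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            som_init(np.zeros((0, 3)), 2, 2, epochs=1, seed=0)


class TestSigma:
    def test_self_neighborhood_is_one(self):
        m = tiny_model()
        for t in (0, 100, 9999):
            assert sigma_t(1, 1, t, m.config, m.grid) == pytest.approx(1.0)

    def test_decreasing_in_time_and_distance(self):
        m = tiny_model()
        early = sigma_t(0, 3, 10, m.config, m.grid)
        late = sigma_t(0, 3, 9000, m.config, m.grid)
        assert late < early
        near = sigma_t(0, 1, 10, m.config, m.grid)
        far = sigma_t(0, 3, 10, m.config, m.grid)
        assert far < near

    def test_defined_at_final_iteration(self):
        m = tiny_model()
        v = sigma_t(0, 3, m.config.max_iterations - 1, m.config, m.grid)
        assert 0.0 <= v < 1.0 and np.isfinite(v)


class TestForward:
    def test_sigmoid_at_zero(self):
        assert sigmoid(np.zeros(1))[0] == 0.5

    def test_outputs_in_open_interval(self):
        m = tiny_model()
        X = np.random.default_rng(0).normal(size=(5, 4))
        _, O = forward_train(X, m, t=0)
        assert np.all((O > 0) & (O < 1))

    def test_single_unit_reduces_to_kernel(self):
        rng = np.random.default_rng(3)
        w = rng.normal(size=(1, 4))
        grid = SomGrid(1, 1, w)
        out = OutputLayer(np.zeros((1, 2)), np.zeros(2))
        model = SomModel(grid=grid, out=out,
                         config=TrainConfig(rows=1, cols=1, scale=False))
        X = rng.normal(size=(6, 4))
        A, _ = forward_train(X, model, t=0)
        expected = np.exp(-0.5 * ((X - w) ** 2).sum(axis=1, keepdims=True))
        np.testing.assert_allclose(A, expected)

    def test_prototype_match_contributes_fully(self):
        m = tiny_model(seed=5)
        x = m.grid.weights[2][None]
        A, _ = forward_train(x, m, t=0)
        # unit 2's kernel term is exp(0)=1, weighted by sigma into each unit
        sig_row = np.array([sigma_t(2, u, 0, m.config, m.grid) for u in range(4)])
        assert np.all(A[0] >= sig_row - 1e-12)


class TestLoss:
    def test_perfect_prediction_zero_ce(self):
        m = tiny_model()
        m.out.weights[:] = 0
        m.config.lambda_reg = 1e-300  # isolate the cross-entropy term
        Y = np.array([[1.0, 0], [0, 1]])
        O = np.array([[1.0 - 1e-12, 1e-12], [1e-12, 1.0 - 1e-12]])
        assert loss(Y, O, m) == pytest.approx(0.0, abs=1e-9)

    def test_uninformative_outputs_closed_form(self):
        # o = 0.5 everywhere: each sample contributes 2 ln 2 (both outputs)
        m = tiny_model()
        m.out.weights[:] = 0
        m.config.lambda_reg = 1e-300
        Y = np.array([[1.0, 0]] * 4)
        O = np.full((4, 2), 0.5)
        assert loss(Y, O, m) == pytest.approx(2 * np.log(2))

    def test_regularizer_isolated_and_nonnegative(self):
        m = tiny_model(seed=2)
        Y = np.array([[1.0, 0]])
        O = np.array([[1.0 - 1e-12, 1e-12]])
        expected = m.config.lambda_reg * (m.out.weights**2).sum()
        assert loss(Y, O, m) == pytest.approx(expected, rel=1e-6)
        assert loss(Y, O, m) >= 0


class TestGradients:
    @staticmethod
    def finite_difference(f, P, eps=1e-6):
        g = np.zeros_like(P)
        it = np.nditer(P, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = P[i]
            P[i] = old + eps
            fp = f()
            P[i] = old - eps
            fm = f()
            P[i] = old
            g[i] = (fp - fm) / (2 * eps)
        return g

    @pytest.mark.parametrize("seed", range(5))
    def test_output_and_bias_gradients_match_fd(self, seed):
        rng = np.random.default_rng(seed)
        m = tiny_model(seed=seed)
        X = m.grid.weights[rng.integers(4, size=6)] + rng.normal(0, 0.05, (6, 4))
        Y = np.zeros((6, 2))
        Y[np.arange(6), rng.integers(2, size=6)] = 1
        t = 3
        gW, gb, _ = gradients(X, Y, m, t)

        def f():
            _, O = forward_train(X, m, t)
            return loss(Y, O, m)

        fW = self.finite_difference(f, m.out.weights)
        fb = self.finite_difference(f, m.out.biases)
        assert np.abs(gW - fW).max() <= 1e-5 * max(np.abs(fW).max(), 1e-8)
        assert np.abs(gb - fb).max() <= 1e-5 * max(np.abs(fb).max(), 1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_som_gradient_is_descent_direction(self, seed):
        rng = np.random.default_rng(seed + 100)
        m = tiny_model(seed=seed, positive_out=True, bias=-2.0)
        m.grid.weights *= 4  # well-separated prototypes: BMU term dominates
        X = m.grid.weights[rng.integers(4, size=8)] + rng.normal(0, 0.05, (8, 4))
        Y = np.zeros((8, 2))
        Y[np.arange(8), rng.integers(2, size=8)] = 1
        t = 3
        _, _, gS = gradients(X, Y, m, t)

        def f():
            _, O = forward_train(X, m, t)
            return loss(Y, O, m)

        before = f()
        m.grid.weights -= 1e-4 * gS
        assert f() <= before + 1e-12


class TestTrain:
    def test_zero_learning_rate_keeps_weights(self, separable_dataset):
        d = separable_dataset
        idx = d["train_idx"][:120]
        cfg = TrainConfig(seed=4, mu1=0.0, max_iterations=20)
        model = train(d["X"][idx], d["Y"][idx], cfg)
        ref = train(d["X"][idx], d["Y"][idx],
                    TrainConfig(seed=4, mu1=0.0, max_iterations=1))
        np.testing.assert_array_equal(model.out.weights, ref.out.weights)
        np.testing.assert_array_equal(model.grid.weights, ref.grid.weights)

    def test_loss_trace_decreases_early(self, default_model):
        trace = default_model.loss_trace
        assert len(trace) >= 10
        k = min(len(trace) // 2, 50)
        assert trace[k : 2 * k].mean() < trace[:k].mean() + 1e-9

    def test_single_class_warns(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        Y = np.tile([1.0, 0.0], (20, 1))
        with pytest.warns(UserWarning, match="single class"):
            train(X, Y, TrainConfig(rows=2, cols=2, seed=0, scale=False,
                                    max_iterations=5, batch_size=10))

    def test_invalid_labels_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError, match="one-hot"):
            train(X, np.full((3, 2), 0.5), TrainConfig(rows=2, cols=2, seed=0))


class TestPredict:
    def test_argmax_rule_and_tie_to_noncoding(self):
        from somcoding.rejection import classify
        assert classify(0.9, 0.1) == "coding"
        assert classify(0.5, 0.5) == "noncoding"
        assert classify(0.1, 0.9) == "noncoding"

    def test_one_unit_grid_is_logistic_regression_on_kernel(self):
        rng = np.random.default_rng(8)
        w = rng.normal(size=(1, 3))
        wout = rng.normal(size=(1, 2))
        b = rng.normal(size=2)
        model = SomModel(
            grid=SomGrid(1, 1, w),
            out=OutputLayer(wout.copy(), b.copy()),
            config=TrainConfig(rows=1, cols=1, scale=False),
        )
        X = rng.normal(size=(10, 3))
        O, bmus, _ = predict(X, model)
        phi = np.exp(-0.5 * ((X - w) ** 2).sum(axis=1, keepdims=True))
        expected = 1.0 / (1.0 + np.exp(-(phi @ wout + b)))
        np.testing.assert_allclose(O, expected)
        assert np.all(bmus == 0)

    def test_dimension_mismatch_raises(self, default_model):
        with pytest.raises(ValueError, match="dimension"):
            predict(np.zeros((2, 7)), default_model)

    def test_training_set_recovered(self, separable_dataset, default_model):
        d = separable_dataset
        idx = d["train_idx"]
        _, _, classes = predict(d["X"][idx], default_model)
        assert (np.array(classes) == d["labels"][idx]).mean() >= 0.95


class TestScaler:
    def test_gated_minmax_and_bandwidth(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([
            rng.uniform(0, 1, 100),        # natural scale: untouched
            rng.uniform(100, 900, 100),    # unbounded: min-max scaled
        ])
        sc = MinMaxScaler.fit(X)
        Xs = sc.transform(X)
        assert Xs.min() >= -1e-9
        np.testing.assert_allclose(sc.data_range[0], 1.0)  # gate left col 0 alone
        assert sc.data_range[1] > 1.0
        # median pairwise squared distance calibrated to the target
        from scipy.spatial.distance import cdist
        d2 = cdist(Xs[:100], Xs[:100], "sqeuclidean")
        med = np.median(d2[np.triu_indices(100, 1)])
        assert med == pytest.approx(MinMaxScaler.TARGET_MEDIAN_SQDIST, rel=1e-6)


class TestPersistence:
    def test_save_load_roundtrip(self, default_model, tmp_path):
        p = tmp_path / "model.somc"
        default_model.save(p)
        back = SomModel.load(p)
        np.testing.assert_array_equal(back.grid.weights, default_model.grid.weights)
        np.testing.assert_array_equal(back.out.weights, default_model.out.weights)
        np.testing.assert_array_equal(back.out.biases, default_model.out.biases)
        assert back.config == default_model.config
        assert back.scaler.bandwidth == default_model.scaler.bandwidth
        assert back.stop_reason == default_model.stop_reason

    def test_layout_version_mismatch_refused(self, default_model, tmp_path):
        p = tmp_path / "model.somc"
        import dataclasses
        stale = dataclasses.replace(default_model,
                                    feature_layout_version="other-layout-0")
        stale.save(p)
        with pytest.raises(ValueError, match="feature layout"):
            SomModel.load(p)
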