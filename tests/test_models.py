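import numpy as np
import pytest

from mvpakit.models import (
    BuildError,
    LayerSpec,
    ModelSpec,
    build_model,
    classify_wta,
    leaky_relu,
    load_model,
    predict_scores,
    save_model,
    smlr_fit,
    smlr_objective,
    train,
)


# ---------------------------------------------------------------------------
# SMLR vs brute-force oracle
# ---------------------------------------------------------------------------


def grid_oracle_binary(X, y, lam, span=5.0, grid=101, rounds=9):
    """Brute-force reference for 2-class, 1-feature SMLR: an iteratively
    refined dense grid over (w, b) in [-span, span]^2 minimizing the binary
    logistic NLL + lam*|w|.  The penalized softmax optimum coincides with
    this binary optimum (antisymmetric weight split)."""
    x = np.asarray(X, dtype=float).ravel()
    y = np.asarray(y)

    def obj(w, b):
        z = x * w + b
        nll = np.mean(np.log1p(np.exp(-np.abs(z)))
                      + np.where(y == 1, np.maximum(-z, 0), np.maximum(z, 0)))
        return nll + lam * abs(w)

    lo_w, hi_w, lo_b, hi_b = -span, span, -span, span
    best = np.inf
    for _ in range(rounds):
        ws = np.linspace(lo_w, hi_w, grid)
        bs = np.linspace(lo_b, hi_b, grid)
        vals = np.array([[obj(w, b) for b in bs] for w in ws])
        i, j = np.unravel_index(vals.argmin(), vals.shape)
        best, bw, bb = vals[i, j], ws[i], bs[j]
        dw, db = (hi_w - lo_w) / 10, (hi_b - lo_b) / 10
        lo_w, hi_w, lo_b, hi_b = bw - dw, bw + dw, bb - db, bb + db
    return best


SMLR_FIXTURES = [
    (np.array([[-2.0], [-1.0], [-0.5], [0.5], [1.5], [2.5]]),
     np.array([0, 0, 0, 1, 1, 1])),
    (np.array([[-1.0], [0.0], [1.0], [2.0]]), np.array([0, 1, 0, 1])),
    (np.array([[0.3], [-0.2], [1.1], [-0.9], [0.6], [-0.4], [2.0], [-1.5]]),
     np.array([1, 0, 1, 0, 1, 0, 1, 0])),
]


class TestSMLR:
    @pytest.mark.parametrize("X,y", SMLR_FIXTURES)
    @pytest.mark.parametrize("lam", [0.01, 0.1, 0.5])
    def test_objective_matches_grid_oracle(self, X, y, lam):
        oracle = grid_oracle_binary(X, y, lam)
        res = smlr_fit(X, y, lam=lam, max_iter=5000, tol=1e-12)
        assert res.objective <= oracle + 1e-6

    def test_huge_lambda_gives_uniform_scores(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 4))
        y = np.arange(30) % 3  # balanced
        res = smlr_fit(X, y, lam=100.0, max_iter=500)
        assert np.all(res.W[1:] == 0)
        from mvpakit.models import softmax_scores

        scores = softmax_scores(res.W, X)
        np.testing.assert_allclose(scores, 1 / 3, atol=1e-6)

    def test_sparsity_monotone_in_lambda(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 8))
        w_true = np.zeros((8, 3))
        w_true[:3] = rng.standard_normal((3, 3)) * 2
        y = (X @ w_true).argmax(axis=1)
        nnz = []
        for lam in [0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0]:
            res = smlr_fit(X, y, lam=lam, max_iter=3000, tol=1e-11)
            nnz.append(int(np.count_nonzero(res.W[1:])))
        assert nnz == sorted(nnz, reverse=True)

    def test_soft_threshold_yields_exact_zeros(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 10))
        y = (X[:, 0] > 0).astype(int)
        res = smlr_fit(X, y, lam=0.1, max_iter=2000)
        assert np.count_nonzero(res.W[1:]) < res.W[1:].size

    def test_nonconvergence_flagged_not_raised(self):
        X, y = SMLR_FIXTURES[0]
        res = smlr_fit(X, y, lam=0.01, max_iter=2, tol=1e-15)
        assert res.converged is False

    def test_objective_helper_consistent(self):
        X, y = SMLR_FIXTURES[0]
        res = smlr_fit(X, y, lam=0.1, max_iter=3000, tol=1e-12)
        assert smlr_objective(res.W, X, y, 0.1) == pytest.approx(res.objective, abs=1e-10)


# ---------------------------------------------------------------------------
# Classical backends via the common surface
# ---------------------------------------------------------------------------


def separable_2class():
    X = np.array([[-2.0, -1.5], [-1.0, -2.0], [-1.5, -0.5],
                  [2.0, 1.5], [1.0, 2.0], [1.5, 0.5]])
    y = np.array([0, 0, 0, 1, 1, 1])
    return X, y


class TestClassical:
    def test_svm_defaults_linear_kernel_c_one(self):
        spec = ModelSpec(backend="classical", algorithm="svm")
        kind, impl, _, _ = build_model(spec, (4,), 3)
        assert kind == "svm" and impl.C == 1.0 and impl.kernel == "linear"

    @pytest.mark.parametrize("algorithm", ["svm", "smlr"])
    def test_separable_data_reaches_training_accuracy_one(self, algorithm):
        X, y = separable_2class()
        hp = {"lambda": 0.001} if algorithm == "smlr" else {}
        spec = ModelSpec(backend="classical", algorithm=algorithm, hyperparams=hp)
        tm = train(build_model(spec, (2,), 2), X, y)
        pred = classify_wta(predict_scores(tm, X))
        np.testing.assert_array_equal(pred, y)

    def test_svm_ovr_every_example_gets_one_label(self, small_benchmark):
        spec = ModelSpec(backend="classical", algorithm="svm")
        X = small_benchmark.data
        y = small_benchmark.attribute("condition")
        tm = train(build_model(spec, X.shape[1:], 3), X, y)
        scores = predict_scores(tm, X[:20])
        assert scores.shape == (20, 3)
        labels = classify_wta(scores)
        assert labels.shape == (20,) and set(labels) <= {0, 1, 2}

    def test_smlr_scores_are_probabilities(self):
        X, y = separable_2class()
        spec = ModelSpec(backend="classical", algorithm="smlr")
        tm = train(build_model(spec, (2,), 2), X, y)
        scores = predict_scores(tm, X)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)

    def test_single_class_labels_rejected(self):
        spec = ModelSpec(backend="classical", algorithm="svm")
        with pytest.raises(ValueError, match="single class"):
            train(build_model(spec, (2,), 2), np.zeros((4, 2)), np.zeros(4, dtype=int))


# ---------------------------------------------------------------------------
# Winner-take-all
# ---------------------------------------------------------------------------


class TestWTA:
    def test_argmax_row(self):
        assert classify_wta(np.array([[0.1, 0.7, 0.2]]))[0] == 1

    def test_tie_breaks_toward_lowest_index(self):
        assert classify_wta(np.array([[0.5, 0.5, 0.0]]))[0] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_wta(np.empty((0, 3)))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_wta(np.array([[np.nan, 1.0]]))


# ---------------------------------------------------------------------------
# Deep backend
# ---------------------------------------------------------------------------


def small_deep_spec(n_classes=2, epochs=200, lr=0.05, seed=0):
    return ModelSpec(
        backend="deep",
        layers=[
            LayerSpec("dense", {"units": 16}, activation="leaky_relu"),
            LayerSpec("dense", {"units": n_classes}, activation="softmax"),
        ],
        optimizer={"kind": "sgd", "lr": lr, "momentum": 0.9, "nesterov": True},
        training={"epochs": epochs, "batch_size": 8, "seed": seed},
    )


class TestDeep:
    def test_leaky_relu_pointwise(self):
        x = np.array([-2.0, -0.5, 0.0, 0.7, 3.0])
        np.testing.assert_allclose(leaky_relu(x, 0.3), [-0.6, -0.15, 0.0, 0.7, 3.0])
        np.testing.assert_allclose(leaky_relu(x, 0.1), [-0.2, -0.05, 0.0, 0.7, 3.0])

    def test_wrong_final_width_is_build_error(self):
        spec = ModelSpec(backend="deep", layers=[
            LayerSpec("dense", {"units": 5}, activation="softmax")])
        with pytest.raises(BuildError, match="n_classes"):
            build_model(spec, (4,), 3)

    def test_dense_on_unflattened_input_names_layer(self):
        spec = ModelSpec(backend="deep", layers=[
            LayerSpec("dense", {"units": 3}, activation="softmax")])
        with pytest.raises(BuildError, match="dense layer 0"):
            build_model(spec, (4, 5), 3)

    def test_conv_kernel_rank_exceeding_input_rank_rejected(self):
        spec = ModelSpec(backend="deep", layers=[
            LayerSpec("conv", {"filters": 2, "kernel": [3, 3]}),
            LayerSpec("flatten"),
            LayerSpec("dense", {"units": 2}, activation="softmax")])
        with pytest.raises(BuildError, match="kernel rank"):
            build_model(spec, (10,), 2)

    def test_dropout_rate_bounds(self):
        with pytest.raises(ValueError, match="rate"):
            LayerSpec("dropout", {"rate": 1.0})

    def test_conv_8x20_on_32x1000_builds(self):
        spec = ModelSpec(backend="deep", layers=[
            LayerSpec("conv", {"filters": 4, "kernel": [8, 20]}, activation="leaky_relu"),
            LayerSpec("pool", {"size": [5, 49]}),
            LayerSpec("flatten"),
            LayerSpec("dense", {"units": 3}, activation="softmax")])
        kind, net, _, _ = build_model(spec, (32, 1000), 3)
        assert kind == "deep"
        # filters span 8 channels x 20 timepoints -> (25, 981, 4) feature map
        assert net.layers[0].W.shape == (8, 20, 1, 4)

    def test_memorization_on_tiny_set(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 6))
        y = rng.integers(0, 2, size=20)
        y[:2] = [0, 1]  # both classes present
        tm = train(build_model(small_deep_spec(epochs=400, lr=0.1), (6,), 2), X, y)
        assert tm.history["accuracy"][-1] == 1.0
        scores = predict_scores(tm, X)
        np.testing.assert_array_equal(classify_wta(scores), y)

    def test_scores_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 6))
        y = np.arange(12) % 2
        tm = train(build_model(small_deep_spec(epochs=20), (6,), 2), X, y)
        np.testing.assert_allclose(predict_scores(tm, X).sum(axis=1), 1.0, atol=1e-6)

    def test_same_spec_and_seed_identical_scores(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((16, 6))
        y = np.arange(16) % 2
        out = []
        for _ in range(2):
            tm = train(build_model(small_deep_spec(epochs=30, seed=5), (6,), 2), X, y)
            out.append(predict_scores(tm, X))
        np.testing.assert_array_equal(out[0], out[1])

    def test_history_recorded_per_epoch_with_validation(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((16, 6))
        y = np.arange(16) % 2
        tm = train(build_model(small_deep_spec(epochs=7), (6,), 2),
                   X[:12], y[:12], X[12:], y[12:])
        assert len(tm.history["loss"]) == 7
        assert len(tm.history["val_accuracy"]) == 7

    @pytest.mark.parametrize("shape,layers", [
        ((20,), [LayerSpec("conv", {"filters": 3, "kernel": [5]}, activation="leaky_relu"),
                 LayerSpec("flatten"),
                 LayerSpec("dense", {"units": 8}, activation="leaky_relu"),
                 LayerSpec("dropout", {"rate": 0.3}),
                 LayerSpec("dense", {"units": 2}, activation="softmax")]),
        ((6, 8), [LayerSpec("conv", {"filters": 3, "kernel": [2, 3]}, activation="leaky_relu"),
                  LayerSpec("conv", {"filters": 2, "kernel": [2, 2]}, activation="relu"),
                  LayerSpec("flatten"),
                  LayerSpec("dense", {"units": 8}, activation="tanh"),
                  LayerSpec("dense", {"units": 2}, activation="softmax")]),
    ])
    def test_reference_conv_dense_architectures_train_on_2d_and_3d(self, shape, layers):
        """1-2 conv + 2-3 dense stacks build and train on vector and array examples."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((24, *shape))
        y = np.arange(24) % 2
        spec = ModelSpec(backend="deep", layers=layers,
                         optimizer={"kind": "adam", "lr": 0.01},
                         training={"epochs": 5, "batch_size": 8, "seed": 0})
        tm = train(build_model(spec, shape, 2), X, y)
        assert predict_scores(tm, X).shape == (24, 2)

    def test_recurrent_layer_trains_on_sequences(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((20, 10, 3))
        y = (X[:, :, 0].mean(axis=1) > 0).astype(int)
        spec = ModelSpec(backend="deep", layers=[
            LayerSpec("recurrent", {"cells": 6}),
            LayerSpec("dense", {"units": 2}, activation="softmax")],
            optimizer={"kind": "adam", "lr": 0.02},
            training={"epochs": 30, "batch_size": 8, "seed": 1})
        tm = train(build_model(spec, (10, 3), 2), X, y)
        assert tm.history["accuracy"][-1] > 0.6

    def test_intermediate_softmax_rejected(self):
        spec = ModelSpec(backend="deep", layers=[
            LayerSpec("dense", {"units": 4}, activation="softmax"),
            LayerSpec("dense", {"units": 2}, activation="softmax")])
        with pytest.raises(BuildError, match="final layer"):
            build_model(spec, (4,), 2)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


class TestSerialization:
    @pytest.mark.parametrize("algorithm", ["svm", "smlr"])
    def test_classical_round_trip(self, tmp_path, algorithm):
        X, y = separable_2class()
        spec = ModelSpec(backend="classical", algorithm=algorithm)
        tm = train(build_model(spec, (2,), 2), X, y)
        path = save_model(tm, tmp_path / "m.npz")
        reloaded = load_model(path)
        np.testing.assert_allclose(predict_scores(reloaded, X),
                                   predict_scores(tm, X), atol=1e-10)

    def test_deep_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((16, 6))
        y = np.arange(16) % 2
        tm = train(build_model(small_deep_spec(epochs=10), (6,), 2), X, y)
        reloaded = load_model(save_model(tm, tmp_path / "net.npz"))
        np.testing.assert_allclose(predict_scores(reloaded, X),
                                   predict_scores(tm, X), atol=1e-12)
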