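import numpy as np
import pytest

from henvox.classify import (
    CVResult,
    KernelSpec,
    TrainConfig,
    cross_validate,
    grid_search,
    kernel_eval,
    kernel_matrix,
    load_model,
    predict,
    sequential_feature_selection,
    train,
)


def separable_data(n_per_class=20, seed=0, n_features=9):
    """Four well-separated Gaussian clusters in feature space."""
    rng = np.random.default_rng(seed)
    centres = {
        "alarm": 0.0, "gakel": 6.0, "squawk": 12.0, "others": 18.0,
    }
    X, y = [], []
    for label, c in centres.items():
        X.append(rng.normal(c, 0.5, size=(n_per_class, n_features)))
        y.extend([label] * n_per_class)
    return np.vstack(X), np.asarray(y, dtype=object)


class TestKernelEval:
    def test_rbf_identity_is_one(self):
        x = np.arange(9.0)
        assert kernel_eval(x, x, KernelSpec(kind="rbf", gamma=0.2)) == 1.0

    def test_polynomial_orthogonal_vectors(self):
        x = np.array([1.0, 0.0]); y = np.array([0.0, 1.0])
        spec = KernelSpec(kind="polynomial", gamma=0.2, coef0=1.0, degree=3)
        assert kernel_eval(x, y, spec) == pytest.approx(1.0)

    @pytest.mark.parametrize("kind", ["polynomial", "rbf", "sigmoid"])
    def test_matches_term_by_term_oracle(self, kind):
        rng = np.random.default_rng(1)
        spec = KernelSpec(kind=kind, gamma=0.37, coef0=0.5, degree=4)
        for _ in range(20):
            x, y = rng.normal(size=9), rng.normal(size=9)
            dot = sum(a * b for a, b in zip(x, y))
            if kind == "polynomial":
                expected = (0.37 * dot + 0.5) ** 4
            elif kind == "rbf":
                expected = np.exp(-0.37 * sum((a - b) ** 2 for a, b in zip(x, y)))
            else:
                expected = np.tanh(0.37 * dot + 0.5)
            assert kernel_eval(x, y, spec) == pytest.approx(expected, abs=1e-12)
            assert kernel_matrix(x[None], y[None], spec)[0, 0] == pytest.approx(
                expected, abs=1e-10)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            kernel_eval(np.ones(3), np.ones(4), KernelSpec())


class TestTrainPredict:
    def test_separable_clusters_perfect_training_accuracy(self):
        X, y = separable_data()
        model = train(X, y, TrainConfig())
        assert (predict(model, X) == y).all()

    def test_one_binary_machine_per_class(self):
        X, y = separable_data()
        model = train(X, y)
        assert len(model.machines) == 4
        assert model.classes == ("alarm", "gakel", "squawk", "others")

    def test_duplication_invariance(self):
        X, y = separable_data(12)
        base = predict(train(X, y), X)
        doubled = predict(train(np.vstack([X, X]), np.concatenate([y, y])), X)
        assert (base == doubled).all()

    def test_single_class_rejected(self):
        X = np.zeros((10, 9))
        with pytest.raises(ValueError):
            train(X, np.asarray(["alarm"] * 10, dtype=object))

    def test_shuffled_sample_order_gives_identical_predictions(self):
        X, y = separable_data(15, seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        base = predict(train(X, y), X)
        shuffled = predict(train(X[perm], y[perm]), X)
        assert (base == shuffled).all()

    def test_empty_input_predicts_empty(self):
        X, y = separable_data(10)
        model = train(X, y)
        assert len(predict(model, np.empty((0, 9)))) == 0

    def test_nan_features_imputed_with_training_median(self):
        X, y = separable_data(20, seed=4)
        X[::7, 3] = np.nan
        model = train(X, y)
        assert np.isfinite(model.impute_values).all()
        assert (predict(model, X) == y).mean() > 0.9

    def test_json_round_trip_predicts_identically(self, tmp_path):
        X, y = separable_data(15, seed=5)
        model = train(X, y)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = load_model(path)
        Xq = np.random.default_rng(6).normal(6.0, 4.0, size=(30, 9))
        assert (predict(model, Xq) == predict(loaded, Xq)).all()
        np.testing.assert_allclose(model.decision_values(Xq),
                                   loaded.decision_values(Xq), atol=1e-8)


class TestCrossValidate:
    def test_fold_sizes_balanced_at_2368(self):
        """5 folds over 2368 items differ in size by at most 1."""
        rng = np.random.default_rng(7)
        # class sizes mirroring a realistic imbalanced label set
        sizes = {"alarm": 917, "gakel": 110, "squawk": 750, "others": 591}
        X = rng.normal(size=(2368, 3))
        y = np.asarray([c for c, n in sizes.items() for _ in range(n)],
                       dtype=object)
        offsets = {"alarm": 0, "gakel": 5, "squawk": 10, "others": 15}
        for i, label in enumerate(y):
            X[i] += offsets[label]
        res = cross_validate(X, y, TrainConfig(k_folds=5, seed=1))
        fold_sizes = [m.sum() for m in res.fold_matrices]
        assert sum(fold_sizes) == 2368
        assert max(fold_sizes) - min(fold_sizes) <= 1

    def test_perfect_classifier_gives_diagonal_pooled_matrix(self):
        X, y = separable_data(25, seed=8)
        res = cross_validate(X, y, TrainConfig(k_folds=5, seed=2))
        assert res.pooled.sum() == 100
        assert np.count_nonzero(res.pooled - np.diag(np.diag(res.pooled))) == 0
        mm = res.metric_mean_sd()
        assert mm["sensitivity"]["macro"] == 100.0
        assert mm["precision"]["macro"] == 100.0

    def test_fold_metric_means_recomputable_from_stored_matrices(self):
        X, y = separable_data(15, seed=9)
        X += np.random.default_rng(10).normal(0, 2.0, X.shape)  # imperfect
        res = cross_validate(X, y, TrainConfig(k_folds=3, seed=3))
        mm = res.metric_mean_sd()
        for ci, c in enumerate(res.classes):
            per_fold = []
            for m in res.fold_matrices:
                row = m[ci].sum()
                if row:
                    per_fold.append(100.0 * m[ci, ci] / row)
            assert mm["sensitivity"]["per_class"][c]["mean"] == pytest.approx(
                np.mean(per_fold))

    def test_class_smaller_than_k_raises_naming_class(self):
        X, y = separable_data(10)
        y[y == "gakel"] = "alarm"
        y[:3] = "gakel"
        with pytest.raises(ValueError, match="gakel"):
            cross_validate(X, y, TrainConfig(k_folds=5))

    def test_same_seed_reproduces_pooled_matrix(self):
        X, y = separable_data(15, seed=11)
        X += np.random.default_rng(12).normal(0, 1.5, X.shape)
        a = cross_validate(X, y, TrainConfig(k_folds=5, seed=42))
        b = cross_validate(X, y, TrainConfig(k_folds=5, seed=42))
        assert np.array_equal(a.pooled, b.pooled)

    def test_no_leakage_of_test_fold_statistics(self):
        """An extreme outlier confined to one fold's test portion must not
        move the training-fold standardisation statistics."""
        X, y = separable_data(15, seed=13)
        folds = TrainConfig(k_folds=5, seed=0)
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        train_idx, test_idx = next(skf.split(X, y))
        X_out = X.copy()
        X_out[test_idx[0]] = 1e6  # poison a test-fold-only row
        m_clean = train(X[train_idx], y[train_idx], folds)
        m_poison = train(X_out[train_idx], y[train_idx], folds)
        np.testing.assert_array_equal(m_clean.loc, m_poison.loc)
        np.testing.assert_array_equal(m_clean.scale, m_poison.scale)


class TestFeatureSelection:
    def test_dominant_feature_selected_first(self):
        rng = np.random.default_rng(14)
        n = 160
        y = np.asarray(["alarm", "gakel", "squawk", "others"] * (n // 4),
                       dtype=object)
        X = rng.normal(size=(n, 5))
        informative = {"alarm": 0.0, "gakel": 5.0, "squawk": 10.0, "others": 15.0}
        X[:, 2] = [informative[c] for c in y] + rng.normal(0, 0.3, n)
        order, curve = sequential_feature_selection(X, y, TrainConfig(seed=1))
        assert order[0] == 2
        assert len(curve) == 5
        assert curve[0] <= max(curve) + 1e-9

    def test_curve_length_equals_feature_count(self):
        X, y = separable_data(10, n_features=4)
        order, curve = sequential_feature_selection(X, y, TrainConfig(seed=2))
        assert len(order) == len(curve) == 4
        assert sorted(order) == [0, 1, 2, 3]


class TestGridSearch:
    def test_singleton_grid_returns_that_config(self):
        X, y = separable_data(10)
        cfg, results = grid_search(
            X, y, kernel_kinds=("rbf",), C_grid=(2.0,), gamma_grid=(0.5,),
            degree_grid=(3,), coef0_grid=(0.0,), base_cfg=TrainConfig(seed=3),
        )
        assert cfg.kernel.kind == "rbf" and cfg.C == 2.0
        assert len(results) == 1

    def test_winner_score_is_table_maximum(self):
        X, y = separable_data(10, seed=15)
        cfg, results = grid_search(
            X, y, kernel_kinds=("polynomial", "rbf"), C_grid=(0.1, 1.0),
            gamma_grid=(0.2,), degree_grid=(3,), coef0_grid=(1.0,),
            base_cfg=TrainConfig(seed=4),
        )
        best_score = max(r["score"] for r in results)
        winner = [r for r in results if r["config"] == cfg]
        assert winner and winner[0]["score"] == best_score

    def test_perfect_config_found_on_separable_fixture(self):
        X, y = separable_data(15, seed=16)
        cfg, _ = grid_search(
            X, y, kernel_kinds=("polynomial", "rbf"), C_grid=(1.0,),
            gamma_grid=(0.2,), degree_grid=(3,), coef0_grid=(1.0,),
            base_cfg=TrainConfig(seed=5),
        )
        res = cross_validate(X, y, cfg)
        assert res.metric_mean_sd()["sensitivity"]["macro"] == 100.0
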