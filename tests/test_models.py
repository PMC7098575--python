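"""Network builders, the transfer-learning recipe, CV protocol and search."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from gexmap.tl_models import (
    ModelSpec,
    bayesian_search,
    build_cnn,
    build_mlnn,
    make_nn_pipeline,
    pretrain_finetune,
    repeated_cv,
    run_ml_baseline,
)


def _blob_images(n, size, seed, signal=2.0):
    """Images whose top-left quadrant mean carries the class signal."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, size, size)).astype(np.float32)
    half = size // 2
    X[y == 1, :half, :half] += signal
    return X, y


def _signal_vectors(n, p, seed, signal=1.5, informative=5):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, p))
    X[y == 1, :informative] += signal
    return X, y


class TestBuildCnn:
    def test_parameter_count_matches_hand_formula(self):
        spec = ModelSpec(kind="cnn", conv_filters=(8,), kernel_sizes=(5,),
                         pool_sizes=(2,), dense_units=(16,), dropout=0.0)
        model = build_cnn(spec, (20, 20))
        conv = 8 * (5 * 5 * 1) + 8            # weights + biases
        flat = 8 * ((20 - 4) // 2) ** 2        # 8 x 8 x 8
        dense1 = flat * 16 + 16
        head = 16 * 1 + 1
        assert model.n_params() == conv + dense1 + head

    def test_output_is_probability(self):
        model = build_cnn(ModelSpec(kind="cnn"), (16, 16))
        proba = model.predict_proba(np.random.default_rng(0).normal(size=(5, 16, 16)))
        assert proba.shape == (5,)
        assert ((proba > 0) & (proba < 1)).all()

    def test_overfits_tiny_separable_set(self):
        X, y = _blob_images(20, 12, seed=0, signal=3.0)
        spec = ModelSpec(kind="cnn", conv_filters=(4,), kernel_sizes=(3,),
                         pool_sizes=(2,), dense_units=(8,), dropout=0.0, seed=1)
        model = build_cnn(spec, (12, 12))
        model.fit(X, y, epochs=60, lr=1e-3, batch_size=8, seed=1)
        assert roc_auc_score(y, model.predict_proba(X)) == 1.0

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            build_cnn(ModelSpec(kind="cnn", kernel_sizes=(9,)), (8, 8))

    def test_wrong_kind_rejected(self):
        with pytest.raises(ValueError):
            build_cnn(ModelSpec(kind="mlnn"), (8, 8))


class TestBuildMlnn:
    def test_parameter_count_with_batch_norm(self):
        spec = ModelSpec(kind="mlnn", dense_units=(32, 8), dropout=0.1, batch_norm=True)
        model = build_mlnn(spec, 100)
        expected = (100 * 32 + 32) + 2 * 32 + (32 * 8 + 8) + 2 * 8 + (8 * 1 + 1)
        assert model.n_params() == expected

    def test_output_is_probability(self):
        model = build_mlnn(ModelSpec(kind="mlnn"), 30)
        proba = model.predict_proba(np.random.default_rng(1).normal(size=(7, 30)))
        assert ((proba > 0) & (proba < 1)).all()

    def test_overfits_tiny_separable_set(self):
        X, y = _signal_vectors(20, 10, seed=3, signal=3.0)
        spec = ModelSpec(kind="mlnn", dense_units=(16,), dropout=0.0, seed=2)
        model = build_mlnn(spec, 10)
        model.fit(X, y, epochs=80, lr=1e-2, batch_size=10, seed=2)
        assert roc_auc_score(y, model.predict_proba(X)) == 1.0


class TestPretrainFinetune:
    def test_zero_finetune_epochs_returns_pretrained_model(self):
        Xb, yb = _signal_vectors(40, 12, seed=4)
        Xt, yt = _signal_vectors(20, 12, seed=5)
        spec = ModelSpec(kind="mlnn", dense_units=(8,), finetune_epochs=0,
                         pretrain_epochs=5, seed=3)
        factory = lambda s: build_mlnn(s, 12)
        model = pretrain_finetune(factory, (Xb, yb), (Xt, yt), spec)
        reference = pretrain_finetune(factory, (Xb, yb), (Xt[:0], yt[:0]), spec)
        for w1, w2 in zip(model.get_weights(), reference.get_weights()):
            for k in w1:
                np.testing.assert_array_equal(w1[k], w2[k])

    def test_shape_mismatch_between_phases_rejected(self):
        Xb, yb = _signal_vectors(30, 10, seed=6)
        Xt, yt = _signal_vectors(30, 12, seed=7)
        with pytest.raises(ValueError, match="shape"):
            pretrain_finetune(lambda s: build_mlnn(s, 10), (Xb, yb), (Xt, yt),
                              ModelSpec(kind="mlnn"))

    def test_deterministic_given_fixed_seeds(self):
        Xb, yb = _signal_vectors(40, 10, seed=8)
        Xt, yt = _signal_vectors(24, 10, seed=9)
        spec = ModelSpec(kind="mlnn", dense_units=(8,), pretrain_epochs=3,
                         finetune_epochs=3, seed=12)
        factory = lambda s: build_mlnn(s, 10)
        p1 = pretrain_finetune(factory, (Xb, yb), (Xt, yt), spec).predict_proba(Xt)
        p2 = pretrain_finetune(factory, (Xb, yb), (Xt, yt), spec).predict_proba(Xt)
        np.testing.assert_array_equal(p1, p2)


def _logistic_pipeline(X_tr, y_tr, X_va, seed):
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(max_iter=500).fit(X_tr, y_tr)
    return clf.predict_proba(X_va)[:, 1], clf.predict_proba(X_tr)[:, 1]


class TestRepeatedCV:
    def test_ten_repeats_five_folds_emit_fifty_records(self):
        X, y = _signal_vectors(120, 8, seed=10)
        result = repeated_cv(X, y, _logistic_pipeline, repeats=10, folds=5, seed=1)
        assert len(result.records) == 50
        assert result.records.groupby("repeat").size().eq(5).all()

    def test_two_folds_partition_the_samples(self):
        X, y = _signal_vectors(40, 5, seed=11)
        seen = []

        def recording_pipeline(X_tr, y_tr, X_va, seed):
            seen.append((len(X_tr), len(X_va)))
            return _logistic_pipeline(X_tr, y_tr, X_va, seed)

        result = repeated_cv(X, y, recording_pipeline, repeats=1, folds=2, seed=2)
        assert len(result.records) == 2
        assert all(tr + va == 40 for tr, va in seen)

    def test_stratification_within_one_sample_of_global_fraction(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(100, 4))
        y = np.array([1] * 20 + [0] * 80)

        def counting_pipeline(X_tr, y_tr, X_va, seed):
            va_len = len(X_va)
            positives = 20 - y_tr.sum()
            expected = 20 * va_len / 100
            assert abs(positives - expected) <= 1
            return _logistic_pipeline(X_tr, y_tr, X_va, seed)

        repeated_cv(X, y, counting_pipeline, repeats=2, folds=5, seed=3)

    def test_class_too_small_to_stratify_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        y = np.array([1, 1] + [0] * 8)
        with pytest.raises(ValueError, match="stratification"):
            repeated_cv(X, y, _logistic_pipeline, repeats=1, folds=3)

    def test_nn_pipeline_runs_in_cv(self):
        X, y = _signal_vectors(60, 12, seed=13, signal=2.0)
        spec = ModelSpec(kind="mlnn", dense_units=(8,), pretrain_epochs=0,
                         finetune_epochs=10)
        result = repeated_cv(X, y, make_nn_pipeline(spec), repeats=1, folds=3, seed=4)
        assert len(result.records) == 3
        assert result.mean_auc() > 0.7


class TestMlBaselines:
    def test_anova_lr_on_separable_data(self):
        X, y = _signal_vectors(90, 40, seed=14, signal=3.0)
        result = run_ml_baseline("anova-k-best", "lr", X, y, repeats=1, folds=3,
                                 seed=5, n_components=10)
        assert result.mean_auc() > 0.95

    def test_twelve_combinations_enumerable(self):
        from gexmap.tl_models import _CLASSIFIERS, _REDUCERS

        assert len(_REDUCERS) * len(_CLASSIFIERS) == 12

    def test_unknown_combination_rejected(self):
        X, y = _signal_vectors(40, 10, seed=15)
        with pytest.raises(ValueError, match="unknown reducer"):
            run_ml_baseline("tsne", "lr", X, y, repeats=1, folds=2)
        with pytest.raises(ValueError, match="unknown classifier"):
            run_ml_baseline("pca", "gbm", X, y, repeats=1, folds=2)

    def test_anova_selection_matches_f_statistic_ranking(self):
        from scipy.stats import f_oneway
        from gexmap.tl_models import _make_reducer

        rng = np.random.default_rng(16)
        X = rng.normal(size=(60, 10))
        y = rng.integers(0, 2, 60)
        X[y == 1, 3] += 2.0
        X[y == 1, 7] += 1.0
        reducer = _make_reducer("anova-k-best", 2, 0).fit(X, y)
        chosen = set(np.flatnonzero(reducer.get_support()))
        f_stats = [f_oneway(X[y == 0, j], X[y == 1, j]).statistic for j in range(10)]
        expected = set(np.argsort(f_stats)[-2:])
        assert chosen == expected

    def test_fold_fitting_prevents_selection_leakage(self):
        """On pure noise, fitting the reducer inside the folds keeps AUC near
        chance, while selecting features on the full data inflates it."""
        rng = np.random.default_rng(17)
        X = rng.normal(size=(60, 400))
        y = np.array([0, 1] * 30)
        proper = run_ml_baseline("anova-k-best", "lr", X, y, repeats=2, folds=3,
                                 seed=6, n_components=10)

        from sklearn.feature_selection import SelectKBest, f_classif

        leaky_X = SelectKBest(f_classif, k=10).fit_transform(X, y)
        leaky = run_ml_baseline("pca", "lr", leaky_X, y, repeats=2, folds=3,
                                seed=6, n_components=10)
        assert leaky.mean_auc() > proper.mean_auc() + 0.1
        assert abs(proper.mean_auc() - 0.5) < 0.15


class TestBayesianSearch:
    def test_quadratic_objective_near_grid_optimum(self):
        objective = lambda cfg: -(cfg["x"] - 0.7) ** 2
        best, log = bayesian_search({"x": (0.0, 1.0)}, objective, iterations=20, seed=0)
        grid = np.linspace(0, 1, 1001)
        grid_best = grid[np.argmax(-(grid - 0.7) ** 2)]
        value_range = 0.7 ** 2  # objective range over the box
        assert abs(objective(best) - (-(grid_best - 0.7) ** 2)) <= 0.05 * value_range
        assert len(log) == 20

    def test_single_iteration_returns_single_sample(self):
        best, log = bayesian_search({"x": (0.0, 1.0)}, lambda c: c["x"],
                                    iterations=1, seed=1)
        assert len(log) == 1
        assert best["x"] == log["x"].iloc[0]

    def test_trial_sequence_is_seeded(self):
        objective = lambda cfg: -(cfg["x"] - 0.3) ** 2
        _, log1 = bayesian_search({"x": (0.0, 1.0)}, objective, iterations=8, seed=5)
        _, log2 = bayesian_search({"x": (0.0, 1.0)}, objective, iterations=8, seed=5)
        np.testing.assert_array_equal(log1["x"], log2["x"])

    def test_mixed_space_types(self):
        space = {"lr": (1e-4, 1e-1), "units": (4, 64, "int"), "kind": ["a", "b"]}
        best, log = bayesian_search(space, lambda c: c["lr"], iterations=5, seed=2)
        assert 4 <= best["units"] <= 64 and isinstance(best["units"], int)
        assert best["kind"] in ("a", "b")

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            bayesian_search({}, lambda c: 0.0, iterations=3)
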