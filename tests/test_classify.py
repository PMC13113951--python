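"""Feature matrix, classifiers, cross-validation, and metrics."""

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

from conftest import quiet_noise
from paglucose.classify import (
    KNNConfig,
    WideNetConfig,
    build_feature_matrix,
    cross_validate,
    holdout_evaluate,
    knn_predict,
    macro_f1,
    stratified_folds,
    wide_net_fit_predict,
)
from paglucose.synth import DatasetConfig, NoiseModel, simulate_dataset


class TestFeatureMatrix:
    def test_default_shape(self, default_dataset):
        m = build_feature_matrix(default_dataset)
        assert m.X.shape == (72, 187)
        assert m.X.size == 13464
        assert m.classes.size == 12
        assert len(m.row_meta) == 72

    def test_single_observation(self):
        cfg = DatasetConfig(days=(1,), classes_mgdl=(85.0,), rounds=1)
        m = build_feature_matrix(simulate_dataset(cfg))
        assert m.X.shape == (1, 187)


class TestKNN:
    def test_query_equals_training_row(self):
        X = np.array([[0.0, 0.0], [10.0, 0.0]])
        y = np.array(["a", "b"])
        assert knn_predict(X, y, X[1:2])[0] == "b"

    def test_two_point_geometry(self):
        X = np.array([[0.0], [10.0]])
        y = np.array(["A", "B"])
        assert knn_predict(X, y, np.array([[3.0]]))[0] == "A"

    def test_tie_breaks_to_lowest_training_index(self):
        # brute-force check: query equidistant from rows 0 and 2
        X = np.array([[0.0], [5.0], [2.0]])
        y = np.array(["a", "b", "c"])
        q = np.array([[1.0]])
        d = np.abs(X - q.T).ravel()
        assert d[0] == d[2]  # genuine tie
        assert knn_predict(X, y, q)[0] == "a"

    def test_matches_sklearn_on_random_data(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 8))
        y = rng.integers(0, 4, 40)
        q = rng.normal(size=(15, 8))
        ours = knn_predict(X, y, q, k=1)
        ref = KNeighborsClassifier(n_neighbors=1).fit(X, y).predict(q)
        np.testing.assert_array_equal(ours, ref)

    def test_k3_majority(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0]])
        y = np.array(["a", "a", "b", "b"])
        assert knn_predict(X, y, np.array([[0.0]]), k=3)[0] == "a"

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            knn_predict(np.empty((0, 3)), np.array([]), np.ones((1, 3)))


class TestWideNet:
    def test_separable_classes_memorised(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (20, 5)), rng.normal(8, 0.1, (20, 5))])
        y = np.array(["lo"] * 20 + ["hi"] * 20)
        pred = wide_net_fit_predict(X, y, X, WideNetConfig(seed=0))
        assert (pred == y).all()

    def test_deterministic_under_seed(self, default_dataset):
        m = build_feature_matrix(default_dataset)
        cfg = WideNetConfig(seed=3)
        p1 = wide_net_fit_predict(m.X[:60], m.y[:60], m.X[60:], cfg)
        p2 = wide_net_fit_predict(m.X[:60], m.y[:60], m.X[60:], cfg)
        np.testing.assert_array_equal(p1, p2)

    def test_rejects_nonfinite(self):
        X = np.ones((4, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            wide_net_fit_predict(X, np.array([1, 1, 2, 2]), np.ones((1, 3)))


class TestFolds:
    def test_fold_sizes_72_by_10(self):
        y = np.repeat(np.arange(12), 6)
        fold = stratified_folds(y, 10, seed=0)
        sizes = np.bincount(fold, minlength=10)
        assert sorted(sizes) == [7] * 8 + [8] * 2

    def test_classes_spread_across_folds(self):
        y = np.repeat(np.arange(12), 6)
        fold = stratified_folds(y, 10, seed=1)
        for cls in range(12):
            per_fold = np.bincount(fold[y == cls], minlength=10)
            assert per_fold.max() <= 1

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(np.arange(5), 10, seed=0)


class TestCrossValidate:
    def test_oracle_classifier_is_perfect(self, default_dataset):
        m = build_feature_matrix(default_dataset)
        lookup = {tuple(row): label for row, label in zip(m.X, m.y)}

        def oracle_fit_predict(tx, ty, qx):
            return np.array([lookup[tuple(row)] for row in qx])

        report = cross_validate(m, oracle_fit_predict, n_folds=10, seed=0)
        assert report.accuracy == 100.0
        assert np.all(report.confusion == np.diag(np.full(12, 6)))

    def test_out_of_fold_coverage(self, default_dataset):
        m = build_feature_matrix(default_dataset)
        report = cross_validate(m, KNNConfig(), n_folds=10, seed=2)
        assert report.n_evaluated == 72
        assert report.fold_assignments.shape == (72,)
        assert np.bincount(report.fold_assignments).sum() == 72
        assert report.confusion.sum(axis=1).tolist() == [6] * 12

    def test_noiseless_limit_is_perfect(self, noiseless_dataset):
        m = build_feature_matrix(noiseless_dataset)
        report = cross_validate(m, KNNConfig(), n_folds=10, seed=0)
        assert report.accuracy == 100.0

    def test_accuracy_degrades_with_gain_jitter(self):
        """CV accuracy is non-increasing as round jitter grows 0.5->4%."""
        means = []
        for jitter in (0.005, 0.01, 0.02, 0.04):
            accs = []
            for seed in range(10):
                cfg = DatasetConfig(
                    noise=NoiseModel(round_jitter_rel=jitter, seed=seed)
                )
                m = build_feature_matrix(simulate_dataset(cfg))
                accs.append(cross_validate(m, KNNConfig(), 10, seed).accuracy)
            means.append(np.mean(accs))
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))


class TestHoldout:
    def test_one_per_class_counts(self, default_dataset):
        m = build_feature_matrix(default_dataset)
        report = holdout_evaluate(m, KNNConfig(), "one-per-class", seed=0)
        assert report.n_evaluated == 12

    def test_fraction_counts(self, default_dataset):
        m = build_feature_matrix(default_dataset)
        report = holdout_evaluate(m, KNNConfig(), 0.1, seed=0)
        assert report.n_evaluated == 7

    def test_metric_matches_11_of_12(self):
        # accuracy of 11 correct out of 12 held-out rows
        conf = np.diag(np.ones(12, dtype=int))
        conf[0, 0] = 0
        conf[0, 1] = 1
        assert 100.0 * np.trace(conf) / conf.sum() == pytest.approx(91.7, abs=0.05)


class TestMacroF1:
    def test_perfect_diagonal(self):
        assert macro_f1(np.diag([5, 5, 5])) == 100.0

    def test_two_class_uniform(self):
        assert macro_f1(np.array([[1, 1], [1, 1]])) == pytest.approx(50.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        conf = rng.integers(0, 6, (5, 5))
        conf += np.eye(5, dtype=int)
        perm = rng.permutation(5)
        assert macro_f1(conf) == pytest.approx(macro_f1(conf[np.ix_(perm, perm)]))

    def test_empty_class_excluded(self):
        conf = np.array([[3, 0, 0], [0, 2, 0], [0, 0, 0]])
        assert macro_f1(conf) == 100.0
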