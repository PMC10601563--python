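"""Cross-validated classification, the printed metric formulas, importance."""

import numpy as np
import pytest

import kneemorph as km
from kneemorph.classify import ConfusionCounts


def separable_data(n_per_class=100, n_noise=5, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, cls in enumerate(("D", "T", "C")):
        block = rng.normal(0, 1, size=(n_per_class, n_noise + 1))
        block[:, 0] = i * 10 + rng.normal(0, 0.5, n_per_class)
        X.append(block)
        y += [cls] * n_per_class
    return np.vstack(X), np.array(y)


class TestCrossval:
    def test_separable_data_high_accuracy(self):
        X, y = separable_data()
        for algo in ("RF", "GB"):
            _, metrics, _ = km.crossval_classify(X, y, km.ModelSpec(algorithm=algo))
            assert metrics.accuracy > 95.0, algo

    def test_deterministic_under_seed(self):
        X, y = separable_data(30)
        a = km.crossval_classify(X, y, km.ModelSpec(seed=3))
        b = km.crossval_classify(X, y, km.ModelSpec(seed=3))
        assert np.array_equal(a[0].matrix, b[0].matrix)
        assert np.array_equal(a[2], b[2])

    def test_shuffled_labels_near_chance(self):
        X, y = separable_data(50)
        accs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            _, metrics, _ = km.crossval_classify(
                X, rng.permutation(y), km.ModelSpec(seed=seed)
            )
            accs.append(metrics.accuracy)
        assert abs(np.mean(accs) - 100.0 / 3.0) < 8.0

    def test_k_larger_than_n_rejected(self):
        X, y = separable_data(2)
        with pytest.raises(ValueError, match="10-fold"):
            km.crossval_classify(X, y, k=10)

    def test_pooled_equals_summed_per_fold_confusions(self):
        X, y = separable_data(40, seed=2)
        counts, metrics, folds = km.crossval_classify(X, y, km.ModelSpec(seed=1))
        # recompute the per-fold confusions from the pooled assignment
        spec = km.ModelSpec(seed=1)
        total = None
        for fold in np.unique(folds):
            test_idx = np.flatnonzero(folds == fold)
            train_idx = np.flatnonzero(folds != fold)
            model = spec.build()
            model.fit(X[train_idx], y[train_idx])
            pred = model.predict(X[test_idx])
            m = np.zeros((3, 3), int)
            index = {c: i for i, c in enumerate(counts.classes)}
            for t, g in zip(y[test_idx], pred):
                m[index[t], index[g]] += 1
            piece = ConfusionCounts(counts.classes, m)
            total = piece if total is None else total.add(piece)
        assert np.array_equal(total.matrix, counts.matrix)
        summed_metrics = km.classification_metrics(total)
        assert summed_metrics.accuracy == metrics.accuracy


class TestMetrics:
    def test_perfect_predictor_all_100(self):
        counts = ConfusionCounts(["C", "D", "T"], np.diag([8, 23, 16]))
        metrics = km.classification_metrics(counts)
        assert metrics.accuracy == 100.0
        for stats in metrics.per_class.values():
            assert stats == {"precision": 100.0, "recall": 100.0, "f1": 100.0}

    def test_hand_evaluated_counts(self):
        # one-vs-rest: TP=8, FP=2, FN=2, TN=35
        matrix = np.array([[8, 1, 1], [1, 20, 0], [1, 0, 15]])
        counts = ConfusionCounts(["D", "T", "C"], matrix)
        ovr = counts.one_vs_rest("D")
        assert ovr == {"TP": 8, "FP": 2, "FN": 2, "TN": 35}
        metrics = km.classification_metrics(counts)
        assert metrics.per_class["D"]["precision"] == pytest.approx(80.0)
        assert metrics.per_class["D"]["recall"] == pytest.approx(80.0)
        assert metrics.per_class["D"]["f1"] == pytest.approx(80.0)

    def test_f1_is_harmonic_mean_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            matrix = rng.integers(1, 30, size=(3, 3))
            metrics = km.classification_metrics(ConfusionCounts(["a", "b", "c"], matrix))
            for stats in metrics.per_class.values():
                pr, re = stats["precision"], stats["recall"]
                if pr + re > 0:
                    assert stats["f1"] == pytest.approx(2 * pr * re / (pr + re))

    def test_undefined_precision_reported_zero_with_warning(self):
        matrix = np.array([[0, 5], [0, 7]])  # first class never predicted
        with pytest.warns(UserWarning, match="precision undefined"):
            metrics = km.classification_metrics(ConfusionCounts(["a", "b"], matrix))
        assert metrics.per_class["a"]["precision"] == 0.0

    def test_ovr_counts_sum_to_total(self):
        matrix = np.array([[5, 2, 1], [0, 9, 3], [2, 2, 6]])
        counts = ConfusionCounts(["a", "b", "c"], matrix)
        for cls in counts.classes:
            assert sum(counts.one_vs_rest(cls).values()) == counts.total


class TestImportance:
    def test_planted_signal_dominates(self):
        rng = np.random.default_rng(0)
        n = 240
        X = rng.normal(size=(n, 96))
        y = np.array(["D", "T", "C"] * (n // 3))
        X[:, 17] = np.where(y == "D", 0.0, np.where(y == "T", 5.0, 10.0))
        X[:, 17] += rng.normal(0, 0.3, n)
        report = km.feature_importance(X, y, km.ModelSpec(seed=0), n_repeats=2)
        ranked = report.ranked()
        assert ranked[0][0] == "f17"
        assert ranked[0][1] > 50.0

    def test_all_noise_no_dominant_feature(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(150, 40))
        y = np.array(["D", "T", "C"] * 50)
        report = km.feature_importance(X, y, km.ModelSpec(seed=1), n_repeats=2)
        assert max(report.per_feature.values()) < 15.0
        assert sum(report.per_feature.values()) == pytest.approx(100.0, abs=1e-6)

    def test_group_sums_match_members(self, default_cohort, schema):
        frame = km.cohort_to_frame(default_cohort, schema)
        X = frame[schema.names].to_numpy(float)
        y = frame["group"].to_numpy()
        report = km.feature_importance(
            X, y, km.ModelSpec(seed=0), feature_names=schema.names,
            schema=schema, n_repeats=1,
        )
        assert sum(report.per_feature.values()) == pytest.approx(100.0, abs=1e-6)
        for group in ("2D", "3D", "MRI", "CT", "Bone", "Cartilage"):
            members = schema.subset_names(group)
            assert report.per_group[group] == pytest.approx(
                sum(report.per_feature[m] for m in members), abs=1e-9
            )
        assert report.per_group["MRI"] + report.per_group["CT"] == pytest.approx(
            report.per_group["2D"], abs=1e-9
        )
        assert report.per_group["2D"] + report.per_group["3D"] == pytest.approx(
            100.0, abs=1e-6
        )


class TestSpecValidation:
    def test_bad_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            km.ModelSpec(n_trees=0)
        with pytest.raises(ValueError):
            km.ModelSpec(algorithm="GB", gb_learning_rate=0.0)
        with pytest.raises(ValueError):
            km.ModelSpec(algorithm="SVM")
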