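import numpy as np
import pandas as pd
import pytest

import ecgsubband as e
from ecgsubband.classify import FittedModel, make_folds


def cloud_matrix(n_per_class=20, sep=10.0, seed=0, n_features=6):
    """Three well-separated Gaussian point clouds as a FeatureMatrix."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i, cls in enumerate(("AF", "CHF", "NSR")):
        center = np.zeros(n_features)
        center[i % n_features] = sep * (i + 1)
        rows.append(center + rng.standard_normal((n_per_class, n_features)))
        labels += [cls] * n_per_class
    data = pd.DataFrame(np.vstack(rows), columns=[f"f{j}" for j in range(n_features)])
    return e.FeatureMatrix(data, pd.Series(labels))


class TestSplitDataset:
    def test_default_split_sizes(self):
        fm = cloud_matrix(n_per_class=50)
        train, test = e.split_dataset(fm, e.SplitSpec(seed=1))
        assert train.n_rows == 112 and test.n_rows == 38

    def test_test_composition(self):
        fm = cloud_matrix(n_per_class=50)
        _, test = e.split_dataset(fm, e.SplitSpec(seed=1))
        counts = test.labels.value_counts()
        assert counts["AF"] == 12 and counts["CHF"] == 14 and counts["NSR"] == 12

    def test_deterministic_and_disjoint(self):
        fm = cloud_matrix(n_per_class=50)
        tr1, te1 = e.split_dataset(fm, e.SplitSpec(seed=9))
        tr2, te2 = e.split_dataset(fm, e.SplitSpec(seed=9))
        assert list(te1.data.index) == list(te2.data.index)
        assert set(tr1.data.index).isdisjoint(te1.data.index)
        assert set(tr1.data.index) | set(te1.data.index) == set(fm.data.index)

    def test_insufficient_class(self):
        fm = cloud_matrix(n_per_class=10)
        with pytest.raises(ValueError):
            e.split_dataset(fm, e.SplitSpec(seed=0))


class TestGrids:
    def test_knn_grid_size(self):
        assert len(e.default_grid("knn")) == 48  # 16 k-values x 3 distances

    def test_svm_grid_size(self):
        assert len(e.default_grid("svm")) == 108  # 3 kernels x 6 gammas x 6 Cs

    def test_rf_grid_size(self):
        assert len(e.default_grid("rf")) == 16  # 8 tree counts x 2 criteria

    def test_fixed_architecture_families(self):
        assert e.default_grid("ann") == [{}]
        assert e.default_grid("rbfn") == [{}]

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            e.default_grid("catboost")

    def test_minkowski_order_distinct_from_euclidean(self):
        est = e.build_estimator("knn", {"n_neighbors": 3, "metric": "minkowski"})
        assert est.p == 3


class TestGridSearch:
    def test_separable_knn_perfect_cv(self):
        fm = cloud_matrix()
        gs = e.grid_search(fm, e.GridSpec("knn", seed=0))
        assert gs.best_mean_accuracy == 1.0
        assert len(gs.cv_table) == 48

    def test_deterministic_best_params(self):
        fm = cloud_matrix()
        g1 = e.grid_search(fm, e.GridSpec("knn", seed=4))
        g2 = e.grid_search(fm, e.GridSpec("knn", seed=4))
        assert g1.best_params == g2.best_params
        pd.testing.assert_frame_equal(g1.cv_table, g2.cv_table)

    def test_tie_breaks_to_first_cell(self):
        fm = cloud_matrix()
        gs = e.grid_search(fm, e.GridSpec("knn", seed=0))
        table = gs.cv_table
        first_best = int(table["mean_accuracy"].to_numpy().argmax())
        import json
        assert gs.best_params == json.loads(table.loc[first_best, "params"])

    def test_custom_grid(self):
        fm = cloud_matrix()
        grid = [{"n_estimators": 10, "criterion": "gini"},
                {"n_estimators": 20, "criterion": "entropy"}]
        gs = e.grid_search(fm, e.GridSpec("rf", grid=grid, seed=0))
        assert gs.best_params in grid

    def test_too_few_rows_per_class(self):
        fm = cloud_matrix(n_per_class=4)
        with pytest.raises(ValueError):
            e.grid_search(fm, e.GridSpec("knn", seed=0))

    def test_folds_stratified_within_one(self):
        fm = cloud_matrix(n_per_class=17)
        y = fm.labels.to_numpy()
        for _, va in make_folds(y, 5, seed=0):
            counts = pd.Series(y[va]).value_counts()
            expected = 17 / 5
            assert all(abs(c - expected) <= 1.0 for c in counts)


class TestTrainAndEvaluate:
    def test_knn_k1_memorizes_training_set(self):
        fm = cloud_matrix()
        model = e.train_final(fm, "knn", {"n_neighbors": 1, "metric": "euclidean"})
        rep = e.evaluate(model, fm)
        assert rep.accuracy == 1.0

    def test_rf_separable_training_accuracy(self):
        fm = cloud_matrix()
        model = e.train_final(fm, "rf", {"n_estimators": 150, "criterion": "gini"}, seed=0)
        assert e.evaluate(model, fm).accuracy == 1.0

    def test_ann_softmax_rows_sum_to_one(self):
        fm = cloud_matrix()
        model = e.train_final(fm, "ann", {}, seed=0)
        proba = model.estimator.predict_proba(fm.data.to_numpy())
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_confusion_row_sums_and_accuracy(self):
        fm = cloud_matrix(n_per_class=50)
        train, test = e.split_dataset(fm, e.SplitSpec(seed=2))
        model = e.train_final(train, "knn", {"n_neighbors": 3, "metric": "euclidean"})
        rep = e.evaluate(model, test)
        row_sums = rep.confusion.sum(axis=1)
        assert row_sums["AF"] == 12 and row_sums["CHF"] == 14 and row_sums["NSR"] == 12
        assert rep.accuracy == np.trace(rep.confusion.to_numpy()) / 38

    def test_majority_class_predictor_accuracy(self):
        class Majority:
            def predict(self, X):
                return np.array(["CHF"] * len(X))

        fm = cloud_matrix(n_per_class=50)
        _, test = e.split_dataset(fm, e.SplitSpec(seed=2))
        model = FittedModel(Majority(), "knn", {}, test.feature_names, [])
        rep = e.evaluate(model, test)
        assert rep.accuracy == pytest.approx(14 / 38)

    def test_column_mismatch_rejected(self):
        fm = cloud_matrix()
        model = e.train_final(fm, "knn", {"n_neighbors": 1, "metric": "euclidean"})
        other = fm.subset("all")
        other.data.columns = [c.upper() for c in other.data.columns]
        with pytest.raises(ValueError):
            e.evaluate(model, other)

    def test_report_serialization(self):
        fm = cloud_matrix(n_per_class=50)
        train, test = e.split_dataset(fm, e.SplitSpec(seed=2))
        model = e.train_final(train, "knn", {"n_neighbors": 1, "metric": "euclidean"})
        text = e.evaluate(model, test).to_text()
        assert "test_accuracy" in text and "confusion_matrix" in text


class TestRBFN:
    def test_separable_clouds(self):
        fm = cloud_matrix(n_per_class=30, seed=5)
        clf = e.RBFNetworkClassifier(n_centers=8, epochs=200, random_state=0)
        X, y = fm.data.to_numpy(), fm.labels.to_numpy()
        clf.fit(X, y)
        assert np.mean(clf.predict(X) == y) >= 0.95

    def test_deterministic(self):
        fm = cloud_matrix(n_per_class=10, seed=6)
        X, y = fm.data.to_numpy(), fm.labels.to_numpy()
        p1 = e.RBFNetworkClassifier(n_centers=4, epochs=50, random_state=1).fit(X, y).decision_function(X)
        p2 = e.RBFNetworkClassifier(n_centers=4, epochs=50, random_state=1).fit(X, y).decision_function(X)
        np.testing.assert_array_equal(p1, p2)

    def test_fewer_samples_than_centers(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 3))
        y = np.array(["AF"] * 5 + ["NSR"] * 5)
        clf = e.RBFNetworkClassifier(n_centers=32, epochs=20, random_state=0).fit(X, y)
        assert clf.centers_.shape[0] == 10
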