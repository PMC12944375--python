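import numpy as np
import pytest

from pfastox import (
    EstimatorSpec,
    ToxClass,
    grid_search_cv,
    knn_fit,
    knn_predict,
    predict_estimator,
    train_estimator,
)
from pfastox.dataset_io import ValidationError
from pfastox.models import default_grids, stratified_folds


HIGH, LOW = ToxClass.HIGH, ToxClass.LOW


class TestKnnFit:
    def test_valid_model_stores_data_verbatim(self, rng):
        X = rng.standard_normal((5, 3))
        m = knn_fit(X, [HIGH, HIGH, LOW, LOW, HIGH], k=3)
        np.testing.assert_array_equal(m.train_matrix, X)
        assert m.k == 3 and m.n_train == 5

    @pytest.mark.parametrize("k", [4, 7, 0])
    def test_even_or_out_of_range_k_rejected(self, rng, k):
        X = rng.standard_normal((5, 3))
        with pytest.raises(ValidationError):
            knn_fit(X, [HIGH] * 3 + [LOW] * 2, k=k)


class TestKnnPredict:
    def test_query_equal_to_training_row(self, rng):
        X = rng.standard_normal((6, 4))
        y = [HIGH, LOW, HIGH, LOW, HIGH, LOW]
        m = knn_fit(X, y, k=1)
        rec = knn_predict(m, X[3])
        assert rec.predicted_class is LOW
        assert rec.neighbours[0] == (m.train_ids[3], pytest.approx(0.0))

    def test_majority_vote_fraction(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0]])
        m = knn_fit(X, [HIGH, HIGH, LOW, LOW], k=3)
        rec = knn_predict(m, [0.05])
        assert rec.predicted_class is HIGH
        assert rec.vote_fraction_high == pytest.approx(2 / 3)
        dists = [d for _, d in rec.neighbours]
        assert dists == sorted(dists)

    def test_matches_exhaustive_search_oracle(self, rng):
        """Neighbour sets equal brute-force all-pairs distances, 50x10."""
        X = rng.standard_normal((50, 6))
        y = [HIGH if i % 2 else LOW for i in range(50)]
        m = knn_fit(X, y, k=3)
        queries = rng.standard_normal((10, 6))
        for q in queries:
            rec = knn_predict(m, q)
            d = np.linalg.norm(X - q, axis=1)
            oracle = np.argsort(d, kind="stable")[:3]
            assert [nid for nid, _ in rec.neighbours] == [str(i) for i in oracle]
            np.testing.assert_allclose(
                [dd for _, dd in rec.neighbours], d[oracle], atol=1e-12
            )

    def test_distance_ties_break_by_training_order(self):
        X = np.array([[1.0], [-1.0], [1.0]])
        m = knn_fit(X, [HIGH, LOW, LOW], k=1)
        rec = knn_predict(m, [0.0])  # all three at distance 1
        assert rec.neighbours[0][0] == "0"

    def test_dimension_mismatch_error(self, rng):
        m = knn_fit(rng.standard_normal((5, 3)), [HIGH] * 3 + [LOW] * 2, k=3)
        with pytest.raises(ValidationError):
            knn_predict(m, [0.0, 1.0])

    def test_shuffle_invariance(self, rng):
        X = rng.standard_normal((30, 4))
        y = [HIGH if i < 18 else LOW for i in range(30)]
        q = rng.standard_normal(4)
        m1 = knn_fit(X, y, k=3)
        perm = rng.permutation(30)
        m2 = knn_fit(X[perm], [y[i] for i in perm], k=3)
        r1, r2 = knn_predict(m1, q), knn_predict(m2, q)
        assert r1.predicted_class is r2.predicted_class
        np.testing.assert_allclose(
            sorted(d for _, d in r1.neighbours),
            sorted(d for _, d in r2.neighbours),
        )


class TestEstimatorAdapters:
    def test_knn_spec_routes_to_native_model(self, rng):
        X = rng.standard_normal((10, 3))
        y = [HIGH] * 5 + [LOW] * 5
        est = train_estimator("knn", {"k": 3}, X, y)
        assert est.family == "knn"
        assert est.inner.k == 3

    def test_rf_reproduction_hyperparameters_accepted(self, rng):
        X = rng.standard_normal((30, 4))
        y = [HIGH] * 18 + [LOW] * 12
        est = train_estimator(
            "random_forest",
            {"feature_fraction": 0.7, "n_ensembles": 150,
             "min_impurity_decrease": 0},
            X, y,
        )
        assert est.inner.n_estimators == 150
        assert est.inner.max_features == 0.7
        preds = predict_estimator(est, X)
        assert set(np.unique(preds)) <= {0, 1}

    @pytest.mark.parametrize("family", ["xgboost", "neural_network"])
    def test_other_families_fit_and_predict(self, rng, family):
        X = np.vstack([rng.standard_normal((20, 3)) + 2,
                       rng.standard_normal((20, 3)) - 2])
        y = [HIGH] * 20 + [LOW] * 20
        est = train_estimator(family, {}, X, y, seed=0)
        acc = (predict_estimator(est, X) == np.array([1] * 20 + [0] * 20)).mean()
        assert acc > 0.9

    def test_unknown_family_error(self, rng):
        with pytest.raises(ValidationError, match="family"):
            train_estimator("svm", {}, rng.standard_normal((4, 2)),
                            [HIGH, HIGH, LOW, LOW])


class TestGridSearch:
    def test_single_candidate_wins(self, rng):
        X = rng.standard_normal((30, 3))
        y = [HIGH] * 18 + [LOW] * 12
        spec = EstimatorSpec("knn", grid=[("k", 3, 3, 1)])
        res = grid_search_cv(X, y, spec, n_folds=5, seed=0)
        assert res.best_candidate == {"k": 3}
        assert len(res.candidates) == 1

    def test_separable_data_high_accuracy_and_oracle_scores(self, rng):
        """kNN grid k in [3,9;1] on 3-sd-separated classes: winner >= 0.9,
        and every fold score equals an independently recomputed accuracy."""
        n = 150
        y_enc = np.array([1] * 90 + [0] * 60)
        X = rng.standard_normal((n, 4))
        X[:, :2] += np.where(y_enc[:, None] == 1, 1.5, -1.5)
        y = [HIGH if v else LOW for v in y_enc]
        spec = EstimatorSpec("knn", grid=[("k", 3, 9, 1)])
        res = grid_search_cv(X, y, spec, n_folds=5, seed=1)
        assert res.best_mean_accuracy >= 0.9
        assert [c["k"] for c in res.candidates] == [3, 5, 7, 9]
        # recompute one candidate's fold accuracies from scratch
        ci = res.best_index
        k = int(res.best_candidate["k"])
        for f in range(5):
            tr, va = res.fold_of_row != f, res.fold_of_row == f
            m = knn_fit(X[tr], y_enc[tr], k=k)
            acc = ((m.vote_fraction(X[va]) > 0.5).astype(int)
                   == y_enc[va]).mean()
            assert res.fold_scores[ci, f] == pytest.approx(acc)

    def test_folds_partition_rows_and_are_stratified(self):
        y = [HIGH] * 33 + [LOW] * 17
        fold = stratified_folds(y, 5, seed=0)
        assert len(fold) == 50
        assert sorted(np.unique(fold)) == [0, 1, 2, 3, 4]
        high_counts = [((fold == f) & (np.arange(50) < 33)).sum() for f in range(5)]
        assert max(high_counts) - min(high_counts) <= 1

    def test_label_shuffled_cv_near_neighbour_null(self, rng):
        """On shuffled labels, kNN CV accuracy approaches p^2 + q^2."""
        n = 300
        y_enc = rng.permutation([1] * 192 + [0] * 108)
        X = rng.standard_normal((n, 5))
        y = [HIGH if v else LOW for v in y_enc]
        res = grid_search_cv(X, y, EstimatorSpec("knn", grid=[("k", 3, 3, 1)]),
                             n_folds=5, seed=2)
        p = 192 / 300
        null = p**2 + (1 - p) ** 2
        assert abs(res.mean_scores[0] - null) < 0.1

    def test_failure_carries_candidate_identity(self, rng):
        X = rng.standard_normal((20, 2))
        y = [HIGH] * 10 + [LOW] * 10
        spec = EstimatorSpec("knn", grid=[("k", 21, 21, 1)])  # k > n_train
        with pytest.raises(ValidationError, match="21"):
            grid_search_cv(X, y, spec, n_folds=5, seed=0)


def test_default_grids_expand_to_expected_sizes():
    g = default_grids()
    assert [c["k"] for c in g["knn"].expand()] == [3, 5, 7, 9]
    assert len(g["xgboost"].expand()) == 4 * 3 * 3 * 3
    assert len(g["random_forest"].expand()) == 3 * 3
    nn = g["neural_network"].expand()
    assert len(nn) == 2 * 3 * 2 * 2
    assert all(c["activation"] == "relu" for c in nn)
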