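import math

import numpy as np
import pytest

from cpctriage.predictors import (
    NO_PREDICTION,
    ClassifierSpec,
    KnnCpcClassifier,
    SeededKMeansCpc,
    SelfTrainingCpcClassifier,
    SupervisedCpcClassifier,
    euc_similarity,
    knn_predict,
    seeded_kmeans,
    self_train,
    stratified_cv,
    stratified_fold_sizes,
    train_supervised,
)


def _blobs(rng, centers, n_per, scale=0.3):
    """Well-separated gaussian clusters labeled by their center index."""
    X, y = [], []
    for label, center in centers.items():
        X.append(rng.normal(loc=center, scale=scale, size=(n_per, len(center))))
        y.extend([label] * n_per)
    return np.vstack(X), np.array(y, dtype=object)


class TestEucSimilarity:
    def test_identity(self):
        assert euc_similarity([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_log_two_distance(self):
        assert euc_similarity([0.0], [math.log(2)]) == pytest.approx(0.5)

    def test_distance_five(self):
        assert euc_similarity([0.0, 0.0], [3.0, 4.0]) == pytest.approx(
            math.exp(-5), rel=1e-9
        )

    def test_strictly_decreasing(self):
        sims = [euc_similarity([0.0], [d]) for d in (0.0, 0.5, 1.0, 2.0)]
        assert sims == sorted(sims, reverse=True)


class TestKnnPredict:
    def test_k1_returns_nearest(self):
        labeled = [([0.0, 0.0], "a"), ([5.0, 5.0], "b")]
        cpc, votes = knn_predict([0.2, 0.0], labeled, k=1)
        assert cpc == "a"
        assert set(votes) == {"a"}

    def test_unanimity(self):
        labeled = [([float(i), 0.0], "a") for i in range(10)]
        cpc, _ = knn_predict([0.0, 0.0], labeled, k=10)
        assert cpc == "a"

    def test_weighted_vote_sum_decides(self):
        # CPC a: similarities 0.5 + 0.4 = 0.9 beats CPC b: 0.6
        labeled = [
            ([-math.log(0.5)], "a"),
            ([-math.log(0.4)], "a"),
            ([-math.log(0.6)], "b"),
        ]
        cpc, votes = knn_predict([0.0], labeled, k=3)
        assert cpc == "a"
        assert votes["a"] == pytest.approx(0.9)
        assert votes["b"] == pytest.approx(0.6)

    def test_no_qualifying_neighbour_sentinel(self):
        # distance so large that exp(-d) underflows to exactly 0
        labeled = [([1e4], "a")]
        cpc, votes = knn_predict([0.0], labeled, k=5)
        assert cpc == NO_PREDICTION
        assert votes == {}

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            knn_predict([0.0], [([0.0], "a")], k=0)

    def test_vote_weights_in_unit_interval_and_winner_maximal(self):
        rng = np.random.default_rng(11)
        X, y = _blobs(rng, {"a": [0, 0], "b": [3, 3], "c": [6, 0]}, 8)
        labeled = list(zip(X.tolist(), y))
        for _ in range(20):
            q = rng.normal(scale=4.0, size=2)
            cpc, votes = knn_predict(q, labeled, k=10)
            assert all(0 < w <= 10 for w in votes.values())
            assert votes[cpc] == max(votes.values())

    def test_estimator_matches_function(self):
        rng = np.random.default_rng(5)
        X, y = _blobs(rng, {"a": [0, 0], "b": [4, 4]}, 10)
        model = KnnCpcClassifier(k=10).fit(X, y)
        queries = rng.normal(scale=3.0, size=(15, 2))
        labeled = list(zip(X.tolist(), y))
        expected = [knn_predict(q, labeled, k=10)[0] for q in queries]
        assert list(model.predict(queries)) == expected


class TestSupervised:
    def _toy(self, seed=0, n=20):
        rng = np.random.default_rng(seed)
        return _blobs(rng, {"a": [0, 0, 0], "b": [5, 5, 5]}, n)

    def test_separable_training_accuracy(self):
        X, y = self._toy()
        model = train_supervised(X, y)
        assert (model.predict(X) == y).all()

    def test_ovo_builds_n_choose_2_problems(self):
        rng = np.random.default_rng(1)
        centers = {f"c{i:02d}": [3.0 * i, 0.0] for i in range(20)}
        X, y = _blobs(rng, centers, 3, scale=0.1)
        spec = ClassifierSpec(algorithm="linear_svm", multiclass_strategy="ovo")
        model = train_supervised(X, y, spec=spec)
        assert model.n_binary_problems_ == 20 * 19 // 2

    def test_ovr_builds_one_per_class(self):
        X, y = self._toy()
        spec = ClassifierSpec(multiclass_strategy="ovr")
        rng = np.random.default_rng(2)
        X3, y3 = _blobs(rng, {"a": [0, 0], "b": [5, 0], "c": [0, 5]}, 5)
        model = train_supervised(X3, y3, spec=spec)
        assert model.n_binary_problems_ == 3

    def test_deterministic_given_seed(self):
        X, y = self._toy(n=30)
        spec = ClassifierSpec(algorithm="random_forest",
                              hyperparameters={"n_estimators": 20})
        rng = np.random.default_rng(9)
        Xq = rng.normal(scale=4.0, size=(25, 3))
        p1 = train_supervised(X, y, spec=spec, seed=42).predict(Xq)
        p2 = train_supervised(X, y, spec=spec, seed=42).predict(Xq)
        assert (p1 == p2).all()

    def test_single_class_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            train_supervised(X, ["a"] * 5)

    @pytest.mark.parametrize("algorithm", ["logistic_regression", "linear_svm"])
    def test_confidence_is_probability_simplex(self, algorithm):
        X, y = self._toy()
        model = train_supervised(X, y, spec=ClassifierSpec(algorithm=algorithm))
        conf = model.predict_confidence(X)
        assert conf.shape == (len(X), 2)
        assert (conf >= 0).all() and (conf <= 1).all()
        np.testing.assert_allclose(conf.sum(axis=1), 1.0, rtol=1e-9)


class TestStratifiedCv:
    def test_1689_rows_give_338_test_fold(self):
        sizes = stratified_fold_sizes(1689, 5)
        assert max(sizes) == 338
        assert sum(sizes) == 1689

    def test_exact_stratification_balanced_toy(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        X = np.hstack([X, (np.arange(10) % 2).reshape(-1, 1) * 10.0])
        y = np.array(["a", "b"] * 5, dtype=object)
        out = stratified_cv(X, y, folds=5, seed=0)
        for idx in out["fold_test_indices"]:
            labels = y[idx]
            assert sorted(labels) == ["a", "b"]

    def test_partition_property_and_pooled_accuracy(self):
        rng = np.random.default_rng(3)
        X, y = _blobs(rng, {"a": [0, 0], "b": [4, 4], "c": [8, 0]}, 10)
        out = stratified_cv(X, y, folds=5, seed=1)
        all_idx = np.concatenate(out["fold_test_indices"])
        assert sorted(all_idx) == list(range(len(y)))  # covers, disjoint
        # pooled accuracy equals total correct / n
        weighted = sum(
            a * len(ix)
            for a, ix in zip(out["fold_accuracies"], out["fold_test_indices"])
        )
        assert out["pooled_accuracy"] == pytest.approx(weighted / len(y))

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            stratified_cv(np.zeros((3, 1)), ["a", "b", "a"], folds=5)


class TestSelfTraining:
    def _separable(self, seed=0):
        rng = np.random.default_rng(seed)
        X, y = _blobs(rng, {"a": [0, 0], "b": [6, 6]}, 30, scale=0.4)
        return rng, X, y

    def test_empty_unlabeled_reduces_to_supervised(self):
        _, X, y = self._separable()
        st_model, log = self_train(X, y, np.empty((0, 2)))
        base = train_supervised(X, y)
        assert log == []
        rng = np.random.default_rng(1)
        Xq = rng.normal(scale=5.0, size=(20, 2))
        assert (st_model.predict(Xq) == base.predict(Xq)).all()

    def test_low_confidence_stops_after_one_iteration(self):
        # unlabeled points exactly between two balanced classes: max
        # confidence ~0.5 < 0.75 threshold
        X = np.array([[0.0, 0.0], [0.1, 0.0], [6.0, 6.0], [6.1, 6.0]])
        y = np.array(["a", "a", "b", "b"], dtype=object)
        U = np.array([[3.0, 3.0], [3.05, 3.0]])
        model, log = self_train(X, y, U, threshold=0.999999)
        assert model.n_iterations_ == 1
        assert log == []

    def test_separable_clusters_recover_generator_labels(self):
        rng, X, y = self._separable(seed=7)
        U_a = rng.normal(loc=[0, 0], scale=0.4, size=(20, 2))
        U_b = rng.normal(loc=[6, 6], scale=0.4, size=(20, 2))
        U = np.vstack([U_a, U_b])
        truth = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        model, log = self_train(X, y, U)
        assert len(log) == 40  # every point pseudo-labeled
        by_row = {p.row: p.label for p in log}
        assert all(by_row[i] == truth[i] for i in range(40))

    def test_pool_growth_monotone_and_log_consistent(self):
        rng, X, y = self._separable(seed=11)
        U = rng.normal(loc=[3, 3], scale=3.0, size=(50, 2))
        model, log = self_train(X, y, U, max_iter=5)
        iters = [p.iteration for p in log]
        assert iters == sorted(iters)
        assert len(log) <= 50
        assert len({p.row for p in log}) == len(log)  # each row added once

    def test_threshold_validation(self):
        _, X, y = self._separable()
        with pytest.raises(ValueError):
            SelfTrainingCpcClassifier(threshold=0.5).fit(X, y, X)


class TestSeededKMeans:
    def test_rows_at_seeds_converge_in_one_iteration(self):
        seeds = {"a": [0.0, 0.0], "b": [10.0, 10.0], "c": [0.0, 10.0]}
        X = np.array([seeds[k] for k in ("a", "b", "c", "a", "b")])
        model, assignments = seeded_kmeans(X, seeds)
        assert model.n_iterations == 1
        assert list(assignments) == ["a", "b", "c", "a", "b"]
        assert model.objective_trace == [0.0]

    def test_hand_computed_lloyd_pass(self):
        seeds = {"c1": [0.0, 0.0], "c2": [10.0, 10.0]}
        X = np.array([[1.0, 0.0], [9.0, 10.0]])
        model, assignments = seeded_kmeans(X, seeds)
        assert list(assignments) == ["c1", "c2"]
        np.testing.assert_allclose(
            model.centroids, [[1.0, 0.0], [9.0, 10.0]]
        )

    def test_objective_trace_non_increasing_random_data(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            X = rng.normal(size=(40, 5))
            seeds = {f"s{i}": rng.normal(size=5) for i in range(4)}
            model, _ = seeded_kmeans(X, seeds)
            trace = model.objective_trace
            assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_k_and_labels_preserved(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        seeds = {f"cpc-{i}": rng.normal(size=3) for i in range(5)}
        model, assignments = seeded_kmeans(X, seeds)
        assert model.k == 5
        assert model.seed_labels == sorted(seeds)
        assert set(assignments) <= set(seeds)

    def test_empty_cluster_keeps_frozen_centroid(self):
        # far-away seed attracts nothing; its centroid must stay put
        seeds = {"a": [0.0], "b": [1.0], "far": [100.0]}
        X = np.array([[0.0], [0.2], [0.9], [1.1]])
        model, assignments = seeded_kmeans(X, seeds)
        assert "far" not in set(assignments)
        far_idx = model.seed_labels.index("far")
        assert model.centroids[far_idx][0] == 100.0

    def test_zero_seed_rejected_by_name(self):
        from cpctriage.features import TermCountVectorizer
        from cpctriage.predictors import vectorize_seeds

        vec = TermCountVectorizer(min_doc_count=1, max_doc_fraction=1.0)
        vec.fit([["hear", "loss"], ["tinnitu"]])
        with pytest.raises(ValueError, match="bad-cpc"):
            vectorize_seeds(vec, {"bad-cpc": ["vertigo"], "ok": ["hear"]})

    def test_fewer_than_two_seeds_rejected(self):
        with pytest.raises(ValueError):
            SeededKMeansCpc(seeds={"only": [1.0]}).fit(np.ones((2, 1)))


class TestPersistence:
    def test_model_round_trip_with_vocabulary_hash(self, tmp_path):
        from cpctriage.predictors import load_model, save_model

        rng = np.random.default_rng(4)
        X, y = _blobs(rng, {"a": [0, 0], "b": [5, 5]}, 10)
        model = train_supervised(X, y, seed=1)
        path = tmp_path / "model.joblib"
        save_model(model, path, vocabulary=["hear", "loss"])
        back, meta = load_model(path)
        assert (back.predict(X) == model.predict(X)).all()
        assert meta["class"] == "SupervisedCpcClassifier"
        assert meta["vocabulary_sha256"]
        assert meta["params"]["seed"] == 1

    def test_pseudo_label_log_frame(self):
        from cpctriage.predictors import pseudo_labels_to_frame

        rng = np.random.default_rng(6)
        X, y = _blobs(rng, {"a": [0, 0], "b": [6, 6]}, 20, scale=0.4)
        U = np.vstack([
            rng.normal(loc=[0, 0], scale=0.4, size=(10, 2)),
            rng.normal(loc=[6, 6], scale=0.4, size=(10, 2)),
        ])
        _, log = self_train(X, y, U)
        frame = pseudo_labels_to_frame(log)
        assert list(frame.columns) == ["iteration", "row", "label", "confidence"]
        assert len(frame) == len(log)
        assert (frame.confidence >= 0.75).all()
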