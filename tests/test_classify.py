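"""LDA/PCA, cross-validated classification, clustering, metrics, ReliefF."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from diatomid import classify
from diatomid.classify import (
    KNNClassifier,
    cluster,
    clustering_metrics,
    crossval_classify,
    fit_lda,
    fit_pca,
    map_clusters,
    relieff_rank,
)


def gaussian_classes(rng, means, n_per_class, cov=None):
    d = len(means[0])
    cov = np.eye(d) if cov is None else cov
    X = np.vstack([rng.multivariate_normal(m, cov, size=n_per_class) for m in means])
    y = np.repeat(np.arange(len(means)), n_per_class)
    return X, y


class TestLDA:
    def test_auto_components_is_classes_minus_one(self):
        rng = np.random.default_rng(0)
        X, y = gaussian_classes(rng, np.eye(8) * 6, 20)
        proj = fit_lda(X, y)
        assert proj.n_components == 7
        assert proj.transform(X).shape == (160, 7)

    def test_two_classes_single_axis(self):
        rng = np.random.default_rng(1)
        X, y = gaussian_classes(rng, [[0, 0], [4, 0]], 30)
        assert fit_lda(X, y).n_components == 1

    def test_fisher_direction_closed_form(self):
        rng = np.random.default_rng(2)
        cov = np.array([[2.0, 0.8, 0.0], [0.8, 1.0, 0.2], [0.0, 0.2, 0.5]])
        mu1, mu2 = np.zeros(3), np.array([1.5, -0.5, 1.0])
        X, y = gaussian_classes(rng, [mu1, mu2], 5000, cov=cov)
        axis = fit_lda(X, y).axes[0]
        fisher = np.linalg.solve(cov, mu2 - mu1)
        cos = abs(axis @ fisher) / (np.linalg.norm(axis) * np.linalg.norm(fisher))
        assert np.degrees(np.arccos(min(cos, 1.0))) < 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(np.random.default_rng(0).normal(size=(10, 3)), np.zeros(10))


class TestPCA:
    def test_isotropic_variance_ratios_near_equal(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(2000, 4))
        proj = fit_pca(X, 4)
        ratios = proj.model.explained_variance_ratio_
        assert ratios.max() / ratios.min() < 1.2

    def test_line_plus_noise_first_component_dominates(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=(500, 1))
        X = np.hstack([t, 2 * t, -t]) + 1e-3 * rng.normal(size=(500, 3))
        proj = fit_pca(X, 3)
        assert proj.model.explained_variance_ratio_[0] > 0.99

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 6))
        proj = fit_pca(X, 6)
        Z = proj.transform(X)
        back = Z @ proj.axes + proj.mean
        assert np.allclose(back, X, atol=1e-9)


class TestCrossval:
    def test_separable_classes_perfect_knn(self):
        rng = np.random.default_rng(6)
        X = np.concatenate([rng.uniform(0, 1, 50), rng.uniform(5, 6, 50)])[:, None]
        y = np.repeat([0, 1], 50)
        rep = crossval_classify(X, y, method="knn", k_folds=5, seed=0,
                                hyperparams={"k": 1}, reducer=None)
        assert rep.overall_accuracy == 1.0

    def test_confusion_bookkeeping(self):
        rng = np.random.default_rng(7)
        X, y = gaussian_classes(rng, [[0, 0], [2, 2], [4, 0]], 30)
        rep = crossval_classify(X, y, method="svm", k_folds=5, seed=1)
        assert rep.confusion.sum() == 90
        assert rep.confusion.sum(axis=1).tolist() == [30, 30, 30]
        assert rep.overall_accuracy == pytest.approx(
            np.trace(rep.confusion) / 90
        )

    def test_shuffled_labels_chance_level(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(400, 5))
        y = np.repeat([0, 1], 200)
        rep = crossval_classify(X, rng.permutation(y), method="knn",
                                k_folds=10, seed=2, reducer=None)
        assert abs(rep.overall_accuracy - 0.5) <= 0.08

    def test_small_class_rejected(self):
        X = np.zeros((12, 2))
        y = np.array([0] * 9 + [1] * 3)
        with pytest.raises(ValueError):
            crossval_classify(X, y, k_folds=5)

    def test_no_leakage_fitting_sees_training_rows_only(self):
        """Every data-dependent step is fitted per fold on training rows
        only: a spy pre-step records what it is given, and none of the rows
        it saw may coincide with that fold's held-out rows."""
        rng = np.random.default_rng(9)
        # unique row fingerprints so membership checks are exact
        X = rng.normal(size=(60, 4)) + np.arange(60)[:, None] * 100.0
        y = np.repeat([0, 1], 30)

        seen: list[np.ndarray] = []

        class Spy:
            def fit(self, Xtr, ytr=None):
                seen.append(Xtr.copy())
                return lambda Z: Z

        crossval_classify(X, y, method="knn", k_folds=5, seed=3,
                          reducer=None, pre_steps=[Spy()])
        assert len(seen) == 5
        all_rows = {tuple(r) for r in X}
        for Xtr in seen:
            assert Xtr.shape[0] == 48  # 4/5 of the data
            train_rows = {tuple(r) for r in Xtr}
            assert train_rows < all_rows  # strict subset: held-out rows absent


class TestKNNTieBreak:
    def test_tie_falls_back_to_nearest(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        clf = KNNClassifier(k=4).fit(X, y)
        # query at 2.0: votes tied 2-2, nearest neighbor (1.0) has class 0
        assert clf.predict(np.array([[2.0]]))[0] == 0
        assert clf.predict(np.array([[9.0]]))[0] == 1


class TestCluster:
    def test_k_one_single_cluster(self):
        X = np.random.default_rng(10).normal(size=(20, 3))
        assert set(cluster(X, "kmeans", k=1)) == {0}

    @pytest.mark.parametrize("method", ["kmeans", "agglomerative", "birch"])
    def test_separated_blobs_recovered(self, method):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X, y = gaussian_classes(
                rng, [[0, 0], [3, 0], [0, 3]], 40, cov=np.eye(2) * 0.01
            )
            labels = cluster(X, method, k=3, seed=seed)
            assert map_clusters(labels, y).mapped_accuracy == 1.0

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValueError):
            cluster(np.zeros((5, 2)), "kmeans", k=9)


class TestMapClusters:
    def test_aligned_identity(self):
        y = np.repeat([0, 1, 2], 10)
        rep = map_clusters(y.copy(), y)
        assert rep.mapped_accuracy == 1.0
        assert all(rep.mapping[c] == c for c in (0, 1, 2))

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_matches_brute_force_permutations(self, k):
        rng = np.random.default_rng(k)
        n = 60
        y = rng.integers(0, k, size=n)
        y[:k] = np.arange(k)  # ensure every class present
        cl = rng.integers(0, k, size=n)
        cl[:k] = np.arange(k)
        rep = map_clusters(cl, y)
        best = max(
            sum(np.sum((cl == i) & (y == perm[i])) for i in range(k))
            for perm in itertools.permutations(range(k))
        )
        assert np.trace(rep.confusion) == best

    def test_swap_invariance(self):
        rng = np.random.default_rng(11)
        y = np.repeat([0, 1, 2], 15)
        cl = rng.permutation(y)
        swapped = cl.copy()
        swapped[cl == 0], swapped[cl == 1] = 1, 0
        assert map_clusters(cl, y).mapped_accuracy == pytest.approx(
            map_clusters(swapped, y).mapped_accuracy
        )

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            map_clusters(np.array([0, 0, 1]), np.array([0, 1, 2]))


class TestClusteringMetrics:
    def test_perfect_labeling(self):
        y = np.repeat([0, 1, 2, 3], 20)
        X = np.repeat(np.eye(4), 20, axis=0)
        m = clustering_metrics(y.copy(), y, X)
        assert m["ari"] == m["ami"] == m["homogeneity"] == m["completeness"] == 1.0

    def test_single_cluster_extremes(self):
        y = np.repeat([0, 1], 10)
        X = np.random.default_rng(12).normal(size=(20, 2))
        with pytest.warns(UserWarning):
            m = clustering_metrics(np.zeros(20, int), y, X)
        assert m["completeness"] == 1.0
        assert m["homogeneity"] == 0.0
        assert m["silhouette"] is None

    def test_random_labels_chance_corrected(self):
        rng = np.random.default_rng(13)
        y = rng.integers(0, 4, size=2000)
        cl = rng.integers(0, 4, size=2000)
        m = clustering_metrics(cl, y, np.zeros((2000, 2)))
        assert abs(m["ari"]) < 0.02
        assert abs(m["ami"]) < 0.02


class TestReliefF:
    def test_label_copy_feature_ranked_first(self):
        rng = np.random.default_rng(14)
        y = rng.integers(0, 2, size=120)
        X = np.column_stack([
            y + 0.01 * rng.normal(size=120),
            rng.normal(size=120),
            rng.normal(size=120),
        ])
        w = relieff_rank(X, y, k_neighbors=5)
        assert np.argmax(w) == 0

    def test_constant_feature_zero_weight(self):
        rng = np.random.default_rng(15)
        y = rng.integers(0, 2, size=60)
        X = np.column_stack([np.full(60, 3.0), rng.normal(size=60)])
        w = relieff_rank(X, y, k_neighbors=3)
        assert w[0] == 0.0

    def test_xor_interaction_detected(self):
        rng = np.random.default_rng(16)
        n = 400
        x1, x2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        y = ((x1 > 0.5) ^ (x2 > 0.5)).astype(int)
        X = np.column_stack([x1, x2])
        w = relieff_rank(X, y, k_neighbors=10, seed=0)
        assert np.all(w > 0)
        # ...even though each feature alone is uninformative
        assert abs(np.corrcoef(x1, y)[0, 1]) < 0.1
        assert abs(np.corrcoef(x2, y)[0, 1]) < 0.1

    def test_weights_within_unit_range(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(100, 6))
        y = rng.integers(0, 3, size=100)
        y[:6] = [0, 0, 1, 1, 2, 2]
        w = relieff_rank(X, y, k_neighbors=2, seed=1)
        assert np.all(np.abs(w) <= 1.0)


def test_metric_ranges_on_random_inputs():
    rng = np.random.default_rng(18)
    for _ in range(50):
        n = int(rng.integers(20, 60))
        k = int(rng.integers(2, 5))
        y = rng.integers(0, k, size=n)
        cl = rng.integers(0, k, size=n)
        X = rng.normal(size=(n, 3))
        if np.unique(cl).size < 2:
            continue
        m = clustering_metrics(cl, y, X)
        assert -1.0 <= m["ari"] <= 1.0
        assert -1.0 <= m["ami"] <= 1.0 + 1e-12
        assert 0.0 <= m["homogeneity"] <= 1.0
        assert 0.0 <= m["completeness"] <= 1.0
        assert -1.0 <= m["silhouette"] <= 1.0
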