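"""Dimensionality reduction, classification, clustering and validation.

scikit-learn provides the estimators (LDA, PCA, SVM, k-means, Ward
agglomerative, BIRCH) and the clustering validation metrics; this module
wraps them behind the pipeline's contracts and adds what scikit-learn
lacks: a KNN with deterministic nearest-neighbor tie-breaking, optimal
(Hungarian) cluster-to-class mapping, and ReliefF feature ranking.

Cross-validation is stratified k-fold with every data-dependent step —
feature selection, standardization, LDA — fitted on the training folds
only, so reported accuracies carry no train/test leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AgglomerativeClustering, Birch, KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    completeness_score,
    confusion_matrix,
    homogeneity_score,
    silhouette_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "Projection",
    "CVReport",
    "ClusterReport",
    "fit_lda",
    "fit_pca",
    "KNNClassifier",
    "crossval_classify",
    "cluster",
    "map_clusters",
    "clustering_metrics",
    "relieff_rank",
]


def _as_matrix(table) -> np.ndarray:
    X = table.to_numpy(dtype=np.float64) if isinstance(table, pd.DataFrame) else np.asarray(table, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("feature table must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite values")
    return X


@dataclass
class Projection:
    """Fitted linear projection (LDA or PCA)."""

    kind: str
    n_components: int
    model: object

    @property
    def axes(self) -> np.ndarray:
        if self.kind == "pca":
            return self.model.components_[: self.n_components]
        return self.model.scalings_[:, : self.n_components].T

    @property
    def mean(self) -> np.ndarray:
        if self.kind == "pca":
            return self.model.mean_
        return getattr(self.model, "xbar_", self.model.means_.mean(axis=0))

    def transform(self, table) -> np.ndarray:
        return self.model.transform(_as_matrix(table))[:, : self.n_components]


def fit_lda(table, labels, n_components: int | str = "auto",
            shrinkage: float = 1e-4) -> Projection:
    """Fisher linear discriminant projection; at most N-1 components.

    A small shrinkage regularizer keeps the within-class scatter invertible
    when features are collinear (the eigen solver then warns rather than
    fails on exactly singular scatter).
    """
    X = _as_matrix(table)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("LDA needs at least 2 classes")
    if X.shape[0] <= classes.size:
        raise ValueError("need more samples than classes")
    cap = classes.size - 1
    k = cap if n_components == "auto" else min(int(n_components), cap)
    model = LinearDiscriminantAnalysis(solver="eigen", shrinkage=shrinkage,
                                       n_components=k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear-feature warnings
        model.fit(X, y)
    return Projection(kind="lda", n_components=k, model=model)


def fit_pca(table, n_components: int) -> Projection:
    X = _as_matrix(table)
    if not 1 <= n_components <= min(X.shape[0] - 1, X.shape[1]):
        raise ValueError("n_components out of range")
    model = PCA(n_components=n_components, svd_solver="full")
    model.fit(X)
    return Projection(kind="pca", n_components=n_components, model=model)


class KNNClassifier:
    """K-nearest-neighbors with deterministic tie-breaking.

    Majority vote over the K Euclidean neighbors; a tied vote falls back to
    the class of the single nearest neighbor.
    """

    def __init__(self, k: int = 5):
        self.k = k
        self._nn: NearestNeighbors | None = None
        self._y: np.ndarray | None = None

    def fit(self, X, y) -> "KNNClassifier":
        X = np.asarray(X, dtype=np.float64)
        self._nn = NearestNeighbors(n_neighbors=min(self.k, X.shape[0])).fit(X)
        self._y = np.asarray(y)
        return self

    def predict(self, X) -> np.ndarray:
        if self._nn is None:
            raise RuntimeError("classifier is not fitted")
        _, idx = self._nn.kneighbors(np.asarray(X, dtype=np.float64))
        out = np.empty(idx.shape[0], dtype=self._y.dtype)
        for i, row in enumerate(idx):
            votes = self._y[row]
            vals, counts = np.unique(votes, return_counts=True)
            winners = vals[counts == counts.max()]
            out[i] = votes[0] if winners.size > 1 else winners[0]
        return out


@dataclass
class CVReport:
    fold_accuracies: np.ndarray
    overall_accuracy: float
    confusion: np.ndarray  # rows = truth, cols = predicted
    classes: np.ndarray
    classifier_config: dict

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "overall_accuracy": float(self.overall_accuracy),
            "confusion": self.confusion.tolist(),
            "classes": self.classes.tolist(),
            "classifier_config": self.classifier_config,
        }


def _make_classifier(method: str, hyperparams: dict, seed: int):
    if method == "knn":
        return KNNClassifier(k=int(hyperparams.get("k", 5)))
    if method == "svm":
        return SVC(
            kernel=hyperparams.get("kernel", "rbf"),
            C=float(hyperparams.get("C", 10.0)),
            gamma=hyperparams.get("gamma", "scale"),
            random_state=seed,
        )
    raise ValueError(f"unknown classifier method {method!r}")


def crossval_classify(
    table,
    labels,
    method: str = "knn",
    k_folds: int = 10,
    seed: int = 0,
    hyperparams: dict | None = None,
    reducer: str | None = "lda",
    pre_steps: Sequence | None = None,
) -> CVReport:
    """Stratified k-fold cross-validated classification.

    Per fold the optional ``pre_steps`` (objects with fit(X, y) -> transform
    callable), a standardizer, the LDA/PCA reducer and the classifier are all
    fitted on the training folds only; predictions are pooled into a single
    confusion matrix.
    """
    X = _as_matrix(table)
    y = np.asarray(labels)
    hyperparams = dict(hyperparams or {})
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k_folds:
        raise ValueError("every class needs at least k_folds samples")

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    fold_acc = []
    for train_idx, test_idx in skf.split(X, y):
        Xtr, Xte = X[train_idx], X[test_idx]
        ytr, yte = y[train_idx], y[test_idx]
        for step in pre_steps or ():
            transform = step.fit(Xtr, ytr)
            Xtr = transform(Xtr)
            Xte = transform(Xte)
        scaler = StandardScaler().fit(Xtr)
        Xtr = scaler.transform(Xtr)
        Xte = scaler.transform(Xte)
        if reducer == "lda":
            proj = fit_lda(Xtr, ytr)
            Xtr, Xte = proj.transform(Xtr), proj.transform(Xte)
        elif reducer == "pca":
            proj = fit_pca(Xtr, n_components=min(Xtr.shape) - 1)
            Xtr, Xte = proj.transform(Xtr), proj.transform(Xte)
        clf = _make_classifier(method, hyperparams, seed)
        clf.fit(Xtr, ytr)
        pred = clf.predict(Xte)
        y_pred[test_idx] = pred
        fold_acc.append(float(np.mean(pred == yte)))

    conf = confusion_matrix(y, y_pred, labels=classes)
    return CVReport(
        fold_accuracies=np.asarray(fold_acc),
        overall_accuracy=float(np.trace(conf) / conf.sum()),
        confusion=conf,
        classes=classes,
        classifier_config={"method": method, "k_folds": k_folds, "seed": seed,
                           "reducer": reducer, **hyperparams},
    )


def cluster(table, method: str = "kmeans", k: int = 2, seed: int = 0) -> np.ndarray:
    """Cluster rows into k groups.

    kmeans: 10 seeded restarts minimizing within-cluster sum of squares.
    agglomerative: Ward linkage on Euclidean distances.
    birch: CF-tree (branching 50, threshold 0.5), global clustering of the
    leaves to k, then a k-means refinement pass seeded at the BIRCH centroids.
    """
    X = _as_matrix(table)
    if not 1 <= k <= X.shape[0]:
        raise ValueError("k must lie in 1..n_rows")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(X)
    if method == "agglomerative":
        return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    if method == "birch":
        labels = Birch(n_clusters=k, branching_factor=50, threshold=0.5).fit_predict(X)
        centroids = np.stack([X[labels == c].mean(axis=0) for c in np.unique(labels)])
        if centroids.shape[0] == k:
            km = KMeans(n_clusters=k, init=centroids, n_init=1, random_state=seed)
            labels = km.fit_predict(X)
        return labels
    raise ValueError(f"unknown clustering method {method!r}")


@dataclass
class ClusterReport:
    cluster_labels: np.ndarray
    mapping: dict
    mapped_accuracy: float
    confusion: np.ndarray
    metrics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mapping": {str(k): int(v) for k, v in self.mapping.items()},
            "mapped_accuracy": float(self.mapped_accuracy),
            "confusion": self.confusion.tolist(),
            "metrics": {k: (None if v is None else float(v)) for k, v in self.metrics.items()},
        }


def map_clusters(cluster_labels, truth) -> ClusterReport:
    """Optimal one-to-one cluster-to-class assignment (Hungarian method).

    Maximizes the total count on the diagonal of the mapped confusion
    matrix; requires as many clusters as truth classes.
    """
    cl = np.asarray(cluster_labels)
    y = np.asarray(truth)
    clusters = np.unique(cl)
    classes = np.unique(y)
    if clusters.size != classes.size:
        raise ValueError("number of clusters must equal number of classes")
    contingency = np.zeros((clusters.size, classes.size), dtype=np.int64)
    for i, c in enumerate(clusters):
        for j, t in enumerate(classes):
            contingency[i, j] = int(np.sum((cl == c) & (y == t)))
    rows, cols = linear_sum_assignment(-contingency)
    mapping = {clusters[i]: classes[j] for i, j in zip(rows, cols)}
    mapped = np.array([mapping[c] for c in cl])
    conf = confusion_matrix(y, mapped, labels=classes)
    return ClusterReport(
        cluster_labels=cl,
        mapping=mapping,
        mapped_accuracy=float(np.trace(conf) / conf.sum()),
        confusion=conf,
    )


def clustering_metrics(cluster_labels, truth, table) -> dict:
    """The five validation metrics: ARI, AMI, homogeneity, completeness,
    silhouette.  Silhouette needs at least 2 clusters; with a single cluster
    it is reported as None with a warning."""
    cl = np.asarray(cluster_labels)
    y = np.asarray(truth)
    out = {
        "ari": float(adjusted_rand_score(y, cl)),
        "ami": float(adjusted_mutual_info_score(y, cl)),
        "homogeneity": float(homogeneity_score(y, cl)),
        "completeness": float(completeness_score(y, cl)),
    }
    if np.unique(cl).size < 2:
        warnings.warn("silhouette undefined for a single cluster", stacklevel=2)
        out["silhouette"] = None
    else:
        out["silhouette"] = float(silhouette_score(_as_matrix(table), cl))
    return out


def relieff_rank(
    table,
    labels,
    k_neighbors: int = 10,
    n_sample: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """ReliefF feature importances.

    For each sampled instance, the weight of a feature grows with its mean
    separation from the k nearest misses of every other class (weighted by
    class priors) and shrinks with its separation from the k nearest hits.
    Feature differences are range-normalized, so weights lie in [-1, 1].
    Unlike univariate scores, ReliefF rewards features that only interact
    (e.g. XOR pairs).
    """
    X = _as_matrix(table)
    y = np.asarray(labels)
    n, d = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if counts.min() < k_neighbors + 1:
        raise ValueError("every class needs at least k_neighbors + 1 samples")
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}

    rng = np.random.default_rng(seed)
    span = X.max(axis=0) - X.min(axis=0)
    span[span <= 0] = 1.0  # constant features contribute zero diff
    Z = X / span

    if n_sample is None or n_sample >= n:
        sample_idx = np.arange(n)
    else:
        sample_idx = rng.choice(n, size=n_sample, replace=False)

    by_class = {c: np.nonzero(y == c)[0] for c in classes}
    nn_by_class = {
        c: NearestNeighbors(n_neighbors=min(k_neighbors + 1, idx.size)).fit(Z[idx])
        for c, idx in by_class.items()
    }

    W = np.zeros(d)
    m = sample_idx.size
    for i in sample_idx:
        ci = y[i]
        # hits: k nearest same-class neighbors, excluding self
        idx_pool = by_class[ci]
        _, knn = nn_by_class[ci].kneighbors(Z[i][None, :])
        hit_rows = [idx_pool[j] for j in knn[0] if idx_pool[j] != i][:k_neighbors]
        hit_diff = np.abs(Z[hit_rows] - Z[i]).mean(axis=0)
        miss_term = np.zeros(d)
        for c in classes:
            if c == ci:
                continue
            pool = by_class[c]
            _, knn_m = nn_by_class[c].kneighbors(Z[i][None, :])
            miss_rows = pool[knn_m[0][:k_neighbors]]
            diff = np.abs(Z[miss_rows] - Z[i]).mean(axis=0)
            miss_term += priors[c] / (1.0 - priors[ci]) * diff
        W += (miss_term - hit_diff) / m
    return W
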