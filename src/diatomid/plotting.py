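"""Plot helpers for experiment reports: 2-D embeddings and confusion matrices."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_embedding(report, kind: str = "lda", ax=None):
    """Scatter the first two reduced dimensions, colored by class, with
    class centroids marked."""
    if kind not in ("lda", "pca"):
        raise ValueError("kind must be 'lda' or 'pca'")
    Z = report.lda_embedding if kind == "lda" else report.pca_embedding
    if Z.shape[1] == 1:  # two-class LDA has a single axis
        Z = np.column_stack([Z[:, 0], np.zeros(Z.shape[0])])
    y = report.feature_table["label"].to_numpy()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for c in np.unique(y):
        pts = Z[y == c]
        ax.scatter(pts[:, 0], pts[:, 1], s=12, label=f"class {c}")
        cx, cy = pts.mean(axis=0)
        ax.plot(cx, cy, "k+", markersize=12)
    sil = report.lda_silhouette if kind == "lda" else report.pca_silhouette
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    ax.set_title(f"{kind.upper()} embedding (silhouette {sil:.2f})")
    ax.legend(fontsize=7)
    return ax


def plot_confusion(confusion: np.ndarray, classes=None, ax=None, title=""):
    """Heatmap of a confusion matrix (rows = truth, cols = predicted)."""
    conf = np.asarray(confusion)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(conf, cmap="Blues")
    n = conf.shape[0]
    ticks = classes if classes is not None else np.arange(n)
    ax.set_xticks(np.arange(n), labels=ticks)
    ax.set_yticks(np.arange(n), labels=ticks)
    for i in range(n):
        for j in range(n):
            if conf[i, j]:
                ax.text(j, i, str(conf[i, j]), ha="center", va="center",
                        color="white" if conf[i, j] > conf.max() / 2 else "black",
                        fontsize=8)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    if title:
        ax.set_title(title)
    return ax
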