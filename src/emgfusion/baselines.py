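"""PCA / LDA + minimum-L2-distance baselines (EmgPCA-L2, EmgLDA-L2).

Feature sequences are flattened row-major into ``5*S*m`` vectors,
projected to a reduced space by PCA (training-mean centering) or Fisher
LDA (within-class scatter ridge-regularized by ``1e-6 * trace`` for
invertibility), and queries are classified by the label of the nearest
training sample in the reduced space (1-NN, Euclidean).  A
class-centroid variant is available since "closest distance to the
label data" is ambiguous between the two readings.  Sweeping the
component count yields the dimension-vs-accuracy curves used to compare
against the two-stream ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from emgfusion.time_features import FeatureSequence

__all__ = [
    "ReducedSpace",
    "vectorize_sequences",
    "fit_reduce",
    "classify_nearest",
    "accuracy_sweep",
]


def vectorize_sequences(sequences: Sequence) -> np.ndarray:
    """Flatten feature sequences row-major into an (n, 5*S*m) matrix."""
    mats = [
        s.values if isinstance(s, FeatureSequence) else np.asarray(s, dtype=float)
        for s in sequences
    ]
    if not mats:
        raise ValueError("no sequences given")
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValueError(f"inconsistent sequence shapes: {m.shape} vs {shape}")
    return np.stack([m.reshape(-1) for m in mats])


@dataclass
class ReducedSpace:
    """A fitted projection plus the projected, label-sorted training data."""

    method: str
    n_components: int
    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features)
    train_projected: np.ndarray
    train_labels: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean.size:
            raise ValueError(
                f"query dimensionality {X.shape[1]} != fitted {self.mean.size}"
            )
        return (X - self.mean) @ self.components.T


def _fit_lda(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """Fisher discriminant directions via the generalized eigenproblem Sb v = l Sw v."""
    classes = np.unique(y)
    n, d = X.shape
    mean = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        dc = Xc - mc
        Sw += dc.T @ dc
        dm = (mc - mean)[:, None]
        Sb += Xc.shape[0] * (dm @ dm.T)
    Sw += np.eye(d) * (1e-6 * np.trace(Sw) / d + 1e-12)
    from scipy.linalg import eigh

    vals, vecs = eigh(Sb, Sw)
    order = np.argsort(vals)[::-1][:n_components]
    W = vecs[:, order].T  # (n_components, d)
    # sign convention: largest-magnitude coefficient positive
    for row in W:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1
    return W


def fit_reduce(
    train_vectors: np.ndarray,
    train_labels: Sequence,
    method: str = "pca",
    n_components: int = 10,
) -> ReducedSpace:
    """Fit a PCA or LDA projection and store the projected training set.

    PCA components are bounded by ``min(n_samples, n_features)``; LDA by
    ``n_classes - 1``.  Training rows are sorted by (label, original
    index) so that distance ties resolve toward the lowest class.
    """
    X = np.asarray(train_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("train_vectors must be a nonempty (n, d) matrix")
    y = np.asarray(train_labels)
    if y.size != X.shape[0]:
        raise ValueError("label count does not match vector count")
    if method == "pca":
        max_c = min(X.shape)
        if not 1 <= n_components <= max_c:
            raise ValueError(f"pca n_components must be in [1, {max_c}], got {n_components}")
        if np.allclose(X.var(axis=0), 0.0):
            raise ValueError("degenerate training set: zero variance in every feature")
        pca = PCA(n_components=n_components, svd_solver="full")
        pca.fit(X)
        mean, components = pca.mean_, pca.components_
    elif method == "lda":
        n_classes = np.unique(y).size
        if n_classes < 2:
            raise ValueError("lda needs at least 2 classes")
        if not 1 <= n_components <= n_classes - 1:
            raise ValueError(
                f"lda n_components must be in [1, {n_classes - 1}], got {n_components}"
            )
        mean = np.zeros(X.shape[1])
        components = _fit_lda(X, y, n_components)
    else:
        raise ValueError(f"unknown reduction method {method!r}; use 'pca' or 'lda'")
    order = np.lexsort((np.arange(y.size), y.astype(str)))
    space = ReducedSpace(
        method=method,
        n_components=n_components,
        mean=mean,
        components=components,
        train_projected=np.empty(0),
        train_labels=y[order],
    )
    space.train_projected = space.transform(X[order])
    return space


def classify_nearest(space: ReducedSpace, query_vectors: np.ndarray, strategy: str = "nn") -> np.ndarray:
    """Minimum-L2-distance classification in the reduced space.

    ``strategy="nn"`` assigns each query the label of its nearest
    training sample; ``"centroid"`` the label of the nearest class mean.
    Ties resolve to the lowest class (training rows are label-sorted).
    """
    if space.train_projected.size == 0:
        raise ValueError("empty training set in reduced space")
    Q = space.transform(query_vectors)
    if strategy == "nn":
        d = cdist(Q, space.train_projected)
        return space.train_labels[np.argmin(d, axis=1)]
    if strategy == "centroid":
        classes = []
        centroids = []
        for c in pd.unique(space.train_labels):
            classes.append(c)
            centroids.append(space.train_projected[space.train_labels == c].mean(axis=0))
        d = cdist(Q, np.stack(centroids))
        return np.asarray(classes, dtype=space.train_labels.dtype)[np.argmin(d, axis=1)]
    raise ValueError(f"unknown strategy {strategy!r}; use 'nn' or 'centroid'")


def accuracy_sweep(
    train_vectors: np.ndarray,
    train_labels: Sequence,
    test_vectors: np.ndarray,
    test_labels: Sequence,
    method: str = "pca",
    dims: Sequence[int] | None = None,
    strategy: str = "nn",
) -> pd.DataFrame:
    """Accuracy for each reduced dimension — the dimension-sweep curve.

    Returns a DataFrame with columns ``dim`` and ``accuracy`` (percent).
    """
    y_test = np.asarray(test_labels)
    if dims is None:
        if method == "lda":
            dims = range(1, np.unique(np.asarray(train_labels)).size)
        else:
            dims = range(1, min(np.asarray(train_vectors).shape) + 1)
    rows = []
    for d in dims:
        space = fit_reduce(train_vectors, train_labels, method=method, n_components=int(d))
        pred = classify_nearest(space, test_vectors, strategy=strategy)
        rows.append({"dim": int(d), "accuracy": 100.0 * float(np.mean(pred == y_test))})
    return pd.DataFrame(rows)
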