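"""Clustering and ordination for replicate-reproducibility QC.

``cluster_features`` builds a hierarchical tree of (typically significant)
features from row-z-scored log2 CPM, by default with 1 - Pearson correlation
distance and average linkage — the common expression-heatmap convention.

``sample_ordination`` reproduces the leading-fold-change MDS idea: the
distance between two samples is the root-mean-square of the ``top_k``
largest absolute log2 CPM differences between them, embedded in two
dimensions by classical metric scaling. Replicates of a condition should sit
next to each other; drug-sensitive and MDR conditions should separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from .core import ValidationError


@dataclass
class LinkageTree:
    """Agglomeration record: scipy-style (n-1, 4) merge matrix plus leaf labels."""

    merges: np.ndarray
    leaves: list[str]


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame            # index: sample label; columns dim1, dim2
    distances: pd.DataFrame = field(repr=False)


def cluster_features(log2cpm: pd.DataFrame, distance: str = "pearson",
                     linkage: str = "average") -> LinkageTree:
    """Hierarchical clustering of features (rows) after per-row z-scoring."""
    if log2cpm.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 features")
    values = log2cpm.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if distance == "pearson" and np.any(sd == 0):
        bad = log2cpm.index[int(np.argmax(sd == 0))]
        raise ValidationError(
            f"feature {bad!r} is constant across samples; correlation distance undefined")
    z = (values - values.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)[:, None]
    metric = {"pearson": "correlation", "euclidean": "euclidean"}.get(distance)
    if metric is None:
        raise ValidationError(f"unknown distance {distance!r}; use 'pearson' or 'euclidean'")
    d = pdist(z, metric=metric)
    d = np.clip(d, 0.0, None)  # guard tiny negative correlation distances
    merges = scipy_linkage(d, method=linkage)
    return LinkageTree(merges=merges, leaves=list(log2cpm.index))


def leading_logfc_distances(log2cpm: pd.DataFrame, top_k: int = 500) -> pd.DataFrame:
    """Pairwise RMS of the top_k largest absolute log2 CPM differences."""
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    values = log2cpm.to_numpy(dtype=float)
    labels = list(log2cpm.columns)
    n = len(labels)
    k = min(top_k, values.shape[0])
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(values[:, i] - values[:, j])
            top = np.partition(diff, len(diff) - k)[len(diff) - k:]
            dist[i, j] = dist[j, i] = np.sqrt(np.mean(top ** 2))
    return pd.DataFrame(dist, index=labels, columns=labels)


def sample_ordination(log2cpm: pd.DataFrame, top_k: int = 500) -> OrdinationResult:
    """Two-dimensional classical-scaling embedding of the samples."""
    if log2cpm.shape[1] < 3:
        raise ValidationError("ordination needs at least 3 samples")
    dist = leading_logfc_distances(log2cpm, top_k=top_k)
    coords = classical_mds(dist.to_numpy(), n_dim=2)
    cdf = pd.DataFrame(coords, index=dist.index, columns=["dim1", "dim2"])
    return OrdinationResult(coordinates=cdf, distances=dist)


def classical_mds(dist: np.ndarray, n_dim: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric scaling of a symmetric distance matrix.

    Eigenvectors are ordered by descending eigenvalue; each dimension's sign
    is fixed by making its largest-magnitude loading positive. Non-positive
    eigenvalues yield zero coordinates.
    """
    n = dist.shape[0]
    d2 = dist ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, n_dim))
    for k in range(min(n_dim, n)):
        if vals[k] > 1e-12:
            v = vecs[:, k] * np.sqrt(vals[k])
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            coords[:, k] = v
    return coords
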