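"""Spatial segmentation of pixel spectra and discriminative m/z discovery.

Pixels are clustered by unbiased hierarchical clustering of their binned
spectra (default: Ward linkage on Euclidean distances of TIC-normalized,
square-root-stabilized 0.1 Da bins), producing a dendrogram that can be cut
at any requested number of clusters.  Cluster-discriminative m/z values are
then found by the ROC criterion: for each bin, the AUC of in-cluster vs
out-of-cluster per-pixel intensities, reported when it reaches a threshold
(default 0.7).  The AUC is one-sided — only bins *enriched* in the cluster
count as its markers; depleted bins (AUC < 0.5) are not flipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import pairwise_distances

from .ims import BinnedMatrix


@dataclass
class SegmentationResult:
    """Dendrogram over pixels plus the machinery to cut it at any k.

    ``linkage_matrix`` is a scipy hierarchical-clustering linkage over the
    (possibly subsampled) tree pixels; ``labels_at(k)`` cuts it and, when
    the tree was built on a subsample, assigns the remaining pixels to the
    nearest cluster centroid in feature space.
    """

    linkage_matrix: np.ndarray
    tree_indices: np.ndarray  # indices of pixels the tree was built on
    n_pixels: int
    linkage: str
    distance: str
    _features: np.ndarray | None = None  # pixels x reduced-bins, for assignment

    def labels_at(self, k: int) -> np.ndarray:
        """Cluster labels (0..k-1) for every pixel at a k-cluster cut."""
        if k < 1 or k > self.n_pixels:
            raise ValueError(f"k must be in [1, {self.n_pixels}], got {k}")
        if k > len(self.tree_indices):
            raise ValueError(f"k={k} exceeds the {len(self.tree_indices)} tree pixels")
        tree_labels = sch.fcluster(self.linkage_matrix, t=k, criterion="maxclust") - 1
        labels = np.full(self.n_pixels, -1, dtype=int)
        labels[self.tree_indices] = tree_labels
        if len(self.tree_indices) < self.n_pixels:
            X = self._features
            centroids = np.stack(
                [X[self.tree_indices[tree_labels == c]].mean(axis=0) for c in range(k)]
            )
            rest = np.flatnonzero(labels < 0)
            d = pairwise_distances(X[rest], centroids)
            labels[rest] = d.argmin(axis=1)
        # relabel in order of first appearance for reproducible ids
        remap: dict[int, int] = {}
        out = np.empty_like(labels)
        for i, lab in enumerate(labels):
            if lab not in remap:
                remap[lab] = len(remap)
            out[i] = remap[lab]
        return out


class HierarchicalSegmenter(ClusterMixin, BaseEstimator):
    """Hierarchical clustering of binned pixel spectra, scikit-learn style.

    Parameters
    ----------
    n_clusters : int
        Number of clusters for the default cut exposed via ``labels_`` /
        ``fit_predict``; any other cut is available from
        ``result_.labels_at(k)``.
    linkage : str, default "ward"
    metric : str, default "euclidean"
    sqrt_transform : bool, default True
        Apply a square-root variance stabilization to intensities before
        computing distances.
    max_tree_pixels : int, default 5000
        Build the dendrogram on a seeded random subsample of at most this
        many pixels and assign the rest to nearest centroids; keeps the
        distance matrix desk-sized.  Set above the pixel count for exact mode.
    min_bin_occupancy : float, default 0.01
        Drop m/z bins occupied in less than this fraction of pixels before
        computing distances.  Sporadic single-pixel (noise) bins carry no
        clustering signal but dominate the column count of a centroided
        dataset; set to 0 to keep every occupied bin.
    random_state : int, default 0

    Attributes
    ----------
    labels_ : per-pixel cluster labels at the ``n_clusters`` cut.
    result_ : the full :class:`SegmentationResult`.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        linkage: str = "ward",
        metric: str = "euclidean",
        sqrt_transform: bool = True,
        max_tree_pixels: int = 5000,
        min_bin_occupancy: float = 0.01,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.linkage = linkage
        self.metric = metric
        self.sqrt_transform = sqrt_transform
        self.max_tree_pixels = max_tree_pixels
        self.min_bin_occupancy = min_bin_occupancy
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, BinnedMatrix):
            X = X.matrix
        if sp.issparse(X):
            occupancy = np.asarray((X != 0).sum(axis=0)).ravel() / X.shape[0]
            keep = occupancy > max(self.min_bin_occupancy, 0.0)
            if not keep.any():
                keep = occupancy > 0
            X = np.asarray(X[:, keep].todense())
        else:
            X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if self.n_clusters < 1 or self.n_clusters > n:
            raise ValueError(f"n_clusters={self.n_clusters} out of range for {n} pixels")
        if self.sqrt_transform:
            X = np.sqrt(np.maximum(X, 0.0))
        rng = np.random.default_rng(self.random_state)
        if n > self.max_tree_pixels:
            tree_idx = np.sort(rng.choice(n, self.max_tree_pixels, replace=False))
        else:
            tree_idx = np.arange(n)
        D = pairwise_distances(X[tree_idx], metric=self.metric)
        np.fill_diagonal(D, 0.0)
        Z = sch.linkage(squareform(D, checks=False), method=self.linkage)
        self.result_ = SegmentationResult(
            linkage_matrix=Z,
            tree_indices=tree_idx,
            n_pixels=n,
            linkage=self.linkage,
            distance=self.metric,
            _features=X,
        )
        self.labels_ = self.result_.labels_at(self.n_clusters)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def segment(
    matrix: BinnedMatrix,
    k: int,
    linkage: str = "ward",
    distance: str = "euclidean",
    seed: int = 0,
    max_tree_pixels: int = 5000,
) -> SegmentationResult:
    """Cluster pixel spectra hierarchically; thin wrapper over the estimator."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    est = HierarchicalSegmenter(
        n_clusters=k,
        linkage=linkage,
        metric=distance,
        random_state=seed,
        max_tree_pixels=max_tree_pixels,
    )
    est.fit(matrix)
    return est.result_


class DiscriminativeMass(NamedTuple):
    mz: float
    cluster: int
    auc: float


def roc_auc_bins(values: np.ndarray, in_cluster: np.ndarray) -> np.ndarray:
    """Column-wise AUC of in-cluster vs out-of-cluster values.

    Equivalent to the Mann-Whitney U statistic divided by n1*n2, with ties
    counted one half (average ranks).
    """
    n1 = int(in_cluster.sum())
    n2 = len(in_cluster) - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both the cluster and its complement must be non-empty")
    ranks = rankdata(values, axis=0)
    r1 = ranks[in_cluster].sum(axis=0)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2)


def discriminative_mz(
    matrix: BinnedMatrix,
    labels: np.ndarray | SegmentationResult,
    cluster_id: int,
    auc_threshold: float = 0.7,
    k: int | None = None,
) -> list[DiscriminativeMass]:
    """Rank m/z bins by how well they mark a cluster (ROC AUC >= threshold).

    ``labels`` may be a per-pixel label array or a SegmentationResult (then
    ``k`` selects the cut).  Returns entries sorted by AUC descending, ties
    broken by ascending m/z.
    """
    if isinstance(labels, SegmentationResult):
        if k is None:
            raise ValueError("k is required when passing a SegmentationResult")
        labels = labels.labels_at(k)
    labels = np.asarray(labels)
    in_cluster = labels == cluster_id
    if not in_cluster.any():
        raise ValueError(f"cluster {cluster_id} is empty")
    if in_cluster.all():
        raise ValueError(f"cluster {cluster_id} has an empty complement")
    # only bins with signal somewhere can exceed AUC 0.5
    occupancy = np.asarray((matrix.matrix != 0).sum(axis=0)).ravel()
    cand = np.flatnonzero(occupancy > 0)
    if not len(cand):
        return []
    vals = np.asarray(matrix.matrix[:, cand].todense())
    auc = roc_auc_bins(vals, in_cluster)
    keep = auc >= auc_threshold
    entries = [
        DiscriminativeMass(float(matrix.bin_centers[c]), int(cluster_id), float(a))
        for c, a in zip(cand[keep], auc[keep])
    ]
    entries.sort(key=lambda e: (-e.auc, e.mz))
    return entries


def export_mass_list(entries: list[DiscriminativeMass], path) -> None:
    """Write a discriminative mass list as TSV (columns mz, cluster, auc)."""
    if not entries:
        raise ValueError("refusing to export an empty mass list")
    with open(path, "w") as fh:
        fh.write("mz\tcluster\tauc\n")
        for e in entries:
            fh.write(f"{e.mz!r}\t{e.cluster}\t{e.auc!r}\n")


def read_mass_list(path) -> list[DiscriminativeMass]:
    """Read a mass list written by :func:`export_mass_list`."""
    entries = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["mz", "cluster", "auc"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            mz, cluster, auc = line.strip().split("\t")
            entries.append(DiscriminativeMass(float(mz), int(cluster), float(auc)))
    return entries
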