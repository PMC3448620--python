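"""Derive isotopically distinct regions by k-means over a standardized stack.

The published African cluster map partitions the continent into four regions
by multivariate clustering of the stacked δ²H/δ¹³C/δ¹⁵N isoscapes; here the
same step runs on any aligned stack.  Layers are standardized first so the
~100‰ span of δ²H does not dominate the ~10‰ spans of δ¹³C/δ¹⁵N.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from isoassign.grids import IsoscapeStack

__all__ = ["ClusterMap", "ClusteringConfig", "standardize_layers",
           "cluster_stack", "match_labels", "DegenerateLayerError"]


class DegenerateLayerError(ValueError):
    """A layer is constant over valid cells and cannot be standardized."""


@dataclasses.dataclass
class ClusterMap:
    """Integer label raster: 0 = nodata/unassigned, 1..K = cluster id."""

    labels: np.ndarray
    n_clusters: int
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 0 or self.labels.max() > self.n_clusters:
            raise ValueError("labels must lie in 0..K")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def cell_counts(self) -> np.ndarray:
        """Cells per cluster id 1..K."""
        return np.bincount(self.labels.ravel(), minlength=self.n_clusters + 1)[1:]

    def cell_center_lons(self) -> np.ndarray:
        west, _ = self.origin
        return west + (np.arange(self.shape[1]) + 0.5) * self.cell_size


@dataclasses.dataclass(frozen=True)
class ClusteringConfig:
    n_clusters: int = 4
    n_init: int = 10
    max_iter: int = 300
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.n_init < 1:
            raise ValueError("n_clusters and n_init must be >= 1")


def standardize_layers(stack: IsoscapeStack) -> IsoscapeStack:
    """Rescale each layer to mean 0, SD 1 over the valid mask."""
    layers = stack.layers.copy()
    for i in range(stack.n_layers):
        vals = layers[i][stack.mask]
        mu, sd = vals.mean(), vals.std(ddof=0)
        if sd == 0 or np.unique(vals).size < 2:
            raise DegenerateLayerError(
                f"layer {stack.labels[i]!r} is constant over valid cells")
        layers[i] = (layers[i] - mu) / sd
    return dataclasses.replace(stack, layers=layers)


def cluster_stack(stack: IsoscapeStack, config: ClusteringConfig) -> ClusterMap:
    """Partition valid cells into K clusters in isotope space.

    k-means with ``n_init`` restarts; deterministic given ``config.seed``.
    Labels are canonicalized 1..K by descending cell count (ties broken by
    ascending centroid value of the first layer) so ids are stable across
    runs.
    """
    work = standardize_layers(stack) if config.standardize else stack
    X = work.valid_matrix()
    k = config.n_clusters
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError("fewer distinct valid cells than clusters")
    km = KMeans(n_clusters=k, n_init=config.n_init, max_iter=config.max_iter,
                random_state=config.seed)
    raw = km.fit_predict(X)
    counts = np.bincount(raw, minlength=k)
    order = sorted(range(k), key=lambda j: (-counts[j], km.cluster_centers_[j, 0]))
    relabel = np.empty(k, dtype=int)
    for new_id, j in enumerate(order, start=1):
        relabel[j] = new_id
    labels = np.zeros(stack.shape, dtype=int)
    labels[stack.mask] = relabel[raw]
    return ClusterMap(labels, k, origin=stack.origin, cell_size=stack.cell_size)


def match_labels(map_a: ClusterMap, map_b: ClusterMap):
    """Best label permutation of ``map_b`` onto ``map_a`` and the agreement.

    Returns ``(perm, agreement)`` where ``perm[j]`` is the label of ``map_a``
    matched to label ``j + 1`` of ``map_b`` and agreement is the fraction of
    jointly labelled cells on which the permuted maps agree.  Solved by the
    Hungarian algorithm on the label confusion matrix (exhaustive search
    gives the same optimum; see tests).
    """
    if map_a.shape != map_b.shape:
        raise ValueError("cluster maps differ in shape")
    if map_a.n_clusters != map_b.n_clusters:
        raise ValueError("cluster maps differ in K")
    k = map_a.n_clusters
    sel = (map_a.labels > 0) & (map_b.labels > 0)
    if not sel.any():
        raise ValueError("no jointly labelled cells")
    a, b = map_a.labels[sel] - 1, map_b.labels[sel] - 1
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (a, b), 1)
    rows, cols = linear_sum_assignment(-confusion)
    perm = np.empty(k, dtype=int)
    perm[cols] = rows + 1
    agreement = confusion[rows, cols].sum() / sel.sum()
    return perm, float(agreement)


def _match_labels_bruteforce(map_a: ClusterMap, map_b: ClusterMap):
    """Exhaustive-permutation reference for match_labels (K <= 6)."""
    k = map_a.n_clusters
    sel = (map_a.labels > 0) & (map_b.labels > 0)
    a, b = map_a.labels[sel], map_b.labels[sel]
    best, best_perm = -1.0, None
    for perm in itertools.permutations(range(1, k + 1)):
        mapped = np.asarray(perm)[b - 1]
        agree = np.mean(mapped == a)
        if agree > best:
            best, best_perm = agree, np.asarray(perm)
    return best_perm, float(best)
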