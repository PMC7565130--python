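"""K=3 clustering of a lesion's SUV histogram.

Voxel SUVs within a lesion are partitioned into K=3 clusters by k-means on
the 1-D value distribution.  The biological reading of the three clusters:
the least glycolytic cluster reflects differentiated cancer cells, the
intermediate cluster a mixed population (partial-volume mixing at 4 mm
resolution), and the most glycolytic cluster the proliferative
cancer-stem-cell compartment whose volume defines MTVcsc.

For 1-D data the within-cluster-sum-of-squares (WCSS) optimum is attained by
a contiguous partition of the sorted values and can be found exactly by
dynamic programming; this deterministic exact solver is the default, with
seeded Lloyd k-means (k-means++ initialization) retained as a fidelity mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .segmentation import LesionVOI

__all__ = [
    "ClusterPartition",
    "DegenerateHistogramError",
    "ClusteringError",
    "cluster_suv_histogram",
    "kmeans_1d_exact",
]


class DegenerateHistogramError(ValueError):
    pass


class ClusteringError(RuntimeError):
    pass


@dataclass(frozen=True)
class ClusterPartition:
    """A k-way split of a VOI's voxels, clusters numbered by ascending centroid.

    Cluster ``k-1`` (highest centroid) is the most glycolytic — the CSC
    compartment proxy.
    """

    labels: np.ndarray  # (n,) int in [0, k)
    centroids: np.ndarray  # (k,) ascending SUV
    wcss: float  # within-cluster sum of squares, SUV^2

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.intp)
        centroids = np.asarray(self.centroids, dtype=np.float64)
        k = centroids.size
        if np.any(np.diff(centroids) <= 0):
            raise ClusteringError(f"centroids must be strictly ascending: {centroids}")
        counts = np.bincount(labels, minlength=k)
        if labels.min(initial=0) < 0 or labels.max(initial=0) >= k:
            raise ClusteringError("cluster labels out of range")
        if np.any(counts == 0):
            raise ClusteringError("every cluster must be nonempty")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "centroids", centroids)

    @property
    def k(self) -> int:
        return int(self.centroids.size)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def _weighted_prefix(x: np.ndarray, w: np.ndarray):
    W = np.concatenate(([0.0], np.cumsum(w)))
    WX = np.concatenate(([0.0], np.cumsum(w * x)))
    WX2 = np.concatenate(([0.0], np.cumsum(w * x * x)))
    return W, WX, WX2


def kmeans_1d_exact(
    values: np.ndarray, k: int, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Globally WCSS-optimal 1-D k-means by dynamic programming.

    Works on the unique sorted values with multiplicities as weights, so the
    result is invariant under any permutation of the input.

    Returns
    -------
    labels : (n,) cluster id per input value, numbered by ascending centroid
    centroids : (k,) ascending cluster means
    wcss : the optimal within-cluster sum of squares
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if weights is None:
        x, inverse, w = np.unique(values, return_inverse=True, return_counts=True)
        w = w.astype(np.float64)
    else:
        weights = np.asarray(weights, dtype=np.float64).ravel()
        order = np.argsort(values, kind="stable")
        x = values[order]
        w = weights[order]
        inverse = np.empty_like(order)
        inverse[order] = np.arange(order.size)
        if np.any(np.diff(x) == 0):  # merge duplicates
            xu, start = np.unique(x, return_inverse=True)
            wu = np.zeros(xu.size)
            np.add.at(wu, start, w)
            inverse = start[inverse]
            x, w = xu, wu
    m = x.size
    if m < k:
        raise DegenerateHistogramError(
            f"degenerate histogram: only {m} distinct SUV value(s) for k={k}"
        )

    W, WX, WX2 = _weighted_prefix(x, w)

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # cost of segment x[i..j] inclusive, vectorized over i
        cnt = W[j + 1] - W[i]
        s = WX[j + 1] - WX[i]
        return (WX2[j + 1] - WX2[i]) - s * s / cnt

    D = np.full((k, m), np.inf)
    split = np.zeros((k, m), dtype=np.intp)
    idx0 = np.zeros(1, dtype=np.intp)
    for j in range(m):
        D[0, j] = seg_cost(idx0, j)[0]
    for c in range(1, k):
        for j in range(c, m):
            i = np.arange(c, j + 1)
            cand = D[c - 1, i - 1] + seg_cost(i, j)
            t = int(np.argmin(cand))
            D[c, j] = cand[t]
            split[c, j] = i[t]

    # backtrack cluster start indices in the unique-value axis
    starts = np.empty(k, dtype=np.intp)
    j = m - 1
    for c in range(k - 1, 0, -1):
        starts[c] = split[c, j]
        j = starts[c] - 1
    starts[0] = 0

    seg_label = np.zeros(m, dtype=np.intp)
    for c in range(1, k):
        seg_label[starts[c]:] = c
    centroids = np.array(
        [
            (WX[e + 1] - WX[s]) / (W[e + 1] - W[s])
            for s, e in zip(starts, np.append(starts[1:] - 1, m - 1))
        ]
    )
    labels = seg_label[inverse]
    return labels, centroids, float(D[k - 1, m - 1])


def _lloyd(values: np.ndarray, k: int, seed: int, weights: np.ndarray | None):
    vals = values.reshape(-1, 1)
    for attempt in range(10):
        km = KMeans(
            n_clusters=k, init="k-means++", n_init=1, random_state=int(seed) + attempt
        ).fit(vals, sample_weight=weights)
        centroids = km.cluster_centers_.ravel()
        order = np.argsort(centroids)
        sorted_centroids = centroids[order]
        counts = np.bincount(km.labels_, minlength=k)
        if np.any(counts == 0) or np.any(np.diff(sorted_centroids) <= 0):
            continue  # empty cluster or coincident centroids: reseed
        relabel = np.empty(k, dtype=np.intp)
        relabel[order] = np.arange(k)
        labels = relabel[km.labels_]
        return labels, sorted_centroids
    raise ClusteringError(
        f"Lloyd k-means failed to produce {k} distinct nonempty clusters "
        "in 10 seeded attempts"
    )


def _bin_values(values: np.ndarray, bin_width: float):
    lo = np.floor(values.min() / bin_width)
    bins = (np.floor(values / bin_width) - lo).astype(np.intp)
    centers_all = (lo + np.arange(bins.max() + 1) + 0.5) * bin_width
    used, inverse, counts = np.unique(bins, return_inverse=True, return_counts=True)
    return centers_all[used], counts.astype(np.float64), inverse


def cluster_suv_histogram(
    voi: LesionVOI,
    k: int = 3,
    method: str = "exact-dp",
    seed: int = 0,
    binned: bool = False,
    bin_width: float = 0.1,
) -> ClusterPartition:
    """Partition a VOI's voxel SUVs into ``k`` clusters.

    Parameters
    ----------
    method
        ``"exact-dp"`` (default): globally WCSS-optimal, deterministic.
        ``"lloyd"``: standard k-means with k-means++ seeding under ``seed``.
    binned
        Cluster 0.1-SUV histogram bins (bin centers weighted by counts)
        instead of raw voxel values — a sensitivity-analysis mode.
    """
    values = voi.suv
    if binned:
        centers, counts, inverse = _bin_values(values, bin_width)
        work, weights = centers, counts
    else:
        work, weights, inverse = values, None, None

    distinct = np.unique(work).size
    if distinct < k:
        raise DegenerateHistogramError(
            f"degenerate histogram: only {distinct} distinct SUV value(s) for k={k}"
        )

    if method == "exact-dp":
        labels, centroids, _ = kmeans_1d_exact(work, k, weights=weights)
    elif method == "lloyd":
        labels, centroids = _lloyd(work, k, seed, weights)
    else:
        raise ValueError(f"unknown clustering method: {method!r}")

    if inverse is not None:
        labels = labels[inverse]
    # WCSS always recomputed on the raw voxel values actually assigned
    wcss = float(sum(((values[labels == c] - values[labels == c].mean()) ** 2).sum()
                     for c in range(k)))
    centroids = np.array([values[labels == c].mean() for c in range(k)]) \
        if binned else centroids
    return ClusterPartition(labels=labels, centroids=centroids, wcss=wcss)
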