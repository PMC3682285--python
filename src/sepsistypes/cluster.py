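"""Clustering primitives: distances, PAM, Ward hierarchical, silhouettes.

Samples are the objects being clustered (matrix columns); genes are the
coordinates.  PAM is the classic BUILD + SWAP k-medoids of Kaufman &
Rousseeuw: BUILD greedily seeds the medoids, SWAP repeatedly applies the
best strictly cost-decreasing (medoid, non-medoid) exchange until none
exists.  All tie-breaks are by index order, so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from .errors import ParameterError
from .io import ExpressionMatrix, require_complete

__all__ = [
    "DistanceMatrix",
    "ClusterSolution",
    "distance_matrix",
    "pam",
    "hierarchical",
    "silhouette",
]


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distances with the metric that produced them."""

    values: np.ndarray
    metric: str = "euclidean"
    p: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ParameterError("distance matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ParameterError("distance matrix must be symmetric")
        if (np.diag(self.values) != 0).any():
            raise ParameterError("distance matrix diagonal must be zero")
        if (self.values < 0).any():
            raise ParameterError("distances must be non-negative")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterSolution:
    """Labels in 1..k plus silhouettes; medoid_indices only for PAM."""

    labels: np.ndarray
    k: int
    medoid_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    silhouettes: np.ndarray = field(default_factory=lambda: np.array([]))
    avg_silhouette: float = float("nan")
    total_cost: float = float("nan")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.medoid_indices = np.asarray(self.medoid_indices, dtype=int)
        self.silhouettes = np.asarray(self.silhouettes, dtype=float)

    @property
    def cluster_sizes(self) -> list[int]:
        return [int((self.labels == c).sum()) for c in range(1, self.k + 1)]


def distance_matrix(
    m: ExpressionMatrix, metric: str = "euclidean", p: float = 2.0
) -> DistanceMatrix:
    """Pairwise sample distances: d(i,j) = (sum_g |x_gi - x_gj|^p)^(1/p)."""
    require_complete(m, "distance computation")
    if metric == "euclidean":
        p = 2.0
    elif metric != "minkowski":
        raise ParameterError(f"unsupported metric {metric!r}")
    if p < 1:
        raise ParameterError("Minkowski exponent must be >= 1")
    X = m.values.T  # samples x genes
    d = squareform(pdist(X, metric="minkowski", p=p))
    return DistanceMatrix(d, metric=metric, p=p)


def silhouette(d: DistanceMatrix, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-sample silhouette widths s(i) = (b - a) / max(a, b).

    a(i) is the mean distance to the other members of i's cluster; b(i) is
    the smallest mean distance to any other cluster.  Conventions for the
    degenerate cases: singleton clusters get s = 0, and a = b = 0 (duplicate
    points) also gives s = 0.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ParameterError("silhouette requires at least 2 clusters")
    D = d.values
    n = d.n
    masks = {c: labels == c for c in uniq}
    sizes = {c: int(masks[c].sum()) for c in uniq}
    # mean distance from each sample to each cluster
    mean_to = np.column_stack([D[:, masks[c]].mean(axis=1) for c in uniq])
    s = np.zeros(n)
    for i in range(n):
        ci = np.nonzero(uniq == labels[i])[0][0]
        size = sizes[labels[i]]
        if size == 1:
            continue  # singleton convention: s = 0
        a = mean_to[i, ci] * size / (size - 1)  # exclude self from own-cluster mean
        b = np.min(np.delete(mean_to[i], ci))
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def _assign(D: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    """Nearest-medoid assignment; ties go to the lowest medoid index."""
    order = np.argsort(medoids)
    med_sorted = medoids[order]
    sub = D[:, med_sorted]
    return med_sorted[np.argmin(sub, axis=1)]


def pam(d: DistanceMatrix, k: int, seed: int | None = None) -> ClusterSolution:
    """Partitioning around medoids (BUILD + SWAP).

    ``seed`` is accepted for interface stability; the implementation is
    fully deterministic (all ties break by index order) and never consumes
    randomness.
    """
    n = d.n
    if not 2 <= k < n:
        raise ParameterError(f"k must satisfy 2 <= k < n (got k={k}, n={n})")
    D = d.values

    # BUILD: first medoid minimizes total distance; each next medoid
    # maximizes the cost reduction it brings.
    medoids = [int(np.argmin(D.sum(axis=0)))]
    dn = D[:, medoids[0]].copy()  # distance to nearest medoid
    while len(medoids) < k:
        gains = np.maximum(dn[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        j = int(np.argmax(gains))
        medoids.append(j)
        dn = np.minimum(dn, D[:, j])

    medoids_arr = np.array(sorted(medoids), dtype=int)

    # SWAP: accept the best strictly cost-decreasing exchange until none.
    while True:
        assign_med = _assign(D, medoids_arr)
        sub = D[:, medoids_arr]
        part = np.argsort(sub, axis=1)
        dn = sub[np.arange(n), part[:, 0]]
        ds = sub[np.arange(n), part[:, 1]] if k >= 2 else np.full(n, np.inf)

        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids_arr] = True
        candidates = np.nonzero(~is_medoid)[0]

        # cost change of swapping medoid m for candidate h, all pairs at once
        term_other = np.minimum(D[:, candidates] - dn[:, None], 0.0)
        term_own = np.minimum(D[:, candidates], ds[:, None]) - dn[:, None]
        total_other = term_other.sum(axis=0)
        delta = np.empty((k, len(candidates)))
        for mi, mval in enumerate(medoids_arr):
            own = assign_med == mval
            delta[mi] = total_other - term_other[own].sum(axis=0) + term_own[own].sum(axis=0)

        best = np.unravel_index(np.argmin(delta), delta.shape)
        if delta[best] >= -1e-12:
            break
        new = medoids_arr.copy()
        new[best[0]] = candidates[best[1]]
        medoids_arr = np.sort(new)

    assign_med = _assign(D, medoids_arr)
    # label clusters 1..k by medoid index order
    labels = np.searchsorted(medoids_arr, assign_med) + 1
    cost = float(D[np.arange(n), assign_med].sum())
    sil, avg = silhouette(d, labels) if k >= 2 else (np.zeros(n), 0.0)
    return ClusterSolution(
        labels=labels,
        k=k,
        medoid_indices=medoids_arr,
        silhouettes=sil,
        avg_silhouette=avg,
        total_cost=cost,
    )


def hierarchical(d: DistanceMatrix, k: int, linkage: str = "ward") -> ClusterSolution:
    """Agglomerative clustering (Lance-Williams Ward update) cut at k.

    Clusters are relabeled 1..k in order of first appearance along the
    sample index.  k = 1 and k = n are permitted (silhouettes are 0 by
    convention in both degenerate cases).
    """
    n = d.n
    if not 1 <= k <= n:
        raise ParameterError(f"k must satisfy 1 <= k <= n (got k={k}, n={n})")
    if k == 1:
        labels = np.ones(n, dtype=int)
        return ClusterSolution(labels=labels, k=1, silhouettes=np.zeros(n), avg_silhouette=0.0)
    Z = scipy_linkage(squareform(d.values, checks=False), method=linkage)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel by first appearance
    mapping: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        labels[i] = mapping[r]
    k_eff = len(mapping)
    if k_eff < 2:
        return ClusterSolution(labels=labels, k=k_eff, silhouettes=np.zeros(n), avg_silhouette=0.0)
    sil, avg = silhouette(d, labels)
    return ClusterSolution(labels=labels, k=k_eff, silhouettes=sil, avg_silhouette=avg)
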