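"""Resampling procedures for cluster-number choice and gene enrichment.

Both procedures repeatedly cluster the samples on a random third of the
candidate genes.  ``select_k`` votes, per repetition, for the cluster
number with the highest average silhouette width; ``enrich_genes`` runs an
outer x inner tournament in which each outer repetition's silhouette-
winning gene subset credits its members in a tally, and the most
frequently credited genes form the enriched subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .cluster import ClusterSolution, DistanceMatrix, hierarchical, pam
from .errors import ParameterError
from .io import ExpressionMatrix, require_complete
from scipy.spatial.distance import pdist, squareform

__all__ = ["KSelectionResult", "EnrichmentTally", "select_k", "enrich_genes"]


@dataclass
class KSelectionResult:
    votes: dict[int, int]
    chosen_k: int
    records: list[dict]  # per repetition: gene subset, best k, best silhouette
    algorithm: str

    @property
    def n_repetitions(self) -> int:
        return int(sum(self.votes.values()))


@dataclass
class EnrichmentTally:
    counts: dict[str, int]
    enriched_subset: list[str]
    n_outer: int
    subset_size: int


def _subset_distance(values: np.ndarray, rows: np.ndarray, metric: str, p: float) -> DistanceMatrix:
    X = values[rows].T
    d = squareform(pdist(X, metric="minkowski", p=(2.0 if metric == "euclidean" else p)))
    return DistanceMatrix(d, metric=metric, p=(2.0 if metric == "euclidean" else p))


def _cluster(d: DistanceMatrix, k: int, algorithm: str) -> ClusterSolution:
    if algorithm == "pam":
        return pam(d, k)
    if algorithm == "hierarchical":
        return hierarchical(d, k, linkage="ward")
    raise ParameterError(f"unknown algorithm {algorithm!r}")


def select_k(
    m: ExpressionMatrix,
    k_range: Iterable[int] = range(2, 11),
    n_reps: int = 100,
    subset_fraction: float = 1 / 3,
    algorithm: str = "pam",
    minkowski_p: float = 3.0,
    seed: int | None = None,
) -> KSelectionResult:
    """Vote for the cluster number over random gene thirds.

    Each repetition draws floor(G * subset_fraction) genes without
    replacement, clusters the samples at every k in ``k_range``, and
    records the k with the highest average silhouette width (ties to the
    smaller k).  The chosen k is the modal recorded k (ties to smaller).
    The PAM backend uses Euclidean distance; the hierarchical backend uses
    Minkowski distance (default exponent 3) with Ward agglomeration.
    """
    require_complete(m, "select_k")
    ks = sorted(set(int(k) for k in k_range))
    n = m.n_samples
    if not ks or ks[0] < 2 or ks[-1] >= n:
        raise ParameterError(f"k_range must lie within [2, n-1] = [2, {n - 1}]")
    G = m.n_genes
    if G < 3:
        raise ParameterError("need at least 3 genes")
    size = max(1, int(np.floor(G * subset_fraction)))
    metric = "euclidean" if algorithm == "pam" else "minkowski"

    rng = np.random.default_rng(seed)
    votes = {k: 0 for k in ks}
    records = []
    for _ in range(n_reps):
        rows = rng.choice(G, size=size, replace=False)
        d = _subset_distance(m.values, rows, metric, minkowski_p)
        best_k, best_sil = None, -np.inf
        for k in ks:
            sol = _cluster(d, k, algorithm)
            if sol.avg_silhouette > best_sil + 1e-12:
                best_k, best_sil = k, sol.avg_silhouette
        votes[best_k] += 1
        records.append(
            {"genes": [m.gene_ids[i] for i in rows], "best_k": best_k, "best_silhouette": best_sil}
        )
    top = max(votes.values())
    chosen = min(k for k, v in votes.items() if v == top)
    return KSelectionResult(votes=votes, chosen_k=chosen, records=records, algorithm=algorithm)


def enrich_genes(
    m: ExpressionMatrix,
    k: int,
    n_outer: int = 100,
    n_inner: int = 100,
    subset_fraction: float = 1 / 3,
    top_m: int = 100,
    seed: int | None = None,
) -> EnrichmentTally:
    """Tally genes over an outer x inner random-thirds PAM tournament.

    Inner loop: draw a random third of the genes, PAM-cluster the samples
    at k, record the average silhouette width.  The inner winner's genes
    each get +1 in the tally; after ``n_outer`` outer repetitions the
    ``top_m`` most frequently credited genes (count descending, ties
    lexicographic by gene ID) form the enriched subset.
    """
    require_complete(m, "enrich_genes")
    G = m.n_genes
    if top_m > G:
        import warnings

        warnings.warn(f"top_m={top_m} exceeds the {G} available genes; capping", stacklevel=2)
        top_m = G
    size = max(1, int(np.floor(G * subset_fraction)))
    rng = np.random.default_rng(seed)
    counts = np.zeros(G, dtype=int)
    for _ in range(n_outer):
        best_rows, best_sil = None, -np.inf
        for _ in range(n_inner):
            rows = rng.choice(G, size=size, replace=False)
            d = _subset_distance(m.values, rows, "euclidean", 2.0)
            sol = pam(d, k)
            if sol.avg_silhouette > best_sil + 1e-12:
                best_rows, best_sil = rows, sol.avg_silhouette
        counts[best_rows] += 1
    count_map = {m.gene_ids[i]: int(c) for i, c in enumerate(counts)}
    nonzero = [g for g in m.gene_ids if count_map[g] > 0]
    ranked = sorted(nonzero, key=lambda g: (-count_map[g], g))
    return EnrichmentTally(
        counts=count_map,
        enriched_subset=ranked[: min(top_m, len(ranked))],
        n_outer=n_outer,
        subset_size=size,
    )
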