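"""Co-expressed gene signature extraction and nearest-medoid transfer."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cluster import ClusterSolution, DistanceMatrix, silhouette
from .errors import ParameterError
from .io import ExpressionMatrix, require_complete
from .pipeline import SubtypeModel

__all__ = [
    "SignatureResult",
    "extract_coexpressed",
    "intersect_signatures",
    "classify_by_medoid",
]

log = logging.getLogger(__name__)


@dataclass
class SignatureResult:
    """Per-cohort co-expressed lists and their intersection (the signature)."""

    derivation_genes: list[str]
    validation_genes: list[str]
    signature: list[str]

    def __post_init__(self) -> None:
        assert set(self.signature) <= set(self.derivation_genes)
        assert set(self.signature) <= set(self.validation_genes)


def _standardized_contrast(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """|mean1 - mean2| / pooled within-subtype SD, per gene."""
    g1, g2 = values[:, labels == 1], values[:, labels == 2]
    n1, n2 = g1.shape[1], g2.shape[1]
    diff = np.abs(g1.mean(axis=1) - g2.mean(axis=1))
    ss = g1.var(axis=1, ddof=1) * (n1 - 1) + g2.var(axis=1, ddof=1) * (n2 - 1)
    pooled_sd = np.sqrt(ss / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(pooled_sd > 0, diff / pooled_sd, 0.0)
    return z


def extract_coexpressed(
    m: ExpressionMatrix,
    labels: np.ndarray,
    min_contrast: float = 1.0,
    module_range: range = range(2, 11),
) -> list[str]:
    """Return the co-expression module with the strongest subtype contrast.

    Genes are clustered hierarchically on correlation distance (1 - r,
    Ward); the dendrogram is cut into every module count in
    ``module_range`` and each module is scored by the mean standardized
    between-subtype difference of its member genes.  The best-scoring
    module is returned (in platform gene order) if its score exceeds
    ``min_contrast`` (SD units); otherwise an empty list with a warning.
    """
    require_complete(m, "extract_coexpressed")
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {1, 2}:
        raise ParameterError("labels must contain exactly subtypes 1 and 2")

    values = m.values
    sd = values.std(axis=1)
    keep = sd > 0
    if keep.sum() < 2:
        raise ParameterError("need at least 2 genes with variance")
    vals = values[keep]
    gene_ids = [g for g, k in zip(m.gene_ids, keep) if k]

    corr = np.corrcoef(vals)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="ward")
    contrast = _standardized_contrast(vals, labels)

    best_score, best_members = -np.inf, None
    for n_mod in module_range:
        if n_mod > len(gene_ids):
            break
        cut = fcluster(Z, t=n_mod, criterion="maxclust")
        for mod in np.unique(cut):
            members = cut == mod
            score = float(contrast[members].mean())
            # prefer higher score; on near-ties keep the larger module
            if score > best_score + 1e-9 or (
                abs(score - best_score) <= 1e-9
                and best_members is not None
                and members.sum() > best_members.sum()
            ):
                best_score, best_members = score, members
    if best_members is None or best_score <= min_contrast:
        log.warning("no co-expression module exceeds the contrast floor %.2f", min_contrast)
        return []
    return [g for g, sel in zip(gene_ids, best_members) if sel]


def intersect_signatures(a: list[str], b: list[str]) -> list[str]:
    """Order-stable intersection (order of the first, derivation, list)."""
    in_b = set(b)
    return [g for g in a if g in in_b]


def classify_by_medoid(model: SubtypeModel, m: ExpressionMatrix) -> ClusterSolution:
    """Assign each sample to the nearest derivation medoid (Euclidean).

    The matrix is restricted to the model's signature genes (an error
    lists any that are absent); ties go to the lower-numbered subtype.
    Silhouette widths are computed on the cohort's own Euclidean distance
    matrix under the assigned labels.
    """
    require_complete(m, "classify_by_medoid")
    missing = [g for g in model.signature_genes if g not in set(m.gene_ids)]
    if missing:
        raise ParameterError(f"matrix lacks signature genes: {missing[:10]}")
    sub = m.subset_genes(model.signature_genes)
    X = sub.values.T  # samples x genes
    dist_to_medoids = np.linalg.norm(X[:, None, :] - model.medoids[None, :, :], axis=2)
    labels = np.argmin(dist_to_medoids, axis=1) + 1  # argmin ties -> lower subtype
    from scipy.spatial.distance import pdist

    d = DistanceMatrix(squareform(pdist(X, metric="euclidean")))
    if len(np.unique(labels)) >= 2:
        sil, avg = silhouette(d, labels)
    else:
        sil, avg = np.zeros(len(labels)), 0.0
    return ClusterSolution(labels=labels, k=model.k, silhouettes=sil, avg_silhouette=avg)
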