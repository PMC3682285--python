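"""Internal validity checks for a clustering solution.

Three complementary views:

* bootstrap co-clustering stability — resample patients with replacement,
  re-cluster (hierarchical, Euclidean + Ward), and record how often each
  pair of patients lands in the same branch;
* the bimodality index BI = sqrt(pi*(1-pi)) * |mu1-mu2| / sigma from a
  two-component common-variance Gaussian mixture fit per gene — BI above
  about 1.1 corresponds to visually evident bimodality in a density plot;
* PCA separability — the variance fraction of the first principal
  component and the BI of its scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .cluster import DistanceMatrix, hierarchical
from .errors import DegenerateInputError, ParameterError
from .io import ExpressionMatrix, require_complete
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "BootstrapMap",
    "BimodalityFit",
    "bootstrap_stability",
    "bimodality_index",
    "bimodal_gene_fraction",
    "pca_separation",
    "PcaSeparation",
]

log = logging.getLogger(__name__)


@dataclass
class BootstrapMap:
    proportions: np.ndarray  # NaN where a pair was never co-drawn
    co_cluster_counts: np.ndarray
    co_drawn_counts: np.ndarray
    n_resamples: int
    sample_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class BimodalityFit:
    pi: float
    mu1: float
    mu2: float
    sigma: float
    delta: float
    bi: float
    converged: bool


def bootstrap_stability(
    m: ExpressionMatrix, k: int, n_resamples: int = 200, seed: int | None = None
) -> BootstrapMap:
    """Co-clustering proportions under bootstrap resampling of samples.

    Each resample draws n samples with replacement; the unique drawn
    samples are re-clustered (hierarchical, Euclidean distance, Ward) and
    every co-drawn pair's co-cluster count is incremented when the two sit
    in the same branch.  Resamples with fewer than k unique samples are
    skipped with a log entry.
    """
    require_complete(m, "bootstrap_stability")
    n = m.n_samples
    rng = np.random.default_rng(seed)
    co_cluster = np.zeros((n, n))
    co_drawn = np.zeros((n, n))
    skipped = 0
    for _ in range(n_resamples):
        drawn = np.unique(rng.integers(0, n, size=n))
        if len(drawn) <= k:
            skipped += 1
            continue
        X = m.values[:, drawn].T
        d = DistanceMatrix(squareform(pdist(X, metric="euclidean")))
        labels = hierarchical(d, k, linkage="ward").labels
        same = labels[:, None] == labels[None, :]
        ix = np.ix_(drawn, drawn)
        co_drawn[ix] += 1
        co_cluster[ix] += same
    if skipped:
        log.info("bootstrap_stability: skipped %d resamples with <= k unique samples", skipped)
    with np.errstate(invalid="ignore", divide="ignore"):
        proportions = np.where(co_drawn > 0, co_cluster / np.maximum(co_drawn, 1), np.nan)
    return BootstrapMap(
        proportions=proportions,
        co_cluster_counts=co_cluster,
        co_drawn_counts=co_drawn,
        n_resamples=n_resamples,
        sample_ids=list(m.sample_ids),
    )


def bimodality_index(
    x: np.ndarray,
    seed: int | None = 0,
    n_init: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> BimodalityFit:
    """Fit a two-component common-variance Gaussian mixture and return BI.

    The data are standardized before the EM fit, which makes the index
    exactly invariant to affine transforms x -> a*x + b; the reported
    component means are mapped back to the original scale.
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 10:
        raise ParameterError("bimodality_index needs at least 10 observations")
    if not np.isfinite(x).all():
        raise ParameterError("bimodality_index requires finite values")
    loc, scale = float(x.mean()), float(x.std())
    if scale == 0:
        return BimodalityFit(pi=0.5, mu1=loc, mu2=loc, sigma=0.0, delta=0.0, bi=0.0, converged=False)
    z = ((x - loc) / scale).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="tied",
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=None if seed is None else int(seed) % (2**31),
    )
    gm.fit(z)
    w = gm.weights_.ravel()
    mu = gm.means_.ravel()
    sigma_z = float(np.sqrt(gm.covariances_.ravel()[0]))
    order = np.argsort(mu)
    pi = float(w[order[0]])
    delta = float(abs(mu[order[1]] - mu[order[0]]) / sigma_z) if sigma_z > 0 else 0.0
    bi = float(np.sqrt(max(pi * (1 - pi), 0.0)) * delta)
    return BimodalityFit(
        pi=pi,
        mu1=float(mu[order[0]] * scale + loc),
        mu2=float(mu[order[1]] * scale + loc),
        sigma=sigma_z * scale,
        delta=delta,
        bi=bi,
        converged=bool(gm.converged_),
    )


def bimodal_gene_fraction(
    m: ExpressionMatrix,
    genes: list[str] | None = None,
    threshold: float = 1.1,
    seed: int | None = 0,
) -> tuple[float, pd.DataFrame]:
    """Fraction of the listed genes whose expression BI exceeds ``threshold``.

    Returns the fraction and a per-gene table of fits.
    """
    require_complete(m, "bimodal_gene_fraction")
    genes = list(m.gene_ids) if genes is None else list(genes)
    if not genes:
        raise DegenerateInputError("empty gene list")
    sub = m.subset_genes(genes)
    rows = []
    for gid, row in zip(sub.gene_ids, sub.values):
        fit = bimodality_index(row, seed=seed)
        rows.append({"gene_id": gid, "bi": fit.bi, "delta": fit.delta, "pi": fit.pi,
                     "converged": fit.converged})
    table = pd.DataFrame(rows)
    fraction = float((table["bi"] > threshold).mean())
    return fraction, table


@dataclass
class PcaSeparation:
    pc1_variance_fraction: float
    pc1_scores: np.ndarray
    pc1_bimodality: BimodalityFit


def pca_separation(m: ExpressionMatrix, labels: np.ndarray | None = None, seed: int | None = 0) -> PcaSeparation:
    """PC1 variance fraction and bimodality of PC1 scores.

    Samples are the observations and genes the variables; genes are
    centered, not scaled.  ``labels`` are accepted for interface symmetry
    but do not influence the decomposition.
    """
    require_complete(m, "pca_separation")
    if m.n_samples < 3:
        raise ParameterError("PCA needs at least 3 samples")
    X = (m.values - m.values.mean(axis=1, keepdims=True)).T  # samples x genes, gene-centered
    _, svals, vt = np.linalg.svd(X, full_matrices=False)
    var = svals**2
    scores = X @ vt[0]
    # deterministic orientation: largest-|loading| gene loads positively
    if vt[0][np.argmax(np.abs(vt[0]))] < 0:
        scores = -scores
    fit = bimodality_index(scores, seed=seed)
    return PcaSeparation(
        pc1_variance_fraction=float(var[0] / var.sum()),
        pc1_scores=scores,
        pc1_bimodality=fit,
    )
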