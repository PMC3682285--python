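"""Multi-stage subtype discovery on a derivation cohort.

Stage A restricts the matrix to the curated sepsis-related candidate
genes, selects the cluster number k by the random-thirds silhouette vote
(with both the PAM and the hierarchical backend), and PAM-clusters the
cohort on the candidate genes.  Stage B runs the random-thirds gene
enrichment tournament and re-clusters on the enriched (top-100) subset.
Stage C returns to the complete gene set: SAM contrasts the enriched
labels, the genes with q-value 0 become the final feature set, and a last
PAM clustering on them yields the final labels and the medoids.  The
medoids restricted to the final feature set form the transferable
subtype model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .cluster import ClusterSolution, distance_matrix, pam
from .errors import ParameterError, PipelineError
from .io import ExpressionMatrix, require_complete, restrict_to_gene_list
from .model_selection import enrich_genes, select_k
from .sam import sam_two_class, select_q_zero

__all__ = [
    "DiscoveryConfig",
    "StageRecord",
    "SubtypeModel",
    "DiscoveryResult",
    "discover",
    "compare_partitions",
]

log = logging.getLogger(__name__)

WEAK_STRUCTURE_SILHOUETTE = 0.15


@dataclass(frozen=True)
class DiscoveryConfig:
    """Knobs of the discovery pipeline with the study-scale defaults."""

    k_min: int = 2
    k_max: int = 10
    n_reps: int = 100  # select_k repetitions
    subset_fraction: float = 1 / 3
    n_outer: int = 100  # enrichment outer repetitions
    n_inner: int = 100  # enrichment candidate draws per repetition
    top_m: int = 100
    sam_permutations: int = 200
    minkowski_p: float = 3.0
    seed: int | None = 0

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)


@dataclass
class StageRecord:
    name: str
    n_genes: int
    gene_ids: list[str]
    solution: ClusterSolution

    @property
    def cluster_sizes(self) -> list[int]:
        return self.solution.cluster_sizes

    @property
    def avg_silhouette(self) -> float:
        return self.solution.avg_silhouette


@dataclass
class SubtypeModel:
    """Final gene signature plus medoid expression vectors — the classifier."""

    signature_genes: list[str]
    medoids: np.ndarray  # k x |signature_genes|
    medoid_sample_ids: list[str]
    k: int

    def __post_init__(self) -> None:
        self.medoids = np.asarray(self.medoids, dtype=float)
        if self.medoids.shape != (self.k, len(self.signature_genes)):
            raise ParameterError("medoid matrix shape must be k x |signature_genes|")
        if self.k < 2:
            raise ParameterError("a subtype model needs k >= 2")

    def to_dict(self) -> dict:
        return {
            "signature_genes": self.signature_genes,
            "medoids": self.medoids.tolist(),
            "medoid_sample_ids": self.medoid_sample_ids,
            "k": self.k,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubtypeModel":
        return cls(
            signature_genes=list(d["signature_genes"]),
            medoids=np.asarray(d["medoids"], dtype=float),
            medoid_sample_ids=list(d["medoid_sample_ids"]),
            k=int(d["k"]),
        )


@dataclass
class DiscoveryResult:
    model: SubtypeModel
    stages: dict[str, StageRecord]
    chosen_k: int
    k_votes: dict[str, dict[int, int]]  # per backend
    weak_structure: bool
    warnings: list[str] = field(default_factory=list)


def discover(
    m: ExpressionMatrix, sepsis_genes: list[str], config: DiscoveryConfig | None = None
) -> DiscoveryResult:
    """Run the three-stage discovery pipeline on an imputed derivation matrix."""
    config = config or DiscoveryConfig()
    require_complete(m, "discover")
    rng = np.random.default_rng(config.seed)
    stage_seeds = rng.integers(0, 2**31 - 1, size=4)

    # Stage A: candidate restriction, k selection with both backends, initial PAM
    candidates, report = restrict_to_gene_list(m, sepsis_genes)
    log.info("candidate list: %d requested, %d on platform", report.n_requested, report.n_found)
    warnings_: list[str] = []

    sel_pam = select_k(
        candidates, k_range=config.k_range, n_reps=config.n_reps,
        subset_fraction=config.subset_fraction, algorithm="pam", seed=int(stage_seeds[0]),
    )
    sel_hier = select_k(
        candidates, k_range=config.k_range, n_reps=config.n_reps,
        subset_fraction=config.subset_fraction, algorithm="hierarchical",
        minkowski_p=config.minkowski_p, seed=int(stage_seeds[1]),
    )
    if sel_pam.chosen_k != sel_hier.chosen_k:
        msg = (
            f"cluster-number backends disagree (PAM {sel_pam.chosen_k}, "
            f"hierarchical {sel_hier.chosen_k}); using PAM's"
        )
        log.warning(msg)
        warnings_.append(msg)
    k = sel_pam.chosen_k
    if k != 2:
        # the SAM refinement stage contrasts exactly two groups; a voted k
        # other than 2 means the cohort does not support the two-subtype model
        raise PipelineError(
            f"cluster-number vote chose k={k}; the SAM refinement stage is "
            "two-class, so discovery requires the cohort to support k=2"
        )

    d_init = distance_matrix(candidates)
    initial = pam(d_init, k)

    # Stage B: gene enrichment tournament, clustering on the enriched subset
    tally = enrich_genes(
        candidates, k, n_outer=config.n_outer, n_inner=config.n_inner,
        subset_fraction=config.subset_fraction, top_m=config.top_m, seed=int(stage_seeds[2]),
    )
    enriched_m = candidates.subset_genes(tally.enriched_subset)
    enriched = pam(distance_matrix(enriched_m), k)

    # Stage C: SAM on the complete gene set with the enriched labels
    sam = sam_two_class(
        m, enriched.labels, n_permutations=config.sam_permutations, seed=int(stage_seeds[3])
    )
    final_genes = select_q_zero(sam)
    if not final_genes:
        raise PipelineError(
            "no gene reached q = 0 in SAM; the subtype contrast is too weak for "
            "this cohort (consider more samples or a larger effect)"
        )
    final_m = m.subset_genes(final_genes)
    final = pam(distance_matrix(final_m), k)

    medoids = final_m.values[:, final.medoid_indices].T
    model = SubtypeModel(
        signature_genes=final_genes,
        medoids=medoids,
        medoid_sample_ids=[m.sample_ids[i] for i in final.medoid_indices],
        k=k,
    )
    stages = {
        "initial": StageRecord("initial", candidates.n_genes, list(candidates.gene_ids), initial),
        "enriched": StageRecord("enriched", enriched_m.n_genes, list(enriched_m.gene_ids), enriched),
        "final": StageRecord("final", final_m.n_genes, list(final_m.gene_ids), final),
    }
    weak = final.avg_silhouette < WEAK_STRUCTURE_SILHOUETTE
    if weak:
        msg = f"weak structure: final average silhouette {final.avg_silhouette:.3f} < {WEAK_STRUCTURE_SILHOUETTE}"
        log.warning(msg)
        warnings_.append(msg)
    return DiscoveryResult(
        model=model,
        stages=stages,
        chosen_k=k,
        k_votes={"pam": sel_pam.votes, "hierarchical": sel_hier.votes},
        weak_structure=weak,
        warnings=warnings_,
    )


def compare_partitions(a: np.ndarray, b: np.ndarray) -> tuple[int, float]:
    """Agreement count (maximized over label matchings) and adjusted Rand index."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ParameterError("label vectors must have equal length")
    ua, ub = np.unique(a), np.unique(b)
    contingency = np.array([[(np.logical_and(a == x, b == y)).sum() for y in ub] for x in ua])
    rows, cols = linear_sum_assignment(-contingency)
    agreement = int(contingency[rows, cols].sum())
    return agreement, float(adjusted_rand_score(a, b))
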