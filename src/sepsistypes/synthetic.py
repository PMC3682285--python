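"""Synthetic two-subtype microarray-like cohorts.

The generator emulates the statistical structure of an ICU sepsis
expression study: two latent subtypes of unequal size, a subset of
"signal" genes whose expression shifts between subtypes by a standardized
amount delta (in units of the within-subtype SD, so the population
bimodality index of a signal gene is sqrt(pi*(1-pi))*delta), uninformative
noise genes, missing-at-random entries, optional samples forced above the
80% missingness threshold, a curated candidate gene list mixing true
signal genes with decoys, and subtype-linked clinical attributes.

Defaults mirror a derivation cohort of 55 septic patients profiled on a
365-gene candidate panel with ~10% truly discriminating genes and a
severe-sepsis prevalence of 36% vs 9% between subtypes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .io import ClinicalTable, ExpressionMatrix, write_clinical, write_expression, write_gene_list

import pandas as pd

__all__ = [
    "ClinicalAttributeSpec",
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_cohort_pair",
    "write_cohort",
]


@dataclass(frozen=True)
class ClinicalAttributeSpec:
    """One subtype-linked clinical attribute.

    binary: params = (prevalence in subtype 1, prevalence in subtype 2).
    continuous: params = (mean in subtype 1, mean in subtype 2, common SD).
    """

    name: str
    kind: str  # "binary" | "continuous"
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind == "binary":
            if len(self.params) != 2 or not all(0 <= p <= 1 for p in self.params):
                raise ParameterError(f"binary attribute {self.name!r} needs two prevalences in [0,1]")
        elif self.kind == "continuous":
            if len(self.params) != 3 or self.params[2] <= 0:
                raise ParameterError(f"continuous attribute {self.name!r} needs (mean1, mean2, sd>0)")
        else:
            raise ParameterError(f"unknown attribute kind {self.kind!r}")


DEFAULT_CLINICAL = (
    ClinicalAttributeSpec("severe_sepsis", "binary", (0.36, 0.09)),
    ClinicalAttributeSpec("septic_shock", "binary", (0.44, 0.64)),
    ClinicalAttributeSpec("age", "continuous", (63.0, 66.0, 15.0)),
    ClinicalAttributeSpec("apache_ii", "continuous", (19.0, 19.0, 6.0)),
)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort. Deterministic given ``seed``."""

    n_samples: int = 55
    n_genes: int = 365
    n_signal_genes: int = 37
    subtype_proportion: float = 0.4  # fraction of samples in subtype 1
    delta: float = 3.0  # standardized between-subtype shift of signal genes
    within_sd: float = 1.0  # within-subtype SD, log2 units
    signal_direction: str = "coherent"  # "coherent": all signal genes shift the same way
    # (a coherently regulated module, as in a co-expressed signature);
    # "mixed": each signal gene's direction drawn at random.
    missing_rate: float = 0.01
    n_high_missing_samples: int = 0
    high_missing_fraction: float = 0.85  # strictly above the 0.80 filter threshold
    sepsis_gene_fraction: float = 0.8  # fraction of signal genes on the curated list
    n_decoy_genes: int | None = None  # noise genes added to the list; default = #included signal
    n_offplatform_genes: int = 0  # list members absent from the platform
    baseline_mean: float = 8.0  # mean log2 intensity of gene baselines
    baseline_sd: float = 1.0
    clinical_spec: tuple[ClinicalAttributeSpec, ...] = DEFAULT_CLINICAL
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_signal_genes > self.n_genes:
            raise ParameterError("n_signal_genes must not exceed n_genes")
        if not 0 < self.subtype_proportion < 1:
            raise ParameterError("subtype_proportion must be in (0, 1)")
        if self.delta < 0:
            raise ParameterError("delta must be >= 0")
        if self.within_sd <= 0:
            raise ParameterError("within_sd must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ParameterError("missing_rate must be in [0, 1)")
        if self.n_high_missing_samples > self.n_samples:
            raise ParameterError("n_high_missing_samples exceeds n_samples")
        if not 0.80 < self.high_missing_fraction < 1:
            raise ParameterError("high_missing_fraction must exceed the 0.80 filter threshold")
        if not 0 <= self.sepsis_gene_fraction <= 1:
            raise ParameterError("sepsis_gene_fraction must be in [0, 1]")
        if self.signal_direction not in ("coherent", "mixed"):
            raise ParameterError("signal_direction must be 'coherent' or 'mixed'")
        if self.n_samples < 4:
            raise ParameterError("need at least 4 samples")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    truth_labels: np.ndarray  # per-sample subtype in {1, 2}
    truth_signal_genes: list[str]
    sepsis_gene_list: list[str]
    spec: CohortSpec

    def __post_init__(self) -> None:
        self.truth_labels = np.asarray(self.truth_labels, dtype=int)
        assert len(self.truth_labels) == self.expression.n_samples
        assert set(self.truth_signal_genes) <= set(self.expression.gene_ids)


@dataclass
class _GenePanel:
    """Gene-level parameters shared by matched cohorts of one study."""

    gene_ids: list[str]
    baselines: np.ndarray
    signal_idx: np.ndarray
    signs: np.ndarray
    sepsis_list: list[str]


def _draw_panel(spec: CohortSpec, rng: np.random.Generator) -> _GenePanel:
    G = spec.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(G)]
    baselines = rng.normal(spec.baseline_mean, spec.baseline_sd, size=G)
    signal_idx = np.sort(rng.choice(G, size=spec.n_signal_genes, replace=False))
    if spec.signal_direction == "coherent":
        signs = np.ones(spec.n_signal_genes)
    else:
        signs = rng.choice([-1.0, 1.0], size=spec.n_signal_genes)

    n_incl = int(round(spec.sepsis_gene_fraction * spec.n_signal_genes))
    included = rng.choice(signal_idx, size=n_incl, replace=False) if n_incl else np.array([], dtype=int)
    noise_idx = np.setdiff1d(np.arange(G), signal_idx)
    n_decoy = spec.n_decoy_genes if spec.n_decoy_genes is not None else n_incl
    n_decoy = min(n_decoy, len(noise_idx))
    decoys = rng.choice(noise_idx, size=n_decoy, replace=False) if n_decoy else np.array([], dtype=int)
    listed = np.concatenate([included, decoys])
    sepsis_list = [gene_ids[i] for i in rng.permutation(listed)]
    sepsis_list += [f"OFF{i + 1:04d}" for i in range(spec.n_offplatform_genes)]
    return _GenePanel(gene_ids, baselines, signal_idx, signs, sepsis_list)


def _draw_samples(
    spec: CohortSpec, panel: _GenePanel, rng: np.random.Generator, sample_prefix: str = "S"
) -> SyntheticCohort:
    n, G = spec.n_samples, spec.n_genes
    gene_ids = panel.gene_ids
    sample_ids = [f"{sample_prefix}{i + 1:03d}" for i in range(n)]

    n1 = int(round(spec.subtype_proportion * n))
    n1 = min(max(n1, 1), n - 1)
    labels = rng.permutation(np.array([1] * n1 + [2] * (n - n1)))

    baselines, signal_idx, signs = panel.baselines, panel.signal_idx, panel.signs
    means = np.tile(baselines[:, None], (1, n))
    shift = spec.delta * spec.within_sd
    for j, g in enumerate(signal_idx):
        means[g, labels == 2] += signs[j] * shift
    values = means + rng.normal(0.0, spec.within_sd, size=(G, n))

    # missing-at-random mask, then forced high-missing samples
    if spec.missing_rate > 0:
        values[rng.random((G, n)) < spec.missing_rate] = np.nan
    if spec.n_high_missing_samples > 0:
        high = rng.choice(n, size=spec.n_high_missing_samples, replace=False)
        n_mask = int(np.ceil(spec.high_missing_fraction * G))
        for s in high:
            values[rng.choice(G, size=n_mask, replace=False), s] = np.nan
    # imputation needs >= 1 observed value per gene
    for g in np.nonzero(np.isnan(values).all(axis=1))[0]:
        values[g, rng.integers(n)] = baselines[g]

    expression = ExpressionMatrix(values, list(gene_ids), sample_ids)

    clin: dict[str, np.ndarray] = {}
    for attr in spec.clinical_spec:
        if attr.kind == "binary":
            p = np.where(labels == 1, attr.params[0], attr.params[1])
            clin[attr.name] = (rng.random(n) < p).astype(int)
        else:
            mu = np.where(labels == 1, attr.params[0], attr.params[1])
            clin[attr.name] = rng.normal(mu, attr.params[2])
    clinical = ClinicalTable(pd.DataFrame(clin, index=pd.Index(sample_ids, name="sample_id")))

    return SyntheticCohort(
        expression=expression,
        clinical=clinical,
        truth_labels=labels,
        truth_signal_genes=[gene_ids[i] for i in signal_idx],
        sepsis_gene_list=list(panel.sepsis_list),
        spec=spec,
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort from the two-subtype Gaussian-mixture model.

    Signal gene g has subtype means (mu_g, mu_g + sign_g * delta * within_sd)
    and common SD ``within_sd``; noise genes are a single Gaussian.  With
    delta = 0 the matrix has no subtype structure by construction.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    panel = _draw_panel(spec, rng)
    return _draw_samples(spec, panel, rng)


def generate_cohort_pair(
    derivation: CohortSpec, validation: CohortSpec
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Matched derivation/validation cohorts sharing one gene panel.

    Gene identities, baselines, signal-gene positions, shift directions
    and the curated candidate list are drawn once from the derivation
    spec; each cohort then draws its own samples (the validation cohort's
    sample-level stream is seeded from ``validation.seed``).  The two
    specs must agree on every gene-panel field.
    """
    for f in ("n_genes", "n_signal_genes", "sepsis_gene_fraction", "n_decoy_genes",
              "n_offplatform_genes", "baseline_mean", "baseline_sd", "signal_direction"):
        if getattr(derivation, f) != getattr(validation, f):
            raise ParameterError(f"matched cohorts must share {f}")
    rng = np.random.default_rng(derivation.seed)
    panel = _draw_panel(derivation, rng)
    der = _draw_samples(derivation, panel, rng, sample_prefix="D")
    rng_val = np.random.default_rng([0 if validation.seed is None else validation.seed, 1])
    val = _draw_samples(validation, panel, rng_val, sample_prefix="V")
    return der, val


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write expression TSV, clinical CSV, gene-list text and truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "clinical": directory / "clinical.csv",
        "sepsis_genes": directory / "sepsis_genes.txt",
        "truth": directory / "truth.json",
    }
    write_expression(cohort.expression, paths["expression"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_gene_list(cohort.sepsis_gene_list, paths["sepsis_genes"])
    spec_echo = dataclasses.asdict(cohort.spec)
    spec_echo["clinical_spec"] = [dataclasses.asdict(a) for a in cohort.spec.clinical_spec]
    truth = {
        "labels": cohort.truth_labels.tolist(),
        "sample_ids": cohort.expression.sample_ids,
        "signal_genes": cohort.truth_signal_genes,
        "spec": spec_echo,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
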