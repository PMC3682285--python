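# Methods

## Model and scope

The package treats a cohort of critically ill septic patients as a
mixture of latent molecular subtypes observable through a normalized
log₂ expression matrix (genes × patients). All inputs are assumed
normalized; background correction, probe summarization and normalization
are out of scope. The discovery pipeline assumes exactly two subtypes in
its refinement stage (the SAM contrast is two-class); the cluster-number
vote is the guard — if the cohort's silhouette profile does not support
k = 2, discovery stops with an explicit error rather than forcing a
two-group contrast.

## Preprocessing

Samples whose missing fraction strictly exceeds 0.80 are removed (a
sample at exactly 80% is kept). Remaining missing entries are imputed
with the gene's median over observed samples: deterministic, monotone,
and median-preserving. Whether the original analyses imputed or used
pairwise-complete distances is not documented anywhere we know of; the
median choice is ours, and distance computation refuses matrices with
missing values so the decision is always explicit. Candidate gene lists
are intersected with the platform, silently dropping absent symbols
(counts reported) and deduplicating by first occurrence.

## Clustering primitives

PAM is the classic Kaufman–Rousseeuw BUILD + SWAP k-medoids on a
precomputed distance matrix. BUILD seeds greedily (first medoid
minimizes total distance, each next maximizes cost reduction); SWAP
applies the best strictly cost-decreasing (medoid, non-medoid) exchange
until none exists. Every tie (BUILD gains, SWAP deltas, nearest-medoid
assignment) breaks by lowest index, so results are deterministic without
randomness; the `seed` argument exists only for interface stability.
SWAP guarantees a 1-swap local optimum, not the global one: on tiny
unstructured instances it can land in the same non-global local optima
as the reference R implementation (we verified identical behavior on
such instances, with our BUILD never worse). On instances with genuine
group structure — the regime the pipeline operates in — it recovers the
exhaustive-search optimum.

Hierarchical clustering is Ward agglomeration (scipy's Lance–Williams
update) on a condensed distance matrix, cut to k clusters and relabeled
1..k by first appearance. Minkowski distance defaults to exponent p = 3
where the intent is a metric genuinely different from Euclidean; p is a
configuration knob.

Silhouette widths follow the standard definition with two pinned
conventions: singleton clusters score 0, and a(i) = b(i) = 0 (exact
duplicates) scores 0.

## Cluster-number vote and gene enrichment

`select_k` draws ⌊G/3⌋ genes without replacement per repetition,
clusters at each k in 2..10, records the argmax-silhouette k (ties to
the smaller k), and returns the modal k over repetitions (ties to the
smaller). `enrich_genes` nests an inner loop (default 100 candidate
thirds, PAM at the chosen k) inside an outer loop (default 100): each
outer round's silhouette-winning third credits its member genes +1, and
the top 100 genes by count (ties lexicographic) form the enriched
subset. The 100 × 100 nesting is one reading of an ambiguous prose
recipe; both counts are knobs, so the flat reading (outer=100, inner=1)
is also runnable.

## SAM

The two-class unpaired statistic is d = (x̄₂ − x̄₁)/(s + s₀) with s the
pooled standard error. s₀ is chosen by the coefficient-of-variation
rule: over the percentile grid {0, 5, …, 100} of s, pick the candidate
minimizing the CV across s-ordered gene windows of the scaled MAD of d.
The null uses all distinct label assignments when there are at most
`n_permutations` of them, otherwise uniformly random permutations. The
q-value at each gene's own |d| threshold is π̂₀ × (median false calls
over permutations) / (observed calls), capped at 1 and made monotone
non-decreasing as |d| decreases; π̂₀ = min(1, 2·mean(|d| ≤ median null
|d|)), with a flag to force π̂₀ = 1. "q = 0" therefore means the median
permutation produced no statistic as extreme — with finite permutations
q is granular and 0 is its exact bottom step. Positive d means higher
expression in the second (larger-coded) class.

## Bimodality index

BI = √(π(1−π))·|μ₁−μ₂|/σ from a two-component, common-variance Gaussian
mixture. The fit is EM (scikit-learn, tied covariance, 10 restarts,
tolerance 1e-8, up to 500 iterations) on standardized data, which makes
BI exactly invariant to affine transforms; means are mapped back to the
input scale. Zero-variance input returns BI = 0, unconverged. BI > 1.1
is used as the "visually bimodal" threshold throughout. A caution on
estimation: at separation δ ≈ 1 the mixture is weakly identified and the
BI estimate carries tens of percent of sampling error even at n = 5000;
from δ ≈ 2 the estimate is accurate to a few percent at that n.

## Bootstrap stability and PCA

Bootstrap stability draws patients with replacement (default 200
resamples), re-clusters the unique drawn patients (hierarchical,
Euclidean + Ward — Euclidean deliberately, while the main verification
clustering uses Minkowski; each is used where it belongs), and reports
per-pair co-clustering proportions over the resamples in which both
patients appear. Resamples with ≤ k unique patients are skipped and
logged. PCA treats patients as observations with gene-wise centering and
no scaling; the PC1 sign is fixed by making the largest-|loading| gene
load positively.

## Signature extraction and transfer

"Differentially co-expressed" is operationalized as: cluster genes
hierarchically on correlation distance (1 − r, Ward; correlation is the
standard gene-side metric — the patient-side metrics do not transfer
naturally to genes), cut the tree into every module count in 2..10, and
score each module by the mean standardized between-subtype difference
(|Δmean|/pooled SD) of its members. The best-scoring module is the
cohort's co-expressed list if it clears the contrast floor (default 1.0
SD); near-ties prefer the larger module. The signature is the
order-stable intersection of the derivation and validation lists.
Classification of a new cohort is nearest-derivation-medoid on the
signature genes (Euclidean; ties to the lower subtype, a probability-zero
event on continuous data).

## Clinical and gene-set statistics

Binary attributes: two-sided Fisher's exact test with per-subtype
percentages; one-level attributes get p = 1 with a note. Continuous:
pooled-variance Student's t (Welch by flag) with per-subtype means.
Fold changes are 2^(mean log₂ subtype 1 − mean log₂ subtype 2), so
swapping labels maps each fold change to its reciprocal; SAM q-values
are attached when available. Over-representation is the upper-tail
hypergeometric test with population = user-supplied universe (default:
the platform), Bonferroni-corrected over the number of sets tested.

## Synthetic cohorts

The generator emulates a two-subtype microarray cohort: per-gene
baselines ~ N(8, 1) log₂ units; signal genes shift by δ × within-SD in
subtype 2 (default δ = 3, within-SD = 1); noise genes are a single
Gaussian; entries go missing at random (default 1% derivation, 5%
suggested for validation-style cohorts — the asymmetry mirrors the
higher missingness such repeat studies show); optional samples are
forced above the 80% filter threshold (85% of entries masked). Defaults
mirror the study scale: 55 patients, 365 candidate genes, 37 signal
genes, subtype proportion 0.4. The curated candidate list takes 80% of
the signal genes plus an equal number of noise-gene decoys (both
fractions are knobs, as is an off-platform count for exercising the
platform intersection). Signal genes shift coherently by default — a
co-expressed, jointly regulated module, which is what the co-expression
signature machinery looks for — with a "mixed" mode drawing random
directions per gene for pharmacogene-style tables. Clinical attributes
are drawn per subtype (binary: Bernoulli; continuous: Gaussian with a
common SD, since only per-subtype means are typically reported); the
default attribute set includes severe sepsis at prevalences 0.36 / 0.09.
`generate_cohort_pair` shares one gene panel (identities, baselines,
directions, candidate list) between matched derivation/validation
cohorts while drawing samples independently.

What the generator does **not** emulate: probe-level effects, batch and
dye effects, gene–gene correlation beyond the subtype-driven kind,
heavy-tailed noise, and informative missingness (missingness is MCAR
except the forced high-missing samples, since only a count threshold is
documented, not a mechanism). Passing tests on these cohorts therefore
demonstrate algorithmic correctness and statistical calibration under
the stated mixture model, not robustness to real microarray artifacts.

## Test profile and problem sizes

The test suite and examples run the resampling procedures at reduced
repetition counts (cluster-number vote 10–50 repetitions, enrichment
10×10 to 25×25, SAM 50–200 permutations) and cohorts of 40–71 patients
with 100–365 genes; these sizes are the package's chosen desk-scale
defaults for its own verification and are knobs on every public entry
point. The acceptance script runs the cluster-number vote at 50
repetitions on the 55 × 365 default cohort.

## Known limitations

* The final-stage silhouette is computed on genes selected *because*
  they separate the labels, so it is inflated by selection: on pure-noise
  cohorts where the k-vote happens to pass, the final average silhouette
  can reach ≈ 0.35. Silhouette alone is therefore not a null guard; the
  verification layer is. On null cohorts the bootstrap co-clustering gap
  collapses (within ≈ between) and BI(PC1) stays far below 1.1, while
  genuine two-subtype cohorts show near-1/near-0 bootstrap structure and
  BI(PC1) an order of magnitude above the threshold.
* Discovery requires the voted k to be 2; cohorts supporting three or
  more subtypes need a different refinement contrast than two-class SAM.
* Per-gene BI estimates at small n (≈ 55) are noisy; a fifth or so of
  pure-noise genes can exceed 1.1 by chance at that size, so bimodal
  fractions should be read comparatively (signal vs noise), not as
  calibrated error rates.
* PAM finds 1-swap local optima; determinism is by index-order
  tie-breaking, so permuting sample order can change which of several
  equal-cost solutions is returned.
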