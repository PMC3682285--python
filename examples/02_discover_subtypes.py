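"""Run the three-stage subtype discovery pipeline on a derivation cohort.

Stage A restricts to the curated candidate genes and votes on the cluster
number k over random gene thirds; stage B runs the gene-enrichment
tournament; stage C returns to the complete gene set and lets SAM's q = 0
rule pick the final signature before the last PAM clustering.
"""

import sepsistypes as st

cohort = st.generate_cohort(st.CohortSpec(seed=7, n_decoy_genes=30))
m = st.impute_missing(cohort.expression)

config = st.DiscoveryConfig(n_reps=25, n_outer=25, n_inner=25, top_m=40,
                            sam_permutations=200, seed=3)
result = st.discover(m, cohort.sepsis_gene_list, config)

print(f"cluster-number votes (PAM backend): {result.k_votes['pam']}")
print(f"chosen k = {result.chosen_k}")
for name, rec in result.stages.items():
    print(f"stage {name:9s}: {rec.n_genes:4d} genes, cluster sizes {rec.cluster_sizes}, "
          f"average silhouette {rec.avg_silhouette:.3f}")
# The average silhouette width rises stage by stage as feature selection
# concentrates the subtype contrast — the discovery signature of the method.

agree, ari = st.compare_partitions(
    result.stages["final"].solution.labels, cohort.truth_labels
)
print(f"final labels vs simulated truth: {agree}/{m.n_samples} agree, ARI = {ari:.2f}")
print(f"transferable model: {len(result.model.signature_genes)} signature genes, "
      f"{result.model.k} medoids")
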