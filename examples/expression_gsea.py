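"""Differential expression and gene set enrichment on the expression arm.

Genes are ranked by the signal-to-noise ratio (class-mean difference over
the sum of floored class standard deviations); pathway enrichment scores
are compared against phenotype-swap permutations in which the ranking is
recomputed from scratch.
"""

import pathuniter as pu

config = pu.SyntheticConfig(
    n_case=64, n_control=75, n_genes=100, snps_per_gene=2,
    n_sets=12, genes_per_set=10, seed=7,
)
genome, truth, _, expression = pu.generate_study(config)

de = pu.differential_expression(expression)
n_deg = int((de["fdr"] < 0.05).sum())
print(f"{n_deg} of {len(de)} genes differentially expressed at FDR < 0.05")
print("strongest genes by |signal-to-noise|:")
print(de.reindex(de["snr"].abs().sort_values(ascending=False).index)
        .head(3)[["gene", "log2_ratio", "t", "fdr", "snr"]]
        .round(3).to_string(index=False))

deg_sets = pu.derive_deg_gene_sets(de)
print(f"\nderived DEG sets: "
      f"{ {name: len(genes) for name, genes in deg_sets} }")

sets, _ = pu.filter_gene_sets(genome.sets, set(expression.gene_ids))
res = pu.gsea_expression(expression, sets, pu.PermutationPlan(n_perm=500, seed=3))
top = res.sort_values("p").head(3)[["set", "size", "score", "nes", "p", "fdr"]]
print("\ntop pathways by enrichment (score = ES, the max running-sum "
      "departure):")
print(top.round(4).to_string(index=False))
print(f"planted pathway: {truth.planted_sets[0]}")
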