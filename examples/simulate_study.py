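"""Generate a synthetic case/control study with one planted pathway.

Builds a genome of genes tiled on synthetic chromosomes, draws LD-blocked
genotypes under a logistic disease model, and a matching expression matrix
with a log2 shift in the planted genes, then prints what was planted.
"""

import pathuniter as pu

config = pu.SyntheticConfig(
    n_case=150, n_control=150, n_genes=100, snps_per_gene=4,
    n_sets=12, genes_per_set=10, seed=7,
)
genome, truth, genotypes, expression = pu.generate_study(config)

print(f"genotypes: {genotypes.n_snps} SNPs x {genotypes.n_samples} samples")
print(f"expression: {len(expression.gene_ids)} genes x "
      f"{len(expression.sample_ids)} samples")
print(f"gene sets: {len(genome.sets)} (sizes "
      f"{min(len(g) for _, g in genome.sets)}-"
      f"{max(len(g) for _, g in genome.sets)})")
print(f"planted pathway: {truth.planted_sets[0]} with "
      f"{len(truth.effect_genes)} effect genes, "
      f"{len(truth.causal_snps)} causal SNPs")
print("each effect gene carries one causal SNP (log odds ratio "
      f"{config.allelic_log_or} per minor allele) and a "
      f"+{config.expr_delta_log2} log2 expression shift in cases")
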