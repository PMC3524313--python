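import numpy as np
import pytest
from hypothesis import settings

import pathuniter as pu
from pathuniter import assoc_qc

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_study():
    """A small planted-effect synthetic study shared across tests.

    100/100 samples, 60 genes x 3 SNPs, 10 sets of 8 genes, one planted
    pathway (SET_000).  The allelic effect is set high so the planted
    signal is unambiguous at this reduced scale; power at the default
    effect sizes is measured separately at full scale.
    """
    cfg = pu.SyntheticConfig(
        n_case=100, n_control=100, n_genes=60, snps_per_gene=3,
        n_sets=10, genes_per_set=8, allelic_log_or=0.7, seed=1,
    )
    genome, truth, geno, expr = pu.generate_study(cfg)
    assoc = assoc_qc.assoc_table(geno)
    snp_map = pu.map_snps_to_genes(assoc[["snp", "chr", "pos"]], genome.genes)
    gene_stats = pu.gene_statistics(assoc, snp_map)
    sets, _ = pu.filter_gene_sets(genome.sets, set(gene_stats.table["gene"]))
    return {
        "config": cfg, "genome": genome, "truth": truth,
        "genotypes": geno, "expression": expr, "assoc": assoc,
        "snp_map": snp_map, "gene_stats": gene_stats, "sets": sets,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
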