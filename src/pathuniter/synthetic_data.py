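"""Synthetic genotype and expression studies with planted pathway effects.

The generator lays out genes on synthetic chromosomes with 50 kb spacing
(so the default 20 kb flank assigns every SNP to exactly one gene), draws
LD blocks within each gene from a latent-Gaussian threshold model with one
exchangeable correlation, assigns a binary phenotype from a logistic
disease model whose causal SNPs sit only in planted-pathway genes, and
writes a matching expression study in which the same planted genes carry a
log2 mean shift in cases.  Every stage of the pipeline is thereby testable
with a known ground truth and no external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit

from pathuniter.formats_io import ExpressionStudy, GeneSetCollection, GenotypeStudy

GENE_SPACING_BP = 50_000
GENE_LENGTH_BP = 10_000
GENES_PER_CHROM = 100


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design knobs for the synthetic generator.

    Defaults describe a balanced 300/300 case/control study over 300 genes
    (5 SNPs each, within-gene dosage correlation 0.6, MAF uniform on
    0.1-0.5), 50 gene sets of 20 genes, and one planted pathway in which
    half the genes carry a per-allele log odds ratio of 0.35 and a +1.0
    log2 expression shift in cases with sigma = 0.5 residual noise.
    """

    n_case: int = 300
    n_control: int = 300
    n_genes: int = 300
    snps_per_gene: int = 5
    ld_block_rho: float = 0.6
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_sets: int = 50
    genes_per_set: int = 20
    planted_sets: tuple[str, ...] = ("SET_000",)
    planted_fraction: float = 0.5
    allelic_log_or: float = 0.35
    expr_delta_log2: float = 1.0
    expr_sigma: float = 0.5
    expr_baseline_mean: float = 8.0
    expr_baseline_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_case, self.n_control, self.n_genes,
               self.snps_per_gene, self.n_sets, self.genes_per_set) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.ld_block_rho < 1.0:
            raise ValueError("ld_block_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be a subset of (0, 0.5]")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must lie in [0, 1]")
        if self.genes_per_set > self.n_genes:
            raise ValueError("genes_per_set cannot exceed n_genes")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of a synthetic study: what was planted where."""

    planted_sets: tuple[str, ...]
    effect_genes: tuple[str, ...]
    causal_snps: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "planted_sets": list(self.planted_sets),
            "effect_genes": list(self.effect_genes),
            "causal_snps": list(self.causal_snps),
        }


@dataclass
class SyntheticGenome:
    """Gene models, SNP positions/MAFs, gene sets, and SNP bookkeeping."""

    genes: pd.DataFrame          # gene, chrom, start, end (1-based inclusive)
    snps: pd.DataFrame           # snp, chr, pos, maf, gene
    sets: GeneSetCollection
    gene_of_snp: np.ndarray = field(repr=False)  # gene row index per SNP


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stream])


def generate_genome(config: SyntheticConfig) -> tuple[SyntheticGenome, TruthRecord]:
    """Lay out genes, SNPs, and gene sets; decide the planted truth.

    Genes are tiled every 50 kb (100 per synthetic chromosome) so each SNP
    falls within the 20 kb flank of exactly one gene.  Each set draws its
    genes without replacement; planted sets flag ``planted_fraction`` of
    their genes as effect genes, each carrying one causal SNP (the gene's
    first).  Set sizes always pass the default 5-250 size filter because
    ``genes_per_set`` is validated against it upstream in the pipeline.
    """
    rng = _rng(config, 1)
    gene_rows = []
    for i in range(config.n_genes):
        chrom = str(i // GENES_PER_CHROM + 1)
        local = i % GENES_PER_CHROM
        start = local * GENE_SPACING_BP + 1
        gene_rows.append((f"GENE_{i:04d}", chrom, start, start + GENE_LENGTH_BP - 1))
    genes = pd.DataFrame(gene_rows, columns=["gene", "chrom", "start", "end"])

    snp_rows = []
    gene_of_snp = []
    step = GENE_LENGTH_BP // (config.snps_per_gene + 1)
    for i, g in enumerate(genes.itertuples(index=False)):
        for j in range(config.snps_per_gene):
            pos = g.start + (j + 1) * step
            maf = float(rng.uniform(*config.maf_range))
            snp_rows.append((f"rs{i:04d}_{j}", g.chrom, pos, maf, g.gene))
            gene_of_snp.append(i)
    snps = pd.DataFrame(snp_rows, columns=["snp", "chr", "pos", "maf", "gene"])

    gene_names = genes["gene"].to_numpy()
    sets: dict[str, tuple[str, ...]] = {}
    for s in range(config.n_sets):
        members = rng.choice(config.n_genes, size=config.genes_per_set, replace=False)
        sets[f"SET_{s:03d}"] = tuple(gene_names[sorted(members)])
    collection = GeneSetCollection(
        sets, provenance={k: "synthetic gene set" for k in sets}
    )

    unknown = set(config.planted_sets) - set(sets)
    if unknown:
        raise ValueError(f"planted sets not generated: {sorted(unknown)}")
    effect_genes: list[str] = []
    for name in config.planted_sets:
        members = list(sets[name])
        k = math.ceil(config.planted_fraction * len(members))
        picked = rng.choice(len(members), size=k, replace=False)
        effect_genes.extend(members[i] for i in sorted(picked))
    effect_genes = sorted(set(effect_genes))
    first_snp = snps.drop_duplicates("gene").set_index("gene")["snp"]
    causal_snps = tuple(first_snp[g] for g in effect_genes)
    truth = TruthRecord(
        planted_sets=tuple(config.planted_sets),
        effect_genes=tuple(effect_genes),
        causal_snps=causal_snps,
    )
    genome = SyntheticGenome(
        genes=genes, snps=snps, sets=collection,
        gene_of_snp=np.array(gene_of_snp, dtype=np.intp),
    )
    return genome, truth


def _draw_dosage(
    genome: SyntheticGenome, config: SyntheticConfig,
    n_samples: int, rng: np.random.Generator,
) -> np.ndarray:
    """Dosages from the latent-Gaussian threshold model, (n_snps, n)."""
    n_snps = len(genome.snps)
    thresh = stats.norm.ppf(genome.snps["maf"].to_numpy())
    rho = config.ld_block_rho
    dosage = np.zeros((n_snps, n_samples))
    for _hap in range(2):
        u = rng.standard_normal((config.n_genes, n_samples))
        e = rng.standard_normal((n_snps, n_samples))
        z = math.sqrt(rho) * u[genome.gene_of_snp] + math.sqrt(1 - rho) * e
        dosage += z < thresh[:, None]
    return dosage


def generate_genotypes(
    config: SyntheticConfig,
    genome: SyntheticGenome,
    truth: TruthRecord,
    max_batches: int = 200,
) -> GenotypeStudy:
    """Case/control genotypes under a logistic disease model.

    Each causal SNP contributes ``allelic_log_or`` per minor allele to the
    logit of disease risk; the intercept is solved so the expected case
    fraction matches n_case / (n_case + n_control).  Individuals are
    simulated and labeled in batches until both class quotas are filled
    exactly (cases first in the output ordering); exceeding
    ``max_batches`` raises, which only happens for extreme effect sizes.
    """
    rng = _rng(config, 2)
    n_total = config.n_case + config.n_control
    target = config.n_case / n_total
    causal_idx = genome.snps.set_index("snp").index.get_indexer(truth.causal_snps)
    if len(causal_idx) and causal_idx.min() < 0:
        raise ValueError("causal SNP absent from genome")
    beta = config.allelic_log_or

    case_cols: list[np.ndarray] = []
    ctrl_cols: list[np.ndarray] = []
    alpha: float | None = None
    for _ in range(max_batches):
        batch = _draw_dosage(genome, config, n_total, rng)
        eta = beta * batch[causal_idx].sum(axis=0) if len(causal_idx) else np.zeros(n_total)
        if alpha is None:
            alpha = float(brentq(lambda a: expit(a + eta).mean() - target, -30, 30))
        is_case = rng.random(n_total) < expit(alpha + eta)
        for col, flag in zip(batch.T, is_case):
            if flag and len(case_cols) < config.n_case:
                case_cols.append(col)
            elif not flag and len(ctrl_cols) < config.n_control:
                ctrl_cols.append(col)
        if len(case_cols) == config.n_case and len(ctrl_cols) == config.n_control:
            break
    else:
        raise RuntimeError(
            "could not reach the requested case/control counts; "
            "the effect sizes make one class too rare"
        )

    dosage = np.column_stack(case_cols + ctrl_cols)
    phenotype = np.array(
        ["case"] * config.n_case + ["control"] * config.n_control, dtype=object
    )
    sample_ids = [f"S{i:04d}" for i in range(n_total)]
    return GenotypeStudy(
        snp_ids=list(genome.snps["snp"]),
        chrom=genome.snps["chr"].to_numpy(dtype=object),
        pos=genome.snps["pos"].to_numpy(dtype=np.int64),
        dosage=dosage,
        sample_ids=sample_ids,
        phenotype=phenotype,
    )


def generate_expression(
    config: SyntheticConfig,
    genome: SyntheticGenome,
    truth: TruthRecord,
) -> ExpressionStudy:
    """Gene-by-sample log2 expression with planted case shifts.

    value = gene baseline N(expr_baseline_mean, expr_baseline_sigma^2)
    + expr_delta_log2 for effect genes in case samples
    + N(0, expr_sigma^2) noise.  Samples are ordered cases first, matching
    the genotype study generated from the same config, so the two arms
    share their class structure under a common seed.
    """
    rng = _rng(config, 3)
    n_total = config.n_case + config.n_control
    gene_ids = list(genome.genes["gene"])
    baseline = config.expr_baseline_mean + config.expr_baseline_sigma * \
        rng.standard_normal(len(gene_ids))
    values = baseline[:, None] + config.expr_sigma * \
        rng.standard_normal((len(gene_ids), n_total))
    effect = np.isin(np.array(gene_ids, dtype=object), truth.effect_genes)
    values[np.ix_(effect, np.arange(config.n_case))] += config.expr_delta_log2
    phenotype = np.array(
        ["case"] * config.n_case + ["control"] * config.n_control, dtype=object
    )
    sample_ids = [f"S{i:04d}" for i in range(n_total)]
    return ExpressionStudy(
        gene_ids=gene_ids, values=values,
        sample_ids=sample_ids, phenotype=phenotype,
    )


def generate_study(
    config: SyntheticConfig,
) -> tuple[SyntheticGenome, TruthRecord, GenotypeStudy, ExpressionStudy]:
    """Convenience: genome + truth + genotype study + expression study."""
    genome, truth = generate_genome(config)
    genotypes = generate_genotypes(config, genome, truth)
    expression = generate_expression(config, genome, truth)
    return genome, truth, genotypes, expression
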