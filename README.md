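# pathuniter

Integrative pathway analysis for case/control studies that have both a
genome-wide association (GWAS) arm and a gene-expression arm.  Single-SNP
and single-gene tests are underpowered for common diseases whose risk is
spread across many small effects; gene-set (pathway) tests aggregate that
signal, and agreement between two independent genomic platforms is much
stronger evidence than either alone.  `pathuniter` is aimed at
statistical-genetics analysts who want the full workflow — QC, per-SNP
association, SNP-to-gene mapping, four complementary pathway tests,
expression GSEA, and cross-platform combination — as a tested, seeded,
reproducible library.

## What it computes

**GWAS arm.** After QC (call rate < 90 %, MAF < 0.05, monomorphic SNPs,
samples with > 10 % missingness) every SNP gets the basic allelic test:
the 1-df Pearson chi-square on the 2×2 table of minor/major allele counts
in cases vs controls (2N alleles per class), with the genomic inflation
factor λ = median(χ²)/0.4549 reported descriptively.  SNPs map to genes
within the gene body ± 20 kb, and each gene is represented by its
maximum-χ² SNP.  Four pathway tests then score every gene set S:

* **GSEA** (competitive): genes are ranked by gene-wise χ²; the
  enrichment score ES(S) is the maximum departure of a weighted
  Kolmogorov–Smirnov running sum (hits weighted by |χ²|ʷ, w = 1); the
  null swaps case/control labels and recomputes everything.
  NES = ES / mean(same-sign permuted ES).
* **ALIGATOR** (competitive): counts genes in S containing ≥ 1 SNP with
  P < 0.05 (each gene once); the null resamples SNPs without replacement
  until the genome-wide significant-gene count matches the observed one.
* **SNP ratio test, SRT** (self-contained): the fraction of S's SNPs
  with P < 0.05, against label permutations.
* **Set-based test** (self-contained): greedily pick the best SNP with
  P < 0.05, prune SNPs with dosage r² > 0.5 to it, repeat up to 5 picks;
  the score is the mean χ² of the picks, against label permutations.

Empirical P-values use the (1+b)/(B+1) convention, so they are never zero.

**Expression arm.** Quantile normalization, optional probe collapsing by
median, Welch t differential expression with Benjamini–Hochberg FDR, and
the same GSEA machinery with genes ranked by the signal-to-noise ratio
(μ_case − μ_control)/(σ_case + σ_control), each σ floored at 0.2·|μ|.

**Combination.** For every pathway eligible on both platforms, Fisher's
method: χ² = −2(ln p_GWAS + ln p_expr) on 2k = 4 degrees of freedom,
BH FDR over the common pathways, and two significance tiers (nominal
P < 0.01; FDR < 0.2), plus Venn-style overlap summaries across methods.

A synthetic-data module generates genotype and expression studies with a
known planted pathway (LD blocks from a latent-Gaussian model, logistic
disease risk, log2 expression shifts) so every stage is testable without
controlled-access data.

## Worked example

`examples/combine_evidence.py` simulates a 300/300 case/control study
(100 genes, 12 pathways of 10 genes, one planted pathway with five causal
SNPs at log-OR 0.35 and a +1 log2 expression shift), runs the set-based
test and expression GSEA at 500 permutations, and combines them:

```
12 pathways eligible on both platforms
    set  p_gwas  p_expr    chi2  p_combined    fdr  tier1  tier2
SET_000   0.004  0.0037 22.2363      0.0002 0.0011   True   True
SET_004   0.004  0.0042 22.0082      0.0002 0.0011   True   True
SET_009   0.006  0.0041 21.2221      0.0003 0.0011   True   True
SET_002   0.022  0.0039 18.7356      0.0009 0.0022   True   True

planted pathway: SET_000 (rank 1 by combined P)
```

`p_gwas` and `p_expr` are the per-platform empirical permutation
P-values; `chi2` is the Fisher statistic on 4 df and `p_combined` its
upper-tail probability; `fdr` is BH over the 12 common pathways; the tier
flags mark nominal P < 0.01 and FDR < 0.2.  The planted pathway tops the
combined ranking; runner-up sets share some of its effect genes by
construction of the random set draw.  The other examples cover the
simulator, the four GWAS tests, the expression arm, and the one-call
pipeline (`run_pipeline` / `pathuniter run --config pipeline.yaml`).

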