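# Methods

## Single-SNP association and QC

The allelic test compares minor-allele counts between cases and controls
in a 2×2 table with 2N alleles per class, using the Pearson chi-square
without continuity correction (1 df).  Missing calls are excluded from
the table, never imputed; a zero marginal (an allele absent overall)
yields χ² = 0, P = 1, flagged degenerate.  QC thresholds are strict
inequalities — call rate < 0.90, MAF < 0.05, sample missingness > 0.10 —
so boundary values survive.  Samples are filtered before SNPs, and call
rate and MAF are recomputed on the retained samples; the QC report
emitted with every run records the counts dropped by each rule.  The genomic
inflation factor λ = median(χ²)/F⁻¹(0.5; χ²₁) uses the exact 1-df median
(≈ 0.45494) and is reported descriptively only; no statistic is rescaled
by it.

## SNP-to-gene mapping and gene statistics

A SNP belongs to a gene when its position lies within the gene body
± `flank_bp` (default 20 000 bp), inclusive at the boundary; a SNP under
two overlapping genes counts for both, since dropping it would silently
shrink pathways.  Strand is ignored.  The gene-wise statistic is the
maximum χ² over the gene's SNPs (the representative SNP); ties break to
the smaller position, then the SNP id, and are logged.  Gene sets are
filtered to an effective size of 5–250 genes inclusive, where effective
size is measured after intersecting the set with the platform's
scoreable-gene universe — the competitive tests are only well-posed on
genes that can actually be scored.

## The four GWAS pathway tests

All label-permutation tests share one engine: the case/control vector is
permuted B times (default 1000), the allelic test is recomputed for every
SNP under every permutation in one vectorized pass, and each method's
statistic is rebuilt from scratch on top — gene statistics and ranking
for GSEA, significance indicators for SRT, greedy LD-pruned selection for
the set-based test.  Empirical P-values use (1+b)/(B+1), where b counts
permutations that beat or tie the observed statistic; P is therefore
never zero and downstream Fisher combination stays finite.

**GSEA.**  The enrichment score walks the genome-wide descending ranking;
member genes add |stat|ʷ normalized by the member total, non-members
subtract 1/(N − N_hit); the ES is the running-sum value of maximum
absolute departure, signed.  The weight exponent defaults to 1; 0 gives
the classic unweighted KS walk.  If every member statistic is zero the
hit weights fall back to equal, keeping the walk defined.  NES divides
the ES by the mean permuted ES of the same sign.  The empirical P is
computed within the same-sign permutation class: a positive ES is
compared only against non-negative permuted ES (and mirrored for
negative).  Comparing one-sided scores against the pooled two-sided null
would concentrate null P-values below 0.5 (a mixture of U(0, q) and
U(0, 1−q) where q is the positive-sign share) — a real miscalibration we
measured before adopting the same-sign convention, which restores
uniformity for sign-symmetric rankings such as the expression
signal-to-noise.  The default FDR is the pooled permutation-NES scheme
(share of pooled permuted NES beyond the threshold over the share of
observed NES beyond it, clipped to [0, 1], computed per sign);
Benjamini–Hochberg on the empirical P is available via `fdr_method="bh"`.

**ALIGATOR.**  A gene is significant when it contains at least one SNP
with P below the cutoff (default 0.05), counted once regardless of how
many.  Each replicate draws SNPs uniformly without replacement from the
full SNP pool until the number of distinct genes hit equals the observed
significant-gene count; a draw that would overshoot the target (one SNP
spanning several new genes) is discarded and drawing continues.  When
every SNP maps to at most one gene the replicate reduces to a vectorized
first-occurrence scan.  The default is 10 000 replicates, reflecting that
the resampling unit is the SNP.

**SRT.**  The observed ratio is (#SNPs in the pathway with P < cutoff) /
(#SNPs in the pathway); a SNP shared between two member genes is counted
once per pathway.  The ratio is recomputed under each label permutation
via a fixed χ² threshold equivalent to the P cutoff.

**Set-based test.**  Greedy selection: take the smallest-P remaining SNP
with P < 0.05 (ties to the earlier SNP in set order), remove every
remaining SNP whose dosage r² with it exceeds 0.5, stop at five picks or
when nothing is eligible; the score is the mean χ² of the picks, zero for
an empty selection.  r² is the squared Pearson correlation of dosage
vectors over pairwise-complete samples (composite LD — no phasing is
assumed anywhere); an undefined correlation is treated as 0 so a
degenerate pair is never pruned on unknowable grounds.  The r² matrix
depends only on genotypes and is computed once per set; the selection is
re-run from scratch under every permutation.

## Expression arm

Quantile normalization maps every sample onto the distribution of
row-wise mean order statistics, ties averaged (fractional ranks
interpolate between order statistics); it is idempotent and
rank-preserving.  Probes collapse to genes by element-wise median.
Differential expression uses Welch's unequal-variance t-test (safer than
the pooled test for unequal class sizes) with BH FDR; the log2 ratio is
the class-mean difference, assuming log2-scale input.  The GSEA ranking
statistic is the signal-to-noise ratio
(μ_case − μ_control)/(σ_case + σ_control) with each class σ floored at
max(σ, 0.2·|μ|, 10⁻⁸); the relative floor follows the classic GSEA
implementation and the tiny absolute term only guards the all-zero gene.
Enrichment, NES, empirical P and FDR share the GWAS code path, with the
statistic recomputed under every label permutation.

## Fisher combination and tiers

χ² = −2 Σ ln pᵢ with 2k df (k = 2 platforms).  Inputs must be positive;
the empirical-P convention guarantees that upstream, and a zero P raises
with instructions to clamp at 1/(B+1).  Combination is restricted to
pathways present in both platforms' filtered collections ("eligible on
both"); BH FDR is computed over that intersection.  Tier 1 is nominal
P < 0.01 and tier 2 is FDR < 0.2, both strict.  Method-comparison
overlaps count every region of the Venn partition over the union of
tier-1 and tier-2 pathways per method, for up to four methods.

## Synthetic data

The generator emulates the structure the pipeline needs, not human
genetics in full.  Genes are tiled every 50 kb (100 per chromosome,
10 kb bodies) so the default 20 kb flank assigns every SNP to exactly one
gene; per-gene SNPs (default 5, MAF ~ U(0.1, 0.5)) come from a
latent-Gaussian threshold model with exchangeable correlation
`ld_block_rho` (default 0.6) per haplotype, giving within-gene LD and
independence between genes — enough to exercise r² pruning, with no
recombination map, population structure, or genotyping error.  Disease
status follows a logistic model: each causal SNP adds `allelic_log_or`
(default 0.35) per minor allele to the logit; the intercept is solved
numerically so the expected case fraction matches the requested design,
and sampling proceeds in batches until the exact case/control counts
(default 300/300) are reached.  Gene sets (default 50 sets of 20) are
drawn uniformly without replacement within each set; the planted set
flags half its genes (`planted_fraction` 0.5) as effect genes, each
carrying one causal SNP — the realistic single-causal-variant-per-locus
regime, which means per-gene detectability varies strongly with the
drawn MAF.  Because non-planted sets are drawn from the full gene pool,
they can share effect genes with the planted set; partially contaminated
competitors are therefore expected, and "the planted set wins" is only a
soft property at small permutation counts.  Expression values are gene
baseline N(8, 1) plus `expr_delta_log2` (default 1.0) for effect genes in
cases plus N(0, 0.5²) noise; samples are ordered cases-first in both arms
so the class structure is aligned under a shared seed.  All randomness
flows through seeded NumPy generators with fixed integer seed streams;
identical seeds give byte-identical outputs.

What passing tests on this generator do show: the permutation machinery
is exchangeable-correct, the statistics match their definitions, planted
multi-gene signals of realistic size are recovered, and the whole
workflow is deterministic.  What they do not show: behavior under
cryptic relatedness, long-range LD, array batch effects, or any property
of real annotation databases.

## Calibration measurement

Two measurement details matter when checking null uniformity.  First,
self-contained tests scored on one study share that study's global chance
signal, so P-values across sets are strongly positively correlated; a KS
test that assumes independent draws will reject even for a perfectly
calibrated test.  Calibration is therefore assessed on sets pooled from
independent replicate null studies.  Second, count-based statistics (the
SRT ratio, the set-based zero-selection mass, allele-count tables) are
discrete, so the reported conservative P cannot be exactly uniform; the
calibration diagnostic uses tie-randomized P-values,
(#{perm > obs} + U·(1 + #{perm = obs}))/(B + 1), which are exactly
U(0, 1) under exchangeability for any statistic.  Reported P-values are
never randomized — they keep the conservative convention.  The
permutation score matrices needed for this diagnostic ride along on each
result table as `DataFrame.attrs`.

## Problem sizes and defaults

Permutation defaults are 1000 label swaps (10 000 SNP resamples for
ALIGATOR); the acceptance script uses 200 permutations per study, 20
replicate null studies for calibration, and 25 replicate studies for
recovery — sizes chosen to give stable rates while keeping a full run in
the minutes range on one CPU.  Known limitations: ALIGATOR's recovery of
the planted pathway hovers near 75–90 % at the default effect sizes
(it counts genes once and ignores effect magnitude, and only about half
the causal SNPs are individually significant at these MAFs — consistent
with its weak showing in published comparisons); and at small permutation
counts several contaminated sets can saturate the 1/(B+1) floor in both
platforms, making the combined top rank partly a coin flip among them.
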