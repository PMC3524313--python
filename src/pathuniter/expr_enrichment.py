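"""Expression preprocessing and gene set enrichment on the expression arm.

Preprocessing: quantile normalization of samples, probe-to-gene collapsing
by element-wise median, and per-gene differential expression (Welch t-test
with Benjamini-Hochberg FDR).  Enrichment: the same weighted-KS GSEA used
on the GWAS arm, with genes ranked by the signal-to-noise ratio
(class-mean difference over the sum of floored class standard deviations)
and a phenotype-swap null in which the ranking statistic is recomputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from pathuniter.formats_io import ExpressionStudy, GeneSetCollection
from pathuniter.gwas_enrichment import (
    PermutationPlan,
    _gsea_from_stat_matrix,
    _permuted_case_matrix,
)

logger = logging.getLogger(__name__)

#: relative floor on each class standard deviation in the signal-to-noise
#: ratio, sigma >= SNR_SIGMA_FLOOR * |mu| (the floor used by the classic
#: GSEA implementation); a tiny absolute floor guards the all-zero gene.
SNR_SIGMA_FLOOR = 0.2
SNR_SIGMA_EPS = 1e-8


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Force every sample (column) onto the mean-order-statistic distribution.

    Each column is replaced by the across-column mean of sorted values,
    assigned by within-column rank with ties averaged.  Idempotent and
    rank-preserving within columns.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.all(col == col[0]):
            logger.warning("sample column %d is constant; set to mean quantile", j)
            out[:, j] = ref.mean()
            continue
        ranks = stats.rankdata(col, method="average")  # 1..n, ties averaged
        # interpolate between order statistics for fractional (tied) ranks
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), ref)
    return out


def collapse_probes(
    values: np.ndarray,
    probe_ids: list[str],
    probe_to_gene: dict[str, str],
) -> tuple[np.ndarray, list[str]]:
    """Collapse a probe-by-sample matrix to gene rows by element-wise median.

    Probes missing from the mapping are dropped with a warning; genes keep
    the order of first appearance among mapped probes.
    """
    groups: dict[str, list[int]] = {}
    dropped = 0
    for i, probe in enumerate(probe_ids):
        gene = probe_to_gene.get(probe)
        if gene is None:
            dropped += 1
            continue
        groups.setdefault(gene, []).append(i)
    if dropped:
        logger.warning("%d unmapped probes dropped during collapsing", dropped)
    if not groups:
        raise ValueError("no probe maps to a gene")
    genes = list(groups)
    out = np.empty((len(genes), values.shape[1]))
    for k, gene in enumerate(genes):
        out[k] = np.median(values[groups[gene]], axis=0)
    return out, genes


def signal_to_noise(
    values: np.ndarray, is_case: np.ndarray
) -> np.ndarray:
    """GSEA signal-to-noise ranking statistic per gene.

    snr = (mu_case - mu_control) / (sigma_case + sigma_control) with each
    class sigma floored at SNR_SIGMA_FLOOR * |mu_class| (plus a tiny
    absolute floor), so a zero-variance class never divides by zero.
    ``is_case`` may be 1-D or a (n_samples, B) matrix of labelings; the
    result is (n_genes,) or (n_genes, B).
    """
    x = np.asarray(values, dtype=float)
    one_d = is_case.ndim == 1
    C = np.atleast_2d(is_case.astype(float).T).T  # (n_samples, B)
    n1 = C.sum(axis=0)
    n0 = C.shape[0] - n1
    s1 = x @ C
    s0 = x.sum(axis=1, keepdims=True) - s1
    mu1 = s1 / n1
    mu0 = s0 / n0
    q1 = (x**2) @ C
    q0 = (x**2).sum(axis=1, keepdims=True) - q1
    var1 = np.maximum(q1 / n1 - mu1**2, 0.0)
    var0 = np.maximum(q0 / n0 - mu0**2, 0.0)
    sd1 = np.maximum(np.sqrt(var1), np.maximum(SNR_SIGMA_FLOOR * np.abs(mu1),
                                               SNR_SIGMA_EPS))
    sd0 = np.maximum(np.sqrt(var0), np.maximum(SNR_SIGMA_FLOOR * np.abs(mu0),
                                               SNR_SIGMA_EPS))
    snr = (mu1 - mu0) / (sd1 + sd0)
    return snr[:, 0] if one_d else snr


def differential_expression(study: ExpressionStudy) -> pd.DataFrame:
    """Per-gene Welch t-test, BH FDR, log2 ratio, and signal-to-noise ratio.

    Values are assumed to be on the log2 scale, so the class-mean
    difference IS the log2 ratio.  Population (ddof 0) standard deviations
    feed the floored signal-to-noise ratio; the t-test itself uses the
    usual ddof-1 variances.
    """
    from pathuniter.integrate import bh_fdr

    is_case = study.is_case
    if min(is_case.sum(), (~is_case).sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    case = study.values[:, is_case]
    ctrl = study.values[:, ~is_case]
    t_stat, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)
    log2_ratio = case.mean(axis=1) - ctrl.mean(axis=1)
    snr = signal_to_noise(study.values, is_case)
    return pd.DataFrame(
        {
            "gene": study.gene_ids,
            "log2_ratio": log2_ratio,
            "t": t_stat,
            "p": p,
            "fdr": bh_fdr(p),
            "snr": snr,
        }
    )


def gsea_expression(
    study: ExpressionStudy,
    sets: GeneSetCollection,
    plan: PermutationPlan = PermutationPlan(),
    weight_exponent: float = 1.0,
    fdr_method: str = "pooled",
) -> pd.DataFrame:
    """GSEA of gene sets in a two-class expression study.

    Identical to the GWAS-side GSEA except that genes are ranked by the
    signal-to-noise ratio, recomputed under every phenotype-swap
    permutation.  Swapping all class labels flips every snr sign and hence
    every enrichment-score sign.
    """
    is_case = study.is_case
    if min(is_case.sum(), (~is_case).sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    snr_obs = signal_to_noise(study.values, is_case)
    rng = plan.rng()
    perm_labels = _permuted_case_matrix(is_case, plan.n_perm, rng)
    snr_perm = signal_to_noise(study.values, perm_labels)
    stat_matrix = np.column_stack([snr_obs, snr_perm])
    return _gsea_from_stat_matrix(
        stat_matrix, study.gene_ids, sets, weight_exponent, fdr_method
    )
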