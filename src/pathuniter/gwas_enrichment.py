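"""Four permutation-based pathway tests for case/control GWAS data.

Two competitive tests (the set is compared against the rest of the genome):

* ``gsea_gwas`` — weighted Kolmogorov-Smirnov enrichment of a pathway in
  the genome-wide ranking of gene-wise max-chi-square statistics, with a
  phenotype-swap null (GenGen-style GSEA).
* ``aligator`` — over-representation of a pathway among genes containing at
  least one significant SNP, with a SNP-resampling null that matches the
  observed number of significant genes.

Two self-contained tests (the set is tested against "no association"):

* ``snp_ratio_test`` — fraction of a pathway's SNPs that are significant,
  against phenotype-swap permutations.
* ``set_based_test`` — mean chi-square of greedily selected, LD-pruned,
  significant SNPs, against phenotype-swap permutations.

All phenotype-swap tests share one engine: case/control labels are
permuted, the allelic test is recomputed for every SNP under every
permutation, and downstream statistics are rebuilt from scratch.  The
empirical P-value convention is (1 + b) / (B + 1) where b counts
permutation statistics that beat or tie the observed one, so P is never
zero and Fisher combination stays finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pathuniter.assoc_qc import allelic_test_all
from pathuniter.formats_io import GeneSetCollection, GenotypeStudy
from pathuniter.gene_mapping import SnpGeneMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationPlan:
    """How many permutations, which scheme, and the RNG seed.

    Defaults mirror the usual practice: 1000 phenotype swaps for the
    label-permutation tests and 10,000 SNP resamples for ALIGATOR.
    """

    n_perm: int = 1000
    seed: int = 0
    scheme: str = "phenotype-swap"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.scheme not in ("phenotype-swap", "snp-resample"):
            raise ValueError(f"unknown permutation scheme {self.scheme!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


ALIGATOR_DEFAULT_PLAN = PermutationPlan(n_perm=10_000, seed=0, scheme="snp-resample")


def empirical_pvalue(
    observed: float, permuted: np.ndarray, direction: str = "ge"
) -> float:
    """Permutation P-value (1 + #{beats or ties}) / (B + 1)."""
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise ValueError("permuted vector must be non-empty")
    if direction == "ge":
        b = int((permuted >= observed).sum())
    elif direction == "le":
        b = int((permuted <= observed).sum())
    else:
        raise ValueError("direction must be 'ge' or 'le'")
    return (1 + b) / (permuted.size + 1)


# ---------------------------------------------------------------------------
# Enrichment score (weighted KS running sum)
# ---------------------------------------------------------------------------

def enrichment_score(
    ranked_stats: np.ndarray,
    membership: np.ndarray,
    weight_exponent: float = 1.0,
) -> tuple[float, int, np.ndarray]:
    """Weighted KS enrichment score over a descending-ranked gene list.

    Walking the ranking, hits increment the running sum by
    |stat|^w / sum over member |stat|^w and misses decrement it by
    1 / (N - N_hit).  The enrichment score is the running-sum value of
    maximum absolute departure from zero (signed); the peak index (0-based)
    and the full running sum are returned alongside.

    ``ranked_stats`` must already be sorted descending; ``membership`` is a
    boolean flag per position.  A ranking without any member is an error.
    If every member statistic is zero (so the hit weights are undefined for
    w > 0), hits fall back to equal weights.
    """
    s = np.asarray(ranked_stats, dtype=float)
    m = np.asarray(membership, dtype=bool)
    if s.shape != m.shape or s.ndim != 1:
        raise ValueError("ranked_stats and membership must be equal-length vectors")
    if np.any(np.diff(s) > 0):
        raise ValueError("ranked_stats must be sorted in descending order")
    n = s.size
    n_hit = int(m.sum())
    if n_hit == 0:
        raise ValueError("no members of the set appear in the ranking")
    if weight_exponent == 0:
        w = m.astype(float)
    else:
        w = np.where(m, np.abs(s) ** weight_exponent, 0.0)
    denom = w.sum()
    if denom == 0:
        w = m.astype(float)
        denom = float(n_hit)
    inc = w / denom
    dec = np.where(m, 0.0, 1.0 / (n - n_hit)) if n > n_hit else np.zeros(n)
    running = np.cumsum(inc - dec)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak, running


def _es_all_sets(
    stats_col: np.ndarray, member: np.ndarray, weight_exponent: float
) -> np.ndarray:
    """Enrichment score of every set (rows of ``member``) for one ranking."""
    order = np.argsort(-stats_col, kind="stable")
    s = stats_col[order]
    M = member[:, order]
    n = s.size
    if weight_exponent == 0:
        wrow = np.ones(n)
    else:
        wrow = np.abs(s) ** weight_exponent
    W = M * wrow
    denom = W.sum(axis=1, keepdims=True)
    n_hit = M.sum(axis=1, keepdims=True)
    # all-zero member stats: equal weights (same fallback as enrichment_score)
    flat = denom[:, 0] == 0
    if flat.any():
        W[flat] = M[flat].astype(float)
        denom[flat] = n_hit[flat]
    hit = np.cumsum(W, axis=1) / denom
    miss_denom = np.maximum(n - n_hit, 1)
    miss = np.cumsum(~M, axis=1) / miss_denom
    run = hit - miss
    peak = np.argmax(np.abs(run), axis=1)
    return run[np.arange(run.shape[0]), peak]


# ---------------------------------------------------------------------------
# Shared permutation machinery
# ---------------------------------------------------------------------------

def _permuted_case_matrix(
    is_case: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_samples, n_perm) boolean matrix of label-swapped phenotypes."""
    n = is_case.size
    out = np.empty((n, n_perm), dtype=bool)
    for b in range(n_perm):
        out[:, b] = is_case[rng.permutation(n)]
    return out


def _observed_from_assoc(
    assoc: pd.DataFrame, snp_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(chi2, p) vectors aligned to ``snp_ids``; errors on missing SNPs."""
    lookup = assoc.set_index("snp")
    missing = [s for s in snp_ids if s not in lookup.index]
    if missing:
        raise ValueError(f"association results missing for SNPs: {missing[:5]}")
    sub = lookup.loc[snp_ids]
    return sub["chi2"].to_numpy(dtype=float), sub["p"].to_numpy(dtype=float)


def _gene_index(
    snp_map: SnpGeneMap, snp_ids: list[str]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Flatten the gene->SNPs map into reduceat-ready (genes, gather, offsets).

    Only genes with at least one SNP present in ``snp_ids`` appear.
    """
    pos = {s: i for i, s in enumerate(snp_ids)}
    genes: list[str] = []
    gather: list[int] = []
    offsets: list[int] = []
    for gene, snps in snp_map.gene_to_snps.items():
        idx = [pos[s] for s in snps if s in pos]
        if not idx:
            continue
        genes.append(gene)
        offsets.append(len(gather))
        gather.extend(idx)
    return genes, np.array(gather, dtype=np.intp), np.array(offsets, dtype=np.intp)


def _membership_matrix(
    sets: GeneSetCollection, genes: list[str]
) -> tuple[list[str], np.ndarray]:
    """(set names, S x G boolean matrix); sets with no scored gene dropped."""
    gene_pos = {g: i for i, g in enumerate(genes)}
    names: list[str] = []
    rows: list[np.ndarray] = []
    for name, members in sets.sets.items():
        row = np.zeros(len(genes), dtype=bool)
        idx = [gene_pos[g] for g in members if g in gene_pos]
        if not idx:
            logger.warning("set %s has no genes in the scored universe; dropped", name)
            continue
        row[idx] = True
        names.append(name)
        rows.append(row)
    if not names:
        raise ValueError("no gene set overlaps the scored gene universe")
    return names, np.array(rows)


def _bh(p: np.ndarray) -> np.ndarray:
    from pathuniter.integrate import bh_fdr

    return bh_fdr(p)


# ---------------------------------------------------------------------------
# GSEA (GenGen-style) for GWAS data
# ---------------------------------------------------------------------------

def _gsea_from_stat_matrix(
    stat_matrix: np.ndarray,
    genes: list[str],
    sets: GeneSetCollection,
    weight_exponent: float,
    fdr_method: str,
) -> pd.DataFrame:
    """GSEA table from a (genes x (1 + B)) statistic matrix, column 0 observed."""
    names, member = _membership_matrix(sets, genes)
    n_cols = stat_matrix.shape[1]
    es = np.empty((len(names), n_cols))
    for c in range(n_cols):
        es[:, c] = _es_all_sets(stat_matrix[:, c], member, weight_exponent)
    es_obs, es_perm = es[:, 0], es[:, 1:]
    B = es_perm.shape[1]

    with np.errstate(invalid="ignore"):
        pos_sum = np.where(es_perm > 0, es_perm, 0.0).sum(axis=1)
        pos_cnt = (es_perm > 0).sum(axis=1)
        neg_sum = np.where(es_perm < 0, es_perm, 0.0).sum(axis=1)
        neg_cnt = (es_perm < 0).sum(axis=1)
    pos_mean = np.divide(pos_sum, pos_cnt, out=np.full(len(names), np.nan),
                         where=pos_cnt > 0)
    neg_mean = np.divide(neg_sum, neg_cnt, out=np.full(len(names), np.nan),
                         where=neg_cnt > 0)

    def _normalize(vals: np.ndarray) -> np.ndarray:
        out = np.full(vals.shape, np.nan)
        posm = pos_mean if vals.ndim == 1 else pos_mean[:, None]
        negm = neg_mean if vals.ndim == 1 else neg_mean[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(vals >= 0, vals / posm, vals / np.abs(negm))
        return out

    nes_obs = _normalize(es_obs)
    # empirical P within the same-sign permutation class (the original GSEA
    # convention): comparing a positive ES against the pooled two-sided null
    # would make null P-values pile up below 0.5 instead of being uniform
    p_emp = np.empty(len(names))
    for i in range(len(names)):
        if es_obs[i] >= 0:
            same = es_perm[i][es_perm[i] >= 0]
            p_emp[i] = (1 + (same >= es_obs[i]).sum()) / (1 + same.size)
        else:
            same = es_perm[i][es_perm[i] < 0]
            p_emp[i] = (1 + (same <= es_obs[i]).sum()) / (1 + same.size)

    if fdr_method == "bh":
        fdr = _bh(p_emp)
    elif fdr_method == "pooled":
        nes_perm = _normalize(es_perm)
        fdr = _pooled_nes_fdr(nes_obs, nes_perm)
    else:
        raise ValueError("fdr_method must be 'pooled' or 'bh'")

    sizes = member.sum(axis=1)
    out = pd.DataFrame(
        {
            "set": names,
            "size": sizes,
            "score": es_obs,
            "nes": nes_obs,
            "p": p_emp,
            "fdr": fdr,
        }
    )
    # permutation scores kept for calibration diagnostics (not serialized)
    out.attrs["obs_scores"] = es_obs
    out.attrs["perm_scores"] = es_perm
    return out


def _pooled_nes_fdr(nes_obs: np.ndarray, nes_perm: np.ndarray) -> np.ndarray:
    """FDR from the pooled permutation-NES distribution (GSEA scheme).

    For a positive observed NES*, q = [share of pooled permutation NES
    >= NES* among non-negative ones] / [share of observed NES >= NES*
    among non-negative ones], clipped to [0, 1]; mirrored for negative.
    """
    pool = nes_perm[np.isfinite(nes_perm)]
    obs = nes_obs[np.isfinite(nes_obs)]
    pool_pos = pool[pool >= 0]
    pool_neg = pool[pool < 0]
    obs_pos = obs[obs >= 0]
    obs_neg = obs[obs < 0]
    fdr = np.full(nes_obs.shape, np.nan)
    for i, v in enumerate(nes_obs):
        if not np.isfinite(v):
            continue
        if v >= 0:
            num = (pool_pos >= v).mean() if pool_pos.size else 1.0
            den = (obs_pos >= v).mean() if obs_pos.size else 1.0
        else:
            num = (pool_neg <= v).mean() if pool_neg.size else 1.0
            den = (obs_neg <= v).mean() if obs_neg.size else 1.0
        fdr[i] = min(1.0, num / den) if den > 0 else 1.0
    return fdr


def gsea_gwas(
    study: GenotypeStudy,
    assoc: pd.DataFrame,
    snp_map: SnpGeneMap,
    sets: GeneSetCollection,
    plan: PermutationPlan = PermutationPlan(),
    weight_exponent: float = 1.0,
    fdr_method: str = "pooled",
) -> pd.DataFrame:
    """GenGen-style GSEA of gene sets in a case/control genotype study.

    Genes are ranked by their max-SNP chi-square; the weighted-KS
    enrichment score of each set is compared against phenotype-swap
    permutations in which the allelic tests and gene statistics are fully
    recomputed.  NES divides ES by the mean permutation ES of the same
    sign; the empirical P counts permutation ES beating the observed one
    on its own side.  FDR uses the pooled permutation-NES scheme by
    default ("bh" selects Benjamini-Hochberg on the empirical P instead).
    """
    if min((study.is_case).sum(), (~study.is_case).sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    chi2_obs, _ = _observed_from_assoc(assoc, study.snp_ids)
    rng = plan.rng()
    perm_labels = _permuted_case_matrix(study.is_case, plan.n_perm, rng)
    chi2_perm = allelic_test_all(study.dosage, perm_labels)
    chi2_all = np.column_stack([chi2_obs, chi2_perm])
    genes, gather, offsets = _gene_index(snp_map, study.snp_ids)
    if not genes:
        raise ValueError("no gene has mapped SNPs")
    gene_stats = np.maximum.reduceat(chi2_all[gather, :], offsets, axis=0)
    return _gsea_from_stat_matrix(gene_stats, genes, sets, weight_exponent, fdr_method)


# ---------------------------------------------------------------------------
# ALIGATOR (SNP resampling)
# ---------------------------------------------------------------------------

def aligator(
    assoc: pd.DataFrame,
    snp_map: SnpGeneMap,
    sets: GeneSetCollection,
    p_cut: float = 0.05,
    plan: PermutationPlan = ALIGATOR_DEFAULT_PLAN,
) -> pd.DataFrame:
    """ALIGATOR over-representation test with a SNP-resampling null.

    A gene is significant when it contains at least one SNP with P below
    ``p_cut`` (counted once however many significant SNPs it holds).  Each
    replicate draws SNPs uniformly without replacement until the number of
    distinct genes hit equals the observed number of significant genes; a
    draw that would overshoot the target is discarded and drawing
    continues.  Each set is then scored on the replicate's gene list and
    the empirical P compares replicate counts against the observed count.
    """
    snp_ids = list(assoc["snp"])
    p_vals = assoc["p"].to_numpy(dtype=float)
    genes, gather, offsets = _gene_index(snp_map, snp_ids)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    # per-SNP gene index lists (most SNPs map to 0 or 1 gene)
    snp_genes: list[list[int]] = [[] for _ in snp_ids]
    snp_pos = {s: i for i, s in enumerate(snp_ids)}
    for gene, snps in snp_map.gene_to_snps.items():
        gi = gene_pos.get(gene)
        if gi is None:
            continue
        for s in snps:
            si = snp_pos.get(s)
            if si is not None:
                snp_genes[si].append(gi)

    sig_snp = p_vals < p_cut
    sig_genes = np.zeros(n_genes, dtype=bool)
    for si in np.flatnonzero(sig_snp):
        for gi in snp_genes[si]:
            sig_genes[gi] = True
    target = int(sig_genes.sum())

    names, member = _membership_matrix(sets, genes)
    obs = member @ sig_genes.astype(np.int64)

    if target == 0:
        logger.warning("no significant genes at p < %g; all ALIGATOR P = 1", p_cut)
        return pd.DataFrame(
            {"set": names, "size": member.sum(axis=1), "score": obs,
             "nes": np.nan, "p": 1.0, "fdr": 1.0}
        )

    rng = plan.rng()
    R = plan.n_perm
    n_snps = len(snp_ids)
    single_gene = all(len(g) <= 1 for g in snp_genes)
    repl_hits = np.zeros((R, n_genes), dtype=bool)
    if single_gene:
        gene_of = np.array([g[0] if g else -1 for g in snp_genes], dtype=np.int64)
        for r in range(R):
            perm = rng.permutation(n_snps)
            gv = gene_of[perm]
            gv = gv[gv >= 0]
            _, first_idx = np.unique(gv, return_index=True)
            first_idx.sort()
            chosen = gv[first_idx[:target]]
            repl_hits[r, chosen] = True
    else:
        for r in range(R):
            perm = rng.permutation(n_snps)
            hit = np.zeros(n_genes, dtype=bool)
            count = 0
            for si in perm:
                new = [gi for gi in snp_genes[si] if not hit[gi]]
                if not new:
                    continue
                if count + len(new) > target:
                    continue  # overshoot: discard this SNP, keep drawing
                for gi in new:
                    hit[gi] = True
                count += len(new)
                if count == target:
                    break
            repl_hits[r] = hit

    repl_scores = member @ repl_hits.T.astype(np.int64)  # (S, R)
    p_emp = (1 + (repl_scores >= obs[:, None]).sum(axis=1)) / (R + 1)
    out = pd.DataFrame(
        {
            "set": names,
            "size": member.sum(axis=1),
            "score": obs.astype(float),
            "nes": np.nan,
            "p": p_emp,
            "fdr": _bh(p_emp),
        }
    )
    out.attrs["obs_scores"] = obs.astype(float)
    out.attrs["perm_scores"] = repl_scores.astype(float)
    return out


# ---------------------------------------------------------------------------
# SNP ratio test
# ---------------------------------------------------------------------------

def snp_ratio_test(
    study: GenotypeStudy,
    assoc: pd.DataFrame,
    snp_map: SnpGeneMap,
    sets: GeneSetCollection,
    p_cut: float = 0.05,
    plan: PermutationPlan = PermutationPlan(),
) -> pd.DataFrame:
    """SNP ratio test: share of a pathway's SNPs that are significant.

    The observed ratio (#SNPs with P < ``p_cut``) / (#SNPs in the pathway)
    is compared against phenotype-swap permutations with the allelic tests
    recomputed.  A SNP shared by several of a pathway's genes is counted
    once for that pathway.  Sets with zero mapped SNPs are dropped with a
    warning.
    """
    chi2_obs, p_obs = _observed_from_assoc(assoc, study.snp_ids)
    snp_pos = {s: i for i, s in enumerate(study.snp_ids)}
    names: list[str] = []
    rows: list[np.ndarray] = []
    for name, members in sets.sets.items():
        snp_idx: set[int] = set()
        for g in members:
            for s in snp_map.gene_to_snps.get(g, ()):  # counted once per pathway
                si = snp_pos.get(s)
                if si is not None:
                    snp_idx.add(si)
        if not snp_idx:
            logger.warning("set %s has no mapped SNPs; dropped from SRT", name)
            continue
        row = np.zeros(study.n_snps, dtype=bool)
        row[sorted(snp_idx)] = True
        names.append(name)
        rows.append(row)
    if not names:
        raise ValueError("no gene set has mapped SNPs")
    M = np.array(rows)
    set_sizes = M.sum(axis=1)

    rng = plan.rng()
    perm_labels = _permuted_case_matrix(study.is_case, plan.n_perm, rng)
    chi2_perm = allelic_test_all(study.dosage, perm_labels)
    chi2_thr = float(stats.chi2.isf(p_cut, df=1))

    obs_ratio = (M.astype(np.int64) @ (p_obs < p_cut).astype(np.int64)) / set_sizes
    perm_ratio = (M.astype(float) @ (chi2_perm > chi2_thr)) / set_sizes[:, None]
    p_emp = (1 + (perm_ratio >= obs_ratio[:, None]).sum(axis=1)) / (plan.n_perm + 1)
    perm_scores = perm_ratio

    # size column reports gene counts for comparability with the other tests
    present_snps = set(study.snp_ids)
    sizes = [
        sum(1 for g in sets.sets[n] if any(
            s in present_snps for s in snp_map.gene_to_snps.get(g, ())))
        for n in names
    ]
    out = pd.DataFrame(
        {
            "set": names,
            "size": sizes,
            "score": obs_ratio,
            "nes": np.nan,
            "p": p_emp,
            "fdr": _bh(p_emp),
        }
    )
    out.attrs["obs_scores"] = obs_ratio
    out.attrs["perm_scores"] = perm_scores
    return out


# ---------------------------------------------------------------------------
# Set-based test (LD-pruned mean chi-square)
# ---------------------------------------------------------------------------

def pairwise_r2(dosage: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between SNP dosage rows.

    Missing entries are handled pairwise-complete via masked arrays;
    undefined correlations (no overlap or zero variance) become 0 so a
    degenerate pair is never pruned on the basis of an unknowable r2.
    """
    dosage = np.atleast_2d(np.asarray(dosage, dtype=float))
    if dosage.shape[0] == 1:
        return np.ones((1, 1))
    d = np.ma.masked_invalid(dosage)
    r = np.ma.corrcoef(d)
    r2 = np.asarray(np.ma.filled(r, 0.0)) ** 2
    np.fill_diagonal(r2, 1.0)
    return r2


def select_independent_snps(
    set_snps: list[str],
    p_values: np.ndarray,
    dosage: np.ndarray,
    r2_cut: float = 0.5,
    p_cut: float = 0.05,
    max_snps: int = 5,
) -> list[str]:
    """Greedy LD-pruned selection of significant SNPs within one set.

    Repeatedly pick the smallest-P remaining SNP with P < ``p_cut`` (ties
    break to the earlier SNP in ``set_snps`` order), then drop every
    remaining SNP whose dosage r2 with the pick exceeds ``r2_cut``; stop
    when ``max_snps`` are selected or no eligible SNP remains.  ``dosage``
    rows align with ``set_snps``.  An empty selection is allowed.
    """
    p = np.asarray(p_values, dtype=float)
    if len(set_snps) != p.size or dosage.shape[0] != p.size:
        raise ValueError("set_snps, p_values and dosage rows must align")
    r2 = pairwise_r2(dosage)
    idx = _greedy_select(p, r2, r2_cut, p_cut, max_snps)
    return [set_snps[i] for i in idx]


def _greedy_select(
    p: np.ndarray,
    r2: np.ndarray,
    r2_cut: float,
    p_cut: float,
    max_snps: int,
) -> list[int]:
    order = np.argsort(p, kind="stable")
    removed = np.zeros(p.size, dtype=bool)
    selected: list[int] = []
    for i in order:
        if removed[i]:
            continue
        if not p[i] < p_cut:
            break  # p sorted ascending: nothing further is eligible
        selected.append(int(i))
        removed |= r2[i] > r2_cut  # prunes i itself (r2 diagonal is 1)
        if len(selected) >= max_snps:
            break
    return selected


def _greedy_select_chi2(
    chi2: np.ndarray, r2: np.ndarray, chi2_thr: float, r2_cut: float, max_snps: int
) -> list[int]:
    """Greedy selection on the chi-square scale (descending == ascending P)."""
    order = np.argsort(-chi2, kind="stable")
    removed = np.zeros(chi2.size, dtype=bool)
    selected: list[int] = []
    for i in order:
        if removed[i]:
            continue
        if not chi2[i] > chi2_thr:
            break
        selected.append(int(i))
        removed |= r2[i] > r2_cut
        if len(selected) >= max_snps:
            break
    return selected


def set_based_test(
    study: GenotypeStudy,
    assoc: pd.DataFrame,
    snp_map: SnpGeneMap,
    sets: GeneSetCollection,
    r2_cut: float = 0.5,
    p_cut: float = 0.05,
    max_snps: int = 5,
    plan: PermutationPlan = PermutationPlan(),
) -> pd.DataFrame:
    """Set-based test: mean chi-square of LD-pruned selected SNPs.

    Per pathway the greedy selection of ``select_independent_snps`` is
    applied and the mean chi-square of the selected SNPs is the score
    (0 when nothing is selected).  Under each phenotype-swap permutation
    the allelic tests are recomputed and the selection re-run from
    scratch; the empirical P compares permutation means against the
    observed mean.  The dosage r2 matrix is permutation-invariant and is
    computed once per set.
    """
    chi2_obs, _p_obs = _observed_from_assoc(assoc, study.snp_ids)
    snp_pos = {s: i for i, s in enumerate(study.snp_ids)}
    chi2_thr = float(stats.chi2.isf(p_cut, df=1))

    set_entries: list[tuple[str, int, np.ndarray, np.ndarray]] = []
    for name, members in sets.sets.items():
        snp_idx_set: set[int] = set()
        n_genes = 0
        for g in members:
            snps_here = [snp_pos[s] for s in snp_map.gene_to_snps.get(g, ())
                         if s in snp_pos]
            if snps_here:
                n_genes += 1
            snp_idx_set.update(snps_here)
        if not snp_idx_set:
            logger.warning("set %s has no mapped SNPs; score 0, p 1", name)
            set_entries.append((name, 0, np.array([], dtype=np.intp), np.empty((0, 0))))
            continue
        snp_idx = np.array(sorted(snp_idx_set), dtype=np.intp)
        r2 = pairwise_r2(study.dosage[snp_idx])
        set_entries.append((name, n_genes, snp_idx, r2))

    rng = plan.rng()
    perm_labels = _permuted_case_matrix(study.is_case, plan.n_perm, rng)
    chi2_perm = allelic_test_all(study.dosage, perm_labels)
    chi2_all = np.column_stack([chi2_obs, chi2_perm])

    records = []
    perm_scores = np.zeros((len(set_entries), plan.n_perm))
    for k, (name, n_genes, snp_idx, r2) in enumerate(set_entries):
        if snp_idx.size == 0:
            records.append((name, n_genes, 0.0, np.nan, 1.0))
            continue
        sub = chi2_all[snp_idx, :]
        means = np.zeros(sub.shape[1])
        for c in range(sub.shape[1]):
            sel = _greedy_select_chi2(sub[:, c], r2, chi2_thr, r2_cut, max_snps)
            if sel:
                means[c] = sub[sel, c].mean()
        obs = means[0]
        perm_scores[k] = means[1:]
        if obs == 0.0:
            p_emp = 1.0
        else:
            p_emp = (1 + (means[1:] >= obs).sum()) / (plan.n_perm + 1)
        records.append((name, n_genes, obs, np.nan, p_emp))

    df = pd.DataFrame(records, columns=["set", "size", "score", "nes", "p"])
    df["fdr"] = _bh(df["p"].to_numpy())
    df.attrs["obs_scores"] = df["score"].to_numpy()
    df.attrs["perm_scores"] = perm_scores
    return df
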