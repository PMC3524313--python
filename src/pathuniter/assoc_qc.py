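"""Quality control, the basic allelic association test, and genomic inflation.

The allelic test compares minor-allele counts between cases and controls in
a 2x2 table with 2N alleles per class, using the Pearson chi-square without
continuity correction (1 df).  QC applies the standard case/control filters
with strict inequalities: samples with missingness > 0.10 are removed
first, then SNPs with call rate < 0.90, MAF < 0.05 (recomputed after the
sample drop), or a monomorphic genotype column.  The genomic inflation
factor lambda is the ratio of the observed median chi-square to the
theoretical 1-df median; it is reported descriptively and never used to
rescale statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pathuniter.formats_io import GenotypeStudy

logger = logging.getLogger(__name__)

# exact 1-df chi-square median, the lambda_GC denominator
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass(frozen=True)
class QCThresholds:
    """Strict-inequality QC cutoffs; boundary values survive every filter."""

    min_call_rate: float = 0.90
    min_maf: float = 0.05
    max_sample_missing: float = 0.10
    drop_monomorphic: bool = True

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class AssocResult:
    snp_id: str
    chi2: float
    p: float
    maf: float
    call_rate: float
    degenerate: bool = False


@dataclass(frozen=True)
class InflationFactor:
    lambda_gc: float

    def __post_init__(self) -> None:
        if not self.lambda_gc > 0:
            raise ValueError("lambda_gc must be positive")


def apply_qc(
    study: GenotypeStudy, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypeStudy, dict[str, int]]:
    """Filter samples then SNPs; return the cleaned study and drop counts.

    Order matters and is fixed: (1) samples with missing fraction
    > max_sample_missing go first; (2) SNP call rate and MAF are recomputed
    on the remaining samples and SNPs failing call rate < min_call_rate,
    MAF < min_maf, or monomorphic status are removed.  The result is
    independent of input row order.  Removing everything raises.
    """
    if study.n_snps == 0 or study.n_samples == 0:
        raise ValueError("empty study")
    missing = np.isnan(study.dosage)
    sample_missing = missing.mean(axis=0)
    keep_samples = sample_missing <= thresholds.max_sample_missing
    n_samples_dropped = int((~keep_samples).sum())
    if not keep_samples.any():
        raise ValueError("empty study: all samples removed by QC")

    dosage = study.dosage[:, keep_samples]
    nonmissing = ~np.isnan(dosage)
    n_called = nonmissing.sum(axis=1)
    call_rate = n_called / dosage.shape[1]
    with np.errstate(invalid="ignore"):
        freq = np.nansum(dosage, axis=1) / np.maximum(2 * n_called, 1)
    maf = np.minimum(freq, 1 - freq)
    d0 = np.where(nonmissing, dosage, np.nan)
    mono = np.array([
        len(np.unique(row[~np.isnan(row)])) <= 1 for row in d0
    ])

    fail_call = call_rate < thresholds.min_call_rate
    fail_maf = maf < thresholds.min_maf
    fail_mono = mono & thresholds.drop_monomorphic
    keep_snps = ~(fail_call | fail_maf | fail_mono)
    if not keep_snps.any():
        raise ValueError("empty study: all SNPs removed by QC")

    report = {
        "samples_in": study.n_samples,
        "samples_dropped_missing": n_samples_dropped,
        "snps_in": study.n_snps,
        "snps_dropped_call_rate": int(fail_call.sum()),
        "snps_dropped_maf": int((fail_maf & ~fail_call).sum()),
        "snps_dropped_monomorphic": int((fail_mono & ~fail_call & ~fail_maf).sum()),
        "snps_out": int(keep_snps.sum()),
        "samples_out": int(keep_samples.sum()),
    }
    logger.info("QC report: %s", report)

    idx = np.flatnonzero(keep_snps)
    cleaned = GenotypeStudy(
        snp_ids=[study.snp_ids[i] for i in idx],
        chrom=study.chrom[keep_snps],
        pos=study.pos[keep_snps],
        dosage=dosage[keep_snps],
        sample_ids=[s for s, k in zip(study.sample_ids, keep_samples) if k],
        phenotype=study.phenotype[keep_samples],
    )
    return cleaned, report


def _allelic_chi2_from_counts(
    a_case: np.ndarray,
    n_case: np.ndarray,
    a_total: np.ndarray,
    n_total: np.ndarray,
) -> np.ndarray:
    """Pearson chi-square (no continuity correction) of the 2x2 allele table.

    a_case:  minor-allele count among case alleles
    n_case:  total case alleles (2 x called cases)
    a_total: minor-allele count overall
    n_total: total alleles overall
    Degenerate tables (a zero marginal) yield chi2 = 0.
    """
    a_case = np.asarray(a_case, dtype=float)
    n_case = np.asarray(n_case, dtype=float)
    a_total = np.asarray(a_total, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    n_ctrl = n_total - n_case
    a_ctrl = a_total - a_case
    # cells: [[a_case, n_case - a_case], [a_ctrl, n_ctrl - a_ctrl]]
    det = a_case * (n_ctrl - a_ctrl) - (n_case - a_case) * a_ctrl
    denom = n_case * n_ctrl * a_total * (n_total - a_total)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n_total * det**2 / denom
    return np.where(denom > 0, chi2, 0.0)


def allelic_test_all(
    dosage: np.ndarray, case_indicator: np.ndarray
) -> np.ndarray:
    """Allelic chi-square for every SNP under one or many case labelings.

    ``dosage`` is (n_snps, n_samples) with NaN for missing; ``case_indicator``
    is (n_samples,) boolean or (n_samples, B) for B labelings at once.
    Returns chi2 of shape (n_snps,) or (n_snps, B).  This is the hot path
    shared by all phenotype-permutation tests.
    """
    dosage = np.asarray(dosage, dtype=float)
    one_d = case_indicator.ndim == 1
    C = np.atleast_2d(case_indicator.astype(float).T).T  # (n_samples, B)
    nonmissing = (~np.isnan(dosage)).astype(float)
    dz = np.nan_to_num(dosage)
    a_case = dz @ C  # (n_snps, B)
    n_case = 2.0 * (nonmissing @ C)
    a_total = dz.sum(axis=1, keepdims=True)
    n_total = 2.0 * nonmissing.sum(axis=1, keepdims=True)
    chi2 = _allelic_chi2_from_counts(a_case, n_case, a_total, n_total)
    return chi2[:, 0] if one_d else chi2


def allelic_test(
    dosage: np.ndarray, phenotype: np.ndarray, snp_id: str = ""
) -> AssocResult:
    """Basic allelic test of a single SNP: 1-df chi-square on allele counts.

    Missing dosages are excluded; both classes must remain after exclusion.
    A zero marginal (one allele absent overall) gives chi2 = 0, p = 1,
    flagged degenerate.
    """
    dosage = np.asarray(dosage, dtype=float)
    phenotype = np.asarray(phenotype, dtype=object)
    called = ~np.isnan(dosage)
    if len({p for p, c in zip(phenotype, called) if c}) < 2:
        raise ValueError("both classes must be present after removing missing calls")
    is_case = phenotype == "case"
    chi2 = float(allelic_test_all(dosage[None, :], is_case)[0])
    n_called = int(called.sum())
    freq = float(dosage[called].sum() / (2 * n_called))
    maf = min(freq, 1 - freq)
    degenerate = freq in (0.0, 1.0)
    p = 1.0 if degenerate else float(stats.chi2.sf(chi2, df=1))
    return AssocResult(
        snp_id=snp_id,
        chi2=0.0 if degenerate else chi2,
        p=p,
        maf=maf,
        call_rate=n_called / dosage.size,
        degenerate=degenerate,
    )


def assoc_table(study: GenotypeStudy) -> pd.DataFrame:
    """Per-SNP allelic test over a whole study.

    Returns a DataFrame with columns snp, chr, pos, maf, call_rate, chi2, p
    in the study's SNP order.
    """
    chi2 = allelic_test_all(study.dosage, study.is_case)
    called = ~np.isnan(study.dosage)
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(study.dosage, axis=1) / np.maximum(2 * n_called, 1)
    maf = np.minimum(freq, 1 - freq)
    degenerate = (freq <= 0.0) | (freq >= 1.0)
    chi2 = np.where(degenerate, 0.0, chi2)
    p = np.where(degenerate, 1.0, stats.chi2.sf(chi2, df=1))
    return pd.DataFrame(
        {
            "snp": study.snp_ids,
            "chr": study.chrom,
            "pos": study.pos,
            "maf": maf,
            "call_rate": n_called / study.n_samples,
            "chi2": chi2,
            "p": p,
        }
    )


def genomic_inflation(results: pd.DataFrame | np.ndarray) -> InflationFactor:
    """Genomic inflation factor: median observed chi2 over the 1-df median.

    Accepts an association table (uses its ``chi2`` column) or a raw
    chi-square vector.
    """
    if isinstance(results, pd.DataFrame):
        chi2 = results["chi2"].to_numpy()
    else:
        chi2 = np.asarray(results, dtype=float)
    if chi2.size == 0:
        raise ValueError("need at least one association result")
    return InflationFactor(lambda_gc=float(np.median(chi2) / CHI2_1DF_MEDIAN))
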