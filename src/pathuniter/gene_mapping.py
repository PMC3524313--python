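"""SNP-to-gene assignment, gene-wise statistics, and derived gene sets.

A SNP is assigned to a gene when it lies within the gene body or within a
flanking distance (default 20 kb) of either boundary, inclusive at the
boundary; a SNP overlapping several genes contributes to all of them.  The
gene-wise association statistic is the maximum chi-square over the gene's
SNPs, represented by that SNP and its P-value.  Gene sets are filtered to
an effective size range (default 5-250, inclusive) after intersection with
the platform's scoreable-gene universe.  Cross-platform derived sets:
top-k GWAS genes, GWAS genes below a P cutoff, and differentially
expressed gene sets at nested |log2 ratio| thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pathuniter.formats_io import GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 20_000


@dataclass
class SnpGeneMap:
    """Bidirectional SNP/gene assignment within a flank distance."""

    gene_to_snps: dict[str, list[str]]
    snp_to_genes: dict[str, list[str]]
    flank_bp: int = DEFAULT_FLANK_BP

    @property
    def genes_with_snps(self) -> list[str]:
        return [g for g, s in self.gene_to_snps.items() if s]


@dataclass
class GeneStatTable:
    """Per-gene representative-SNP statistic: gene, snp, chi2, p."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"gene", "snp", "chi2", "p"}
        if not required <= set(self.table.columns):
            raise ValueError(f"gene stat table needs columns {sorted(required)}")

    def __len__(self) -> int:
        return len(self.table)


def map_snps_to_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, flank_bp: int = DEFAULT_FLANK_BP
) -> SnpGeneMap:
    """Assign SNPs to genes within gene body +- ``flank_bp`` (inclusive).

    ``snps`` needs columns snp/chr/pos (1-based); ``genes`` needs
    gene/chrom/start/end (1-based inclusive).  Genes with no SNPs are
    present with empty lists; the result is independent of SNP input order.
    """
    gene_to_snps: dict[str, list[str]] = {g: [] for g in genes["gene"]}
    snp_to_genes: dict[str, list[str]] = {}
    snps_sorted = snps.sort_values(["chr", "pos", "snp"], kind="stable")
    by_chrom = {str(c): grp for c, grp in snps_sorted.groupby("chr")}
    for row in genes.itertuples(index=False):
        grp = by_chrom.get(str(row.chrom))
        if grp is None:
            continue
        lo, hi = row.start - flank_bp, row.end + flank_bp
        pos = grp["pos"].to_numpy()
        hit = grp["snp"].to_numpy()[(pos >= lo) & (pos <= hi)]
        gene_to_snps[row.gene] = list(hit)
        for s in hit:
            snp_to_genes.setdefault(s, []).append(row.gene)
    return SnpGeneMap(gene_to_snps, snp_to_genes, flank_bp)


def gene_statistics(assoc: pd.DataFrame, snp_map: SnpGeneMap) -> GeneStatTable:
    """Representative-SNP statistic per gene: the maximum-chi2 SNP.

    Every mapped SNP must have an association result.  Genes with no
    mapped SNPs are omitted.  Ties at the maximum chi-square break to the
    smaller genomic position, then SNP id (logged).
    """
    cols = ["chi2", "p"] + (["pos"] if "pos" in assoc.columns else [])
    lookup = assoc.set_index("snp")[cols]
    rows = []
    for gene, snp_ids in snp_map.gene_to_snps.items():
        if not snp_ids:
            continue
        missing = [s for s in snp_ids if s not in lookup.index]
        if missing:
            raise ValueError(
                f"gene {gene}: mapped SNPs missing association results: {missing[:5]}"
            )
        sub = lookup.loc[snp_ids]
        chi2 = sub["chi2"].to_numpy(dtype=float)
        best = chi2.max()
        tied = np.flatnonzero(chi2 == best)
        if len(tied) > 1:
            if "pos" in sub.columns:
                order = np.lexsort((np.array(snp_ids, dtype=object)[tied],
                                    sub["pos"].to_numpy()[tied]))
            else:
                order = np.argsort(np.array(snp_ids, dtype=object)[tied])
            pick = tied[order[0]]
            logger.info("gene %s: max-chi2 tie broken to SNP %s", gene, snp_ids[pick])
        else:
            pick = tied[0]
        rows.append((gene, snp_ids[pick], float(chi2[pick]), float(sub["p"].iloc[pick])))
    return GeneStatTable(pd.DataFrame(rows, columns=["gene", "snp", "chi2", "p"]))


def filter_gene_sets(
    collection: GeneSetCollection,
    universe: set[str] | frozenset[str],
    min_size: int = 5,
    max_size: int = 250,
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Keep sets whose size after universe intersection is in [min, max].

    Returns the filtered collection plus a report of original and effective
    sizes for every input set.  Idempotent by construction.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    kept: dict[str, tuple[str, ...]] = {}
    report_rows = []
    for name, genes in collection.sets.items():
        effective = tuple(g for g in genes if g in universe)
        keep = min_size <= len(effective) <= max_size
        report_rows.append((name, len(genes), len(effective), keep))
        if keep:
            kept[name] = effective
    report = pd.DataFrame(
        report_rows, columns=["set", "original_size", "effective_size", "kept"]
    )
    filtered = GeneSetCollection(
        kept,
        universe=universe,
        provenance={k: v for k, v in collection.provenance.items() if k in kept},
    )
    return filtered, report


def derive_gwas_gene_sets(
    stats: GeneStatTable, top_k: int = 30, p_cut: float = 1e-4
) -> GeneSetCollection:
    """Derive gene sets from GWAS gene-wise P-values for the expression arm.

    GWAS_Top30: the ``top_k`` smallest-P genes (ties at the k-th P broken
    by gene name, logged).  GWAS_TopP-4: all genes with P < ``p_cut``
    (may be empty; then the set is omitted with a warning, since empty
    sets are not representable).
    """
    df = stats.table
    if df.empty:
        raise ValueError("empty gene statistics table")
    if len(df) < top_k:
        logger.warning(
            "only %d genes available for top-%d set; using all", len(df), top_k
        )
    ordered = df.sort_values(["p", "gene"], kind="stable")
    if len(ordered) > top_k:
        kth_p = ordered["p"].iloc[top_k - 1]
        if (ordered["p"] == kth_p).sum() > 1:
            logger.info("top-%d boundary tie at p=%g broken by gene name", top_k, kth_p)
    top = tuple(ordered["gene"].head(top_k))
    sets = {"GWAS_Top30": top}
    prov = {"GWAS_Top30": f"top {top_k} genes by gene-wise association P"}
    low = tuple(ordered.loc[ordered["p"] < p_cut, "gene"])
    if low:
        sets["GWAS_TopP-4"] = low
        prov["GWAS_TopP-4"] = f"genes with gene-wise association P < {p_cut:g}"
    else:
        logger.warning("no gene with P < %g; GWAS_TopP-4 omitted (empty)", p_cut)
    return GeneSetCollection(sets, provenance=prov)


def derive_deg_gene_sets(
    de: pd.DataFrame,
    fdr_cut: float = 0.05,
    lr_thresholds: tuple[float, ...] = (1.0, 1.5, 2.0),
) -> GeneSetCollection:
    """Differentially-expressed gene sets at nested |log2 ratio| thresholds.

    DEG_LR_x = genes with FDR < ``fdr_cut`` and |log2_ratio| > x; by
    construction DEG_LR_2 is a subset of DEG_LR_1.5 is a subset of
    DEG_LR_1.  Thresholds yielding empty sets are omitted with a warning.
    """
    required = {"gene", "log2_ratio", "fdr"}
    if not required <= set(de.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    sets: dict[str, tuple[str, ...]] = {}
    prov: dict[str, str] = {}
    passing = de[de["fdr"] < fdr_cut]
    for thr in lr_thresholds:
        name = f"DEG_LR_{thr:g}"
        genes = tuple(passing.loc[passing["log2_ratio"].abs() > thr, "gene"])
        if genes:
            sets[name] = genes
            prov[name] = f"DE genes with FDR < {fdr_cut:g} and |log2 ratio| > {thr:g}"
        else:
            logger.warning("no genes pass |LR| > %g at FDR < %g", thr, fdr_cut)
    return GeneSetCollection(sets, provenance=prov)
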