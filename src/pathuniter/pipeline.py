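"""End-to-end orchestration: QC -> association -> mapping -> four GWAS
pathway tests -> expression arm -> Fisher combination -> overlap report.

A single :class:`PipelineConfig` (loadable from YAML) names either input
files (PED/MAP, BED, GMT, expression matrix + phenotype) or a synthetic
block, plus per-method parameter blocks.  :func:`run_pipeline` executes the
stages in workflow order, writes every result table with a config snapshot
into the output directory, and is byte-reproducible for a fixed seed.
The combined analysis pairs the set-based test's pathway P-values with the
expression GSEA's, mirroring the standard usage of the two arms.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from pathuniter import assoc_qc, expr_enrichment, gene_mapping, gwas_enrichment
from pathuniter import formats_io, integrate, synthetic_data
from pathuniter.formats_io import GeneSetCollection
from pathuniter.gwas_enrichment import PermutationPlan

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs, per-method parameters, seed, output.

    Exactly one of ``inputs`` (file paths: ped, map, bed, gmt, expr, pheno)
    or ``synthetic`` (SyntheticConfig fields) must be given.
    """

    out_dir: str = "pathuniter_run"
    seed: int = 0
    inputs: dict[str, str] | None = None
    synthetic: dict[str, Any] | None = None
    qc: dict[str, Any] = field(default_factory=dict)
    mapping: dict[str, Any] = field(default_factory=dict)
    methods: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("exactly one of 'inputs' or 'synthetic' must be set")
        if self.inputs is not None:
            required = {"ped", "map", "bed", "gmt", "expr", "pheno"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(f"inputs block missing paths: {sorted(missing)}")
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    raise ValueError(f"input path does not exist: {key}={path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _method_params(config: PipelineConfig, name: str, defaults: dict) -> dict:
    out = dict(defaults)
    out.update(config.methods.get(name, {}))
    return out


def _plan(config: PipelineConfig, offset: int, n_perm: int, scheme: str) -> PermutationPlan:
    return PermutationPlan(
        n_perm=n_perm, seed=(config.seed + offset) % 2**31, scheme=scheme
    )


def _stage(name: str, code: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, code, str(exc)) from exc


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full workflow; return the output directory.

    Emits assoc.tsv, gene_stats.tsv, de.tsv, one results TSV per method
    (gsea_gwas, aligator, srt, setbased, gsea_expr), combined.tsv,
    overlap.tsv, qc_report.json, and config_snapshot.yaml.  Re-running on
    the snapshot reproduces every output byte-identically.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config_snapshot.yaml", "w", newline="\n") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    # -- stage: inputs -----------------------------------------------------
    if config.synthetic is not None:
        syn = _stage("inputs", "bad-synthetic-config",
                     synthetic_data.SyntheticConfig,
                     **{**config.synthetic, "seed": config.synthetic.get("seed", config.seed)})
        genome, truth, geno_study, expr_study = _stage(
            "inputs", "synthesis-failed", synthetic_data.generate_study, syn
        )
        genes_df = genome.genes
        collection = genome.sets
        with open(out / "truth.json", "w", newline="\n") as fh:
            json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        paths = config.inputs
        geno_study = _stage("inputs", "bad-genotypes", formats_io.read_plink_text,
                            paths["ped"], paths["map"])
        genes_df = _stage("inputs", "bad-bed", formats_io.read_gene_bed, paths["bed"])
        collection = _stage("inputs", "bad-gmt", formats_io.read_gmt, paths["gmt"])
        expr_study = _stage("inputs", "bad-expression", formats_io.read_expression,
                            paths["expr"], paths["pheno"])

    # -- stage: qc + association ------------------------------------------
    thresholds = _stage("qc", "bad-thresholds", assoc_qc.QCThresholds, **config.qc)
    geno_study, qc_report = _stage("qc", "qc-failed", assoc_qc.apply_qc,
                                   geno_study, thresholds)
    with open(out / "qc_report.json", "w", newline="\n") as fh:
        json.dump(qc_report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    assoc = _stage("association", "allelic-test-failed", assoc_qc.assoc_table,
                   geno_study)
    lam = assoc_qc.genomic_inflation(assoc).lambda_gc
    assoc.to_csv(out / "assoc.tsv", sep="\t", index=False, float_format="%.6g",
                 lineterminator="\n")
    logger.info("genomic inflation lambda = %.3f (reported, not corrected for)", lam)

    # -- stage: mapping + gene statistics ---------------------------------
    flank = int(config.mapping.get("flank_bp", gene_mapping.DEFAULT_FLANK_BP))
    snp_df = assoc[["snp", "chr", "pos"]]
    snp_map = _stage("mapping", "mapping-failed", gene_mapping.map_snps_to_genes,
                     snp_df, genes_df, flank)
    gene_stats = _stage("mapping", "gene-stats-failed", gene_mapping.gene_statistics,
                        assoc, snp_map)
    gene_stats.table.to_csv(out / "gene_stats.tsv", sep="\t", index=False,
                            float_format="%.6g", lineterminator="\n")

    min_size = int(config.mapping.get("min_set_size", 5))
    max_size = int(config.mapping.get("max_set_size", 250))
    gwas_universe = set(gene_stats.table["gene"])
    gwas_sets, _rep = _stage("mapping", "set-filter-failed",
                             gene_mapping.filter_gene_sets,
                             collection, gwas_universe, min_size, max_size)
    expr_universe = set(expr_study.gene_ids)
    expr_sets, _rep2 = _stage("mapping", "set-filter-failed",
                              gene_mapping.filter_gene_sets,
                              collection, expr_universe, min_size, max_size)

    # -- stage: four GWAS pathway tests -----------------------------------
    results: dict[str, pd.DataFrame] = {}
    p_gsea = _method_params(config, "gsea", {"n_perm": 1000, "weight_exponent": 1.0})
    results["gsea_gwas"] = _stage(
        "gwas-enrichment", "gsea-failed", gwas_enrichment.gsea_gwas,
        geno_study, assoc, snp_map, gwas_sets,
        _plan(config, 11, int(p_gsea["n_perm"]), "phenotype-swap"),
        float(p_gsea["weight_exponent"]),
    )
    p_ali = _method_params(config, "aligator", {"n_perm": 10_000, "p_cut": 0.05})
    results["aligator"] = _stage(
        "gwas-enrichment", "aligator-failed", gwas_enrichment.aligator,
        assoc, snp_map, gwas_sets, float(p_ali["p_cut"]),
        _plan(config, 12, int(p_ali["n_perm"]), "snp-resample"),
    )
    p_srt = _method_params(config, "srt", {"n_perm": 1000, "p_cut": 0.05})
    results["srt"] = _stage(
        "gwas-enrichment", "srt-failed", gwas_enrichment.snp_ratio_test,
        geno_study, assoc, snp_map, gwas_sets, float(p_srt["p_cut"]),
        _plan(config, 13, int(p_srt["n_perm"]), "phenotype-swap"),
    )
    p_set = _method_params(config, "setbased",
                           {"n_perm": 1000, "p_cut": 0.05, "r2_cut": 0.5,
                            "max_snps": 5})
    results["setbased"] = _stage(
        "gwas-enrichment", "setbased-failed", gwas_enrichment.set_based_test,
        geno_study, assoc, snp_map, gwas_sets, float(p_set["r2_cut"]),
        float(p_set["p_cut"]), int(p_set["max_snps"]),
        _plan(config, 14, int(p_set["n_perm"]), "phenotype-swap"),
    )

    # -- stage: expression arm --------------------------------------------
    de = _stage("expression", "de-failed", expr_enrichment.differential_expression,
                expr_study)
    de.to_csv(out / "de.tsv", sep="\t", index=False, float_format="%.6g",
              lineterminator="\n")
    p_ge = _method_params(config, "gsea_expr", {"n_perm": 1000,
                                                "weight_exponent": 1.0})
    results["gsea_expr"] = _stage(
        "expression", "gsea-expr-failed", expr_enrichment.gsea_expression,
        expr_study, expr_sets,
        _plan(config, 15, int(p_ge["n_perm"]), "phenotype-swap"),
        float(p_ge["weight_exponent"]),
    )

    flagged: dict[str, pd.DataFrame] = {}
    for name, table in results.items():
        flagged[name] = integrate.tier_select(table)
        formats_io.write_results_table(flagged[name], out / f"{name}.tsv")

    # -- stage: combination + overlap -------------------------------------
    combined = _stage("integration", "combine-failed", integrate.combine_platforms,
                      results["setbased"], results["gsea_expr"])
    combined_out = combined.rename(columns={"p_combined": "p"})
    combined_out["score"] = combined_out["chi2"]
    formats_io.write_results_table(combined_out, out / "combined.tsv")

    venn_inputs = {
        name: integrate.significant_sets(flagged[name])
        for name in ("gsea_gwas", "setbased", "srt", "gsea_expr")
    }
    overlap = _stage("integration", "overlap-failed", integrate.overlap_summary,
                     venn_inputs)
    overlap.to_csv(out / "overlap.tsv", sep="\t", index=False, lineterminator="\n")

    summary = {
        "lambda_gc": round(lam, 6),
        "n_sets_gwas": len(gwas_sets),
        "n_sets_expr": len(expr_sets),
        "n_common_combined": int(combined.attrs.get("n_common", len(combined))),
    }
    with open(out / "summary.json", "w", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
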