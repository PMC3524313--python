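"""Readers and writers for the external formats the pipeline touches.

Formats: GMT gene sets (MSigDB dialect), PLINK text PED/MAP genotypes,
BED4 gene models, TSV expression matrices with a two-column phenotype
file, and the fixed-column results TSV.  All readers are line-ending
agnostic and order-stable; all writers produce byte-deterministic output
for identical input.

Coordinate conventions: BED is 0-based half-open on disk and converted to
1-based inclusive intervals in memory; every public API uses the in-memory
convention.  Strand is ignored throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHENOTYPE_LABELS = ("control", "case")
VALID_ALLELES = frozenset("ACGT")

RESULTS_COLUMNS = ["set", "size", "score", "nes", "p", "fdr", "tier1", "tier2"]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over an optional universe of scoreable genes.

    ``sets`` maps a unique set name to an ordered tuple of unique gene
    identifiers; ``universe`` restricts which genes are scoreable (``None``
    means unrestricted); ``provenance`` carries free text per set (the GMT
    description field, a filter note, ...).
    """

    sets: dict[str, tuple[str, ...]]
    universe: frozenset[str] | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets left empty."""
        uni = frozenset(universe)
        kept: dict[str, tuple[str, ...]] = {}
        for name, genes in self.sets.items():
            inter = tuple(g for g in genes if g in uni)
            if inter:
                kept[name] = inter
        return GeneSetCollection(
            kept, universe=uni,
            provenance={k: v for k, v in self.provenance.items() if k in kept},
        )


@dataclass
class GenotypeStudy:
    """SNP-by-sample minor-allele dosages with a binary phenotype.

    ``dosage`` holds entries in {0, 1, 2} counting minor alleles, with
    ``NaN`` marking missing calls.  ``phenotype`` holds "case"/"control"
    per sample.  This is the permutation substrate for the self-contained
    pathway tests.
    """

    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    sample_ids: list[str]
    phenotype: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.phenotype = np.asarray(self.phenotype, dtype=object)
        if self.dosage.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.snp_ids)} SNPs x {len(self.sample_ids)} samples"
            )
        if np.any(self.pos < 0):
            raise ValueError("SNP positions must be non-negative")
        bad = set(self.phenotype) - set(PHENOTYPE_LABELS)
        if bad:
            raise ValueError(f"unknown phenotype labels: {sorted(bad)}")
        if len(set(self.phenotype)) < 2:
            raise ValueError("phenotype must contain both cases and controls")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def is_case(self) -> np.ndarray:
        return self.phenotype == "case"


@dataclass
class ExpressionStudy:
    """Gene-by-sample real-valued expression with a binary phenotype."""

    gene_ids: list[str]
    values: np.ndarray
    sample_ids: list[str]
    phenotype: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        bad = set(self.phenotype) - set(PHENOTYPE_LABELS)
        if bad:
            raise ValueError(f"unknown phenotype labels: {sorted(bad)}")
        if len(self.phenotype) != len(self.sample_ids):
            raise ValueError("phenotype length does not match samples")

    @property
    def is_case(self) -> np.ndarray:
        return self.phenotype == "case"


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file: name TAB description TAB gene...

    Duplicate genes within a line are deduplicated (first occurrence wins)
    with a logged warning; a duplicate set name or a line with fewer than
    three fields is an error.
    """
    sets: dict[str, tuple[str, ...]] = {}
    provenance: dict[str, str] = {}
    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    logger.warning(
                        "GMT set %s: duplicate gene %s deduplicated", name, g
                    )
                seen[g] = None
            if not seen:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no genes")
            sets[name] = tuple(seen)
            provenance[name] = desc
    return GeneSetCollection(sets, provenance=provenance)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, genes in collection.sets.items():
            desc = collection.provenance.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeStudy:
    """Read PLINK text PED/MAP into minor-allele dosages.

    The minor allele per SNP is determined from non-missing calls across
    all samples; a 50/50 tie is broken toward the lexicographically
    smaller allele (logged).  "0" codes a missing allele; any allele
    outside {A, C, G, T, 0} is an error.  Phenotype comes from PED
    column 6 (1=control, 2=case).
    """
    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    with open(map_path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{map_path}: line {lineno}: expected 4 columns")
            chroms.append(fields[0])
            snp_ids.append(fields[1])
            positions.append(int(fields[3]))
    n_snps = len(snp_ids)

    sample_ids: list[str] = []
    phenotypes: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_snps} "
                    f"columns for {n_snps} MAP SNPs, got {len(fields)}"
                )
            fid, iid, _father, _mother, _sex, pheno = fields[:6]
            sample_ids.append(f"{fid}_{iid}" if fid not in ("0", iid) else iid)
            if pheno == "1":
                phenotypes.append("control")
            elif pheno == "2":
                phenotypes.append("case")
            else:
                raise FormatError(
                    f"{ped_path}: line {lineno}: phenotype must be 1 or 2, got {pheno!r}"
                )
            alleles = fields[6:]
            for a in alleles:
                if a != "0" and a not in VALID_ALLELES:
                    raise FormatError(
                        f"{ped_path}: line {lineno}: invalid allele {a!r}"
                    )
            allele_rows.append(alleles)

    n_samples = len(sample_ids)
    dosage = np.full((n_snps, n_samples), np.nan)
    alleles_arr = np.array(allele_rows, dtype=object).reshape(n_samples, n_snps, 2)
    for j in range(n_snps):
        calls = alleles_arr[:, j, :]  # (samples, 2)
        flat = calls.ravel()
        counts: dict[str, int] = {}
        for a in flat:
            if a != "0":
                counts[a] = counts.get(a, 0) + 1
        if not counts:
            continue  # all missing; dosage stays NaN
        distinct = sorted(counts)
        if len(distinct) > 2:
            raise FormatError(f"SNP {snp_ids[j]}: more than two alleles {distinct}")
        if len(distinct) == 1:
            minor = distinct[0]
            dose = (calls == minor).sum(axis=1).astype(float)
            # monomorphic: everyone carries only this allele -> count it so
            # the QC monomorphic rule sees a constant column
            dose[:] = np.where((calls == "0").any(axis=1), np.nan, 0.0)
            dosage[j] = dose
            continue
        a1, a2 = distinct
        if counts[a1] == counts[a2]:
            minor = a1  # lexicographic tie-break, deterministic
            logger.info(
                "SNP %s: MAF tie at 0.5, minor allele set to %s", snp_ids[j], minor
            )
        else:
            minor = a1 if counts[a1] < counts[a2] else a2
        dose = (calls == minor).sum(axis=1).astype(float)
        dose[(calls == "0").any(axis=1)] = np.nan
        dosage[j] = dose

    return GenotypeStudy(
        snp_ids=snp_ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        dosage=dosage,
        sample_ids=sample_ids,
        phenotype=np.array(phenotypes, dtype=object),
    )


def write_plink_text(
    study: GenotypeStudy,
    ped_path: str | Path,
    map_path: str | Path,
    minor: str = "A",
    major: str = "G",
) -> None:
    """Write a study as PLINK text, coding dosage d as d copies of ``minor``.

    Missing dosage becomes the "0 0" call.  Reading the files back yields
    the same dosage matrix up to allele polarity: the reader re-derives
    the minor allele from the sample, so a SNP whose realized frequency
    exceeds 0.5 comes back with complementary dosage (2 - d).  The
    allelic chi-square is invariant to that choice.
    """
    with open(map_path, "w", newline="\n") as fh:
        for chrom, sid, pos in zip(study.chrom, study.snp_ids, study.pos):
            fh.write(f"{chrom}\t{sid}\t0\t{pos}\n")
    code = {0: f"{major} {major}", 1: f"{minor} {major}", 2: f"{minor} {minor}"}
    with open(ped_path, "w", newline="\n") as fh:
        for i, sid in enumerate(study.sample_ids):
            pheno = "2" if study.phenotype[i] == "case" else "1"
            calls = []
            for d in study.dosage[:, i]:
                calls.append("0 0" if np.isnan(d) else code[int(d)])
            fh.write(f"{sid} {sid} 0 0 0 {pheno} " + " ".join(calls) + "\n")


# ---------------------------------------------------------------------------
# BED gene models
# ---------------------------------------------------------------------------

def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read BED4+ gene models into a DataFrame (gene, chrom, start, end).

    On-disk intervals are 0-based half-open; in memory they become 1-based
    inclusive.  Strand (column 6) is ignored.  Zero-length intervals and
    duplicate gene ids are errors.
    """
    rows = []
    seen: set[str] = set()
    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise FormatError(
                    f"{path}: line {lineno}: BED4 requires chrom/start/end/name"
                )
            chrom, start_s, end_s, name = fields[:4]
            start, end = int(start_s), int(end_s)
            if end <= start:
                raise FormatError(
                    f"{path}: line {lineno}: empty or inverted interval "
                    f"[{start}, {end})"
                )
            if name in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate gene id {name!r}")
            seen.add(name)
            rows.append((name, chrom, start + 1, end))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Write 1-based inclusive gene models back to 0-based half-open BED4."""
    with open(path, "w", newline="\n") as fh:
        for row in genes.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene}\n")


# ---------------------------------------------------------------------------
# Expression matrix + phenotype
# ---------------------------------------------------------------------------

def read_expression(
    matrix_path: str | Path, phenotype_path: str | Path
) -> ExpressionStudy:
    """Read a genes-x-samples TSV and a sample->class phenotype TSV.

    Column order follows the matrix header; every sample must appear in the
    phenotype file.  Duplicate gene-id rows are preserved (collapsing
    probes to genes is a separate operation).
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{matrix_path}: non-numeric cell at gene "
                    f"{df.index[i]!r}, sample {col!r}: {raw!r}"
                ) from None
    pheno_df = pd.read_csv(
        phenotype_path, sep="\t", header=None, names=["sample", "class"], dtype=str,
        comment="#",
    )
    pheno_map = dict(zip(pheno_df["sample"], pheno_df["class"]))
    phenotype = []
    for s in df.columns:
        if s not in pheno_map:
            raise FormatError(f"{phenotype_path}: no phenotype for sample {s!r}")
        label = pheno_map[s]
        if label not in PHENOTYPE_LABELS:
            raise FormatError(
                f"{phenotype_path}: sample {s!r}: label must be case/control, "
                f"got {label!r}"
            )
        phenotype.append(label)
    return ExpressionStudy(
        gene_ids=list(df.index),
        values=values,
        sample_ids=list(df.columns),
        phenotype=np.array(phenotype, dtype=object),
    )


def write_expression(
    study: ExpressionStudy, matrix_path: str | Path, phenotype_path: str | Path
) -> None:
    df = pd.DataFrame(study.values, index=study.gene_ids, columns=study.sample_ids)
    df.index.name = "gene"
    df.to_csv(matrix_path, sep="\t", float_format="%.10g", lineterminator="\n")
    with open(phenotype_path, "w", newline="\n") as fh:
        for s, lab in zip(study.sample_ids, study.phenotype):
            fh.write(f"{s}\t{lab}\n")


# ---------------------------------------------------------------------------
# Results table
# ---------------------------------------------------------------------------

def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write an enrichment/combined results TSV, byte-deterministically.

    Rows are sorted by ascending P then set name; floats use %.6g; NaN is
    serialized as "NA".  Columns absent from ``results`` (e.g. ``nes`` for
    count-based methods) are emitted as NA to keep the column order fixed.
    """
    if "set" not in results.columns or "p" not in results.columns:
        raise ValueError("results must carry at least 'set' and 'p' columns")
    out = results.copy()
    for col in RESULTS_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[RESULTS_COLUMNS]
    out = out.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    out.to_csv(
        path, sep="\t", index=False, float_format="%.6g", na_rep="NA",
        lineterminator="\n",
    )


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
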