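import numpy as np
import pandas as pd
import pytest

from pathuniter import formats_io
from pathuniter.formats_io import (
    ExpressionStudy,
    FormatError,
    GeneSetCollection,
    GenotypeStudy,
    read_expression,
    read_gene_bed,
    read_gmt,
    read_plink_text,
    write_expression,
    write_gene_bed,
    write_gmt,
    write_plink_text,
    write_results_table,
)


class TestGmt:
    def test_duplicate_genes_within_line_are_deduplicated(self, tmp_path, caplog):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tdesc\tA\tB\tA\n")
        with caplog.at_level("WARNING"):
            coll = read_gmt(p)
        assert coll.sets["S1"] == ("A", "B")
        assert "duplicate gene" in caplog.text

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "e.gmt"
        p.write_text("")
        assert len(read_gmt(p)) == 0

    def test_duplicate_set_name_is_an_error(self, tmp_path):
        p = tmp_path / "d.gmt"
        p.write_text("S1\td\tA\tB\nS1\td\tC\tD\n")
        with pytest.raises(FormatError, match="duplicate set name"):
            read_gmt(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "m.gmt"
        p.write_text("S1\td\tA\nS2_only_two_fields\td\n")
        with pytest.raises(FormatError, match="line 2"):
            read_gmt(p)

    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(
            {"S1": ("A", "B"), "S2": ("C",)}, provenance={"S1": "x", "S2": "y"}
        )
        write_gmt(coll, tmp_path / "r.gmt")
        back = read_gmt(tmp_path / "r.gmt")
        assert back.sets == coll.sets
        assert back.provenance == coll.provenance

    def test_crlf_line_endings_are_accepted(self, tmp_path):
        p = tmp_path / "w.gmt"
        p.write_bytes(b"S1\td\tA\tB\r\nS2\td\tC\r\n")
        coll = read_gmt(p)
        assert coll.sets == {"S1": ("A", "B"), "S2": ("C",)}


class TestPlink:
    def _write(self, tmp_path, ped_lines, map_lines):
        ped = tmp_path / "s.ped"
        mp = tmp_path / "s.map"
        ped.write_text("\n".join(ped_lines) + "\n")
        mp.write_text("\n".join(map_lines) + "\n")
        return ped, mp

    def test_minor_allele_dosage_counting(self, tmp_path):
        # calls AA, AA, AG, GG: G is minor -> dosages 0, 0, 1, 2
        ped, mp = self._write(
            tmp_path,
            ["F1 I1 0 0 0 2 A A", "F2 I2 0 0 0 2 A A",
             "F3 I3 0 0 0 2 A G", "F4 I4 0 0 0 1 G G"],
            ["1 rs1 0 1000"],
        )
        study = read_plink_text(ped, mp)
        np.testing.assert_array_equal(study.dosage[0], [0.0, 0.0, 1.0, 2.0])
        assert list(study.phenotype) == ["case", "case", "case", "control"]

    def test_missing_call_gives_nan_dosage(self, tmp_path):
        ped, mp = self._write(
            tmp_path,
            ["F1 I1 0 0 0 2 0 0", "F2 I2 0 0 0 1 A G"],
            ["1 rs1 0 1000"],
        )
        study = read_plink_text(ped, mp)
        assert np.isnan(study.dosage[0, 0])

    def test_maf_tie_breaks_to_lexicographically_smaller_allele(self, tmp_path):
        # equal counts of A and G: A (smaller) is counted as minor
        ped, mp = self._write(
            tmp_path,
            ["F1 I1 0 0 0 2 A A", "F2 I2 0 0 0 1 G G"],
            ["1 rs1 0 1000"],
        )
        study = read_plink_text(ped, mp)
        np.testing.assert_array_equal(study.dosage[0], [2.0, 0.0])

    def test_invalid_allele_rejected(self, tmp_path):
        ped, mp = self._write(
            tmp_path,
            ["F1 I1 0 0 0 2 A N", "F2 I2 0 0 0 1 A A"],
            ["1 rs1 0 1000"],
        )
        with pytest.raises(FormatError, match="invalid allele"):
            read_plink_text(ped, mp)

    def test_ped_map_length_mismatch_rejected(self, tmp_path):
        ped, mp = self._write(
            tmp_path,
            ["F1 I1 0 0 0 2 A A A G", "F2 I2 0 0 0 1 A A A A"],
            ["1 rs1 0 1000"],
        )
        with pytest.raises(FormatError, match="expected"):
            read_plink_text(ped, mp)

    def test_round_trip_through_writer(self, small_study, tmp_path):
        study = small_study["genotypes"]
        write_plink_text(study, tmp_path / "s.ped", tmp_path / "s.map")
        back = read_plink_text(tmp_path / "s.ped", tmp_path / "s.map")
        assert back.snp_ids == study.snp_ids
        np.testing.assert_array_equal(back.pos, study.pos)
        # the reader re-derives the minor allele, so a SNP whose sample
        # frequency crossed 0.5 comes back with complementary dosage; the
        # allelic chi-square is invariant to that polarity
        for i in range(study.n_snps):
            same = np.allclose(back.dosage[i], study.dosage[i])
            flipped = np.allclose(back.dosage[i], 2 - study.dosage[i])
            assert same or flipped, i
        assert list(back.phenotype) == list(study.phenotype)


class TestBed:
    def test_bed_is_converted_to_one_based_inclusive(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t999\t2000\tG1\n")
        genes = read_gene_bed(p)
        row = genes.iloc[0]
        assert (row.gene, row.start, row.end) == ("G1", 1000, 2000)

    def test_zero_length_interval_rejected(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t100\t100\tG1\n")
        with pytest.raises(FormatError, match="interval"):
            read_gene_bed(p)

    def test_three_columns_rejected(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t100\t200\n")
        with pytest.raises(FormatError, match="BED4"):
            read_gene_bed(p)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t0\t10\tG1\nchr1\t20\t30\tG1\n")
        with pytest.raises(FormatError, match="duplicate gene id"):
            read_gene_bed(p)

    def test_round_trip(self, tmp_path):
        genes = pd.DataFrame(
            [("G1", "1", 1000, 2000), ("G2", "2", 5, 50)],
            columns=["gene", "chrom", "start", "end"],
        )
        write_gene_bed(genes, tmp_path / "g.bed")
        back = read_gene_bed(tmp_path / "g.bed")
        pd.testing.assert_frame_equal(back.astype({"chrom": str}), genes)


class TestExpression:
    def test_round_trip(self, tmp_path):
        study = ExpressionStudy(
            gene_ids=["G1", "G2"],
            values=np.array([[1.5, 2.5], [3.0, 4.0]]),
            sample_ids=["s1", "s2"],
            phenotype=np.array(["case", "control"], dtype=object),
        )
        write_expression(study, tmp_path / "m.tsv", tmp_path / "p.tsv")
        back = read_expression(tmp_path / "m.tsv", tmp_path / "p.tsv")
        assert back.gene_ids == study.gene_ids
        np.testing.assert_allclose(back.values, study.values)
        assert list(back.phenotype) == list(study.phenotype)

    def test_missing_phenotype_for_sample_is_an_error(self, tmp_path):
        (tmp_path / "m.tsv").write_text("gene\ts1\ts2\nG1\t1\t2\n")
        (tmp_path / "p.tsv").write_text("s1\tcase\n")
        with pytest.raises(FormatError, match="no phenotype"):
            read_expression(tmp_path / "m.tsv", tmp_path / "p.tsv")

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        (tmp_path / "m.tsv").write_text("gene\ts1\nG1\toops\n")
        (tmp_path / "p.tsv").write_text("s1\tcase\n")
        with pytest.raises(FormatError, match="G1.*s1"):
            read_expression(tmp_path / "m.tsv", tmp_path / "p.tsv")

    def test_duplicate_gene_rows_are_preserved(self, tmp_path):
        (tmp_path / "m.tsv").write_text("gene\ts1\ts2\nG1\t1\t2\nG1\t3\t4\n")
        (tmp_path / "p.tsv").write_text("s1\tcase\ns2\tcontrol\n")
        back = read_expression(tmp_path / "m.tsv", tmp_path / "p.tsv")
        assert back.gene_ids == ["G1", "G1"]


class TestResultsTable:
    def _results(self):
        return pd.DataFrame(
            {
                "set": ["B", "A", "C"],
                "size": [3, 2, 4],
                "score": [0.5, 0.5, 0.1],
                "nes": [1.1, np.nan, 0.9],
                "p": [0.02, 0.02, 0.5],
                "fdr": [0.06, 0.06, np.nan],
                "tier1": [False, False, False],
                "tier2": [True, True, False],
            }
        )

    def test_equal_p_rows_ordered_by_name_and_nan_is_na(self, tmp_path):
        out = tmp_path / "r.tsv"
        write_results_table(self._results(), out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == formats_io.RESULTS_COLUMNS
        assert [ln.split("\t")[0] for ln in lines[1:]] == ["A", "B", "C"]
        assert "NA" in lines[1]

    def test_byte_determinism(self, tmp_path):
        write_results_table(self._results(), tmp_path / "a.tsv")
        write_results_table(self._results(), tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_empty_results_give_header_only_file(self, tmp_path):
        empty = self._results().iloc[:0]
        write_results_table(empty, tmp_path / "e.tsv")
        lines = (tmp_path / "e.tsv").read_text().splitlines()
        assert len(lines) == 1


class TestTypes:
    def test_gene_set_invariants(self):
        with pytest.raises(ValueError, match="duplicate"):
            GeneSetCollection({"S": ("A", "A")})
        with pytest.raises(ValueError, match="empty"):
            GeneSetCollection({"S": ()})

    def test_genotype_study_requires_both_classes(self):
        with pytest.raises(ValueError, match="both"):
            GenotypeStudy(
                snp_ids=["rs1"], chrom=np.array(["1"]), pos=np.array([10]),
                dosage=np.zeros((1, 2)), sample_ids=["a", "b"],
                phenotype=np.array(["case", "case"], dtype=object),
            )
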