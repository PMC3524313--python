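import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pathuniter as pu
from pathuniter.formats_io import GeneSetCollection
from pathuniter.gene_mapping import SnpGeneMap
from pathuniter.gwas_enrichment import (
    PermutationPlan,
    _permuted_case_matrix,
    aligator,
    empirical_pvalue,
    enrichment_score,
    gsea_gwas,
    pairwise_r2,
    select_independent_snps,
    set_based_test,
    snp_ratio_test,
)


def brute_force_es(ranked_stats, membership, w):
    """Independent running-sum walk, written as the textbook loop."""
    s = list(ranked_stats)
    m = list(membership)
    n = len(s)
    n_hit = sum(m)
    weights = [abs(x) ** w if flag else 0.0 for x, flag in zip(s, m)]
    denom = sum(weights)
    if denom == 0:
        weights = [1.0 if flag else 0.0 for flag in m]
        denom = float(n_hit)
    run, best, cur = [], 0.0, 0.0
    for i in range(n):
        if m[i]:
            cur += weights[i] / denom
        else:
            cur -= 1.0 / (n - n_hit)
        run.append(cur)
        if abs(cur) > abs(best):
            best = cur
    return best


class TestEnrichmentScore:
    def test_all_members_gives_one_at_last_index(self):
        stats_ = np.array([5.0, 3.0, 1.0])
        es, peak, running = enrichment_score(stats_, np.ones(3, dtype=bool))
        assert es == pytest.approx(1.0)
        assert peak == 2

    def test_single_member_ranked_first_gives_one(self):
        stats_ = np.linspace(100, 1, 100)
        member = np.zeros(100, dtype=bool)
        member[0] = True
        es, peak, _ = enrichment_score(stats_, member, weight_exponent=0)
        assert es == pytest.approx(1.0)
        assert peak == 0

    def test_unweighted_top_half_matches_brute_force(self):
        stats_ = np.ones(10)
        member = np.array([True] * 5 + [False] * 5)
        es, _, _ = enrichment_score(stats_, member, weight_exponent=0)
        assert es == pytest.approx(brute_force_es(stats_, member, 0))

    @pytest.mark.parametrize("w", [0.0, 1.0, 2.0])
    def test_matches_brute_force_on_random_instances(self, w, rng):
        for _ in range(100):
            n = int(rng.integers(3, 50))
            stats_ = np.sort(rng.gamma(2.0, 2.0, size=n))[::-1]
            member = rng.random(n) < 0.3
            if not member.any():
                member[int(rng.integers(n))] = True
            es, _, _ = enrichment_score(stats_, member, w)
            assert es == pytest.approx(brute_force_es(stats_, member, w), abs=1e-12)

    def test_requires_a_member(self):
        with pytest.raises(ValueError, match="no members"):
            enrichment_score(np.array([2.0, 1.0]), np.zeros(2, dtype=bool))

    def test_requires_descending_order(self):
        with pytest.raises(ValueError, match="descending"):
            enrichment_score(np.array([1.0, 2.0]), np.array([True, False]))


class TestEmpiricalPvalue:
    def test_observed_beats_all(self):
        assert empirical_pvalue(10.0, np.zeros(999)) == pytest.approx(0.001)

    def test_observed_is_minimum(self):
        assert empirical_pvalue(-1.0, np.zeros(999)) == 1.0

    def test_single_permutation_tie(self):
        assert empirical_pvalue(1.0, np.array([1.0])) == 1.0


class TestSelectIndependentSnps:
    def test_greedy_hand_trace(self):
        # A(p=.001) picked; B pruned by r2 .8; C fails p cutoff
        d = np.array([
            [0, 1, 2, 1, 0, 2, 1, 0],
            [0, 1, 2, 1, 0, 2, 0, 0],   # highly correlated with A
            [2, 0, 1, 0, 2, 0, 1, 2],
        ], dtype=float)
        sel = select_independent_snps(
            ["A", "B", "C"], np.array([0.001, 0.002, 0.5]), d
        )
        assert sel == ["A"]

    def test_identical_dosage_always_pruned(self):
        d = np.tile([0.0, 1.0, 2.0, 1.0, 0.0, 2.0], (2, 1))
        sel = select_independent_snps(["A", "B"], np.array([0.01, 0.02]), d)
        assert sel == ["A"]

    def test_cap_at_max_snps(self, rng):
        d = rng.integers(0, 3, size=(7, 400)).astype(float)
        p = np.linspace(0.001, 0.04, 7)
        sel = select_independent_snps(
            [f"S{i}" for i in range(7)], p, d, max_snps=5
        )
        assert sel == [f"S{i}" for i in range(5)]

    def test_empty_selection_allowed(self):
        d = np.array([[0.0, 1.0, 2.0, 0.0]])
        assert select_independent_snps(["A"], np.array([0.9]), d) == []

    def test_r2_is_squared_pearson_of_dosages(self, rng):
        d = rng.integers(0, 3, size=(3, 100)).astype(float)
        r2 = pairwise_r2(d)
        expected = np.corrcoef(d) ** 2
        np.testing.assert_allclose(r2, expected, atol=1e-12)


def _toy_single_snp_genes(p_values):
    """n genes, one SNP each, with the given association P-values."""
    n = len(p_values)
    chi2 = stats.chi2.isf(np.clip(p_values, 1e-12, 1), df=1)
    assoc = pd.DataFrame({
        "snp": [f"rs{i}" for i in range(n)],
        "chr": "1", "pos": np.arange(1, n + 1) * 1000,
        "chi2": chi2, "p": p_values,
    })
    snp_map = SnpGeneMap(
        {f"G{i}": [f"rs{i}"] for i in range(n)},
        {f"rs{i}": [f"G{i}"] for i in range(n)},
    )
    return assoc, snp_map


class TestAligator:
    def test_matches_hypergeometric_tail_in_single_snp_regime(self):
        # 10 genes, 1 SNP each, 2 significant; set = the 2 significant
        # genes.  Replicates draw 2 of 10 SNPs, so P(score >= 2) is the
        # hypergeometric tail 1/C(10,2).
        p = np.array([0.01, 0.01] + [0.5] * 8)
        assoc, snp_map = _toy_single_snp_genes(p)
        sets = GeneSetCollection({"hit": ("G0", "G1"), "other": ("G5", "G6", "G7")})
        R = 2000
        res = aligator(assoc, snp_map, sets, 0.05,
                       PermutationPlan(n_perm=R, seed=5, scheme="snp-resample"))
        exact = 1 / 45
        se = np.sqrt(exact * (1 - exact) / R)
        p_hit = float(res.loc[res["set"] == "hit", "p"].iloc[0])
        assert abs(p_hit - exact) <= 3 * se + 1 / (R + 1)

    def test_no_significant_genes_means_all_p_one(self):
        p = np.full(6, 0.5)
        assoc, snp_map = _toy_single_snp_genes(p)
        sets = GeneSetCollection({"s": ("G0", "G1")})
        res = aligator(assoc, snp_map, sets, 0.05,
                       PermutationPlan(n_perm=50, seed=1, scheme="snp-resample"))
        assert (res["p"] == 1.0).all()

    def test_everything_significant_is_degenerate(self):
        # p_cut = 1 -> every gene significant -> every replicate matches
        p = np.linspace(0.01, 0.9, 8)
        assoc, snp_map = _toy_single_snp_genes(p)
        sets = GeneSetCollection({"s": ("G0", "G1", "G2")})
        res = aligator(assoc, snp_map, sets, 1.0,
                       PermutationPlan(n_perm=50, seed=1, scheme="snp-resample"))
        assert (res["p"] == 1.0).all()

    def test_set_without_significant_genes_has_p_near_one(self, small_study):
        res = aligator(small_study["assoc"], small_study["snp_map"],
                       small_study["sets"], 1e-12,
                       PermutationPlan(n_perm=50, seed=2, scheme="snp-resample"))
        assert (res["p"] == 1.0).all()


class TestSnpRatioTest:
    def test_observed_ratio_worked_example(self, small_study):
        # 3-SNP pathway with p-values (0.01, 0.2, 0.04) at cut 0.05 -> 2/3
        assoc = small_study["assoc"].copy()
        snp_ids = list(assoc["snp"].iloc[:3])
        assoc.loc[assoc["snp"].isin(snp_ids), "p"] = [0.01, 0.2, 0.04]
        gene = small_study["snp_map"].snp_to_genes[snp_ids[0]][0]
        sets = GeneSetCollection({"one_gene": (gene,)})
        res = snp_ratio_test(
            small_study["genotypes"], assoc, small_study["snp_map"], sets,
            0.05, PermutationPlan(n_perm=10, seed=1),
        )
        assert float(res["score"].iloc[0]) == pytest.approx(2 / 3)

    def test_raising_p_cut_never_decreases_ratio(self, small_study):
        prev = None
        for cut in (0.01, 0.05, 0.2, 0.5):
            res = snp_ratio_test(
                small_study["genotypes"], small_study["assoc"],
                small_study["snp_map"], small_study["sets"], cut,
                PermutationPlan(n_perm=5, seed=1),
            ).set_index("set")["score"]
            if prev is not None:
                assert (res >= prev - 1e-12).all()
            prev = res

    def test_no_significant_snps_gives_ratio_zero_p_one(self, small_study):
        res = snp_ratio_test(
            small_study["genotypes"], small_study["assoc"],
            small_study["snp_map"], small_study["sets"], 1e-15,
            PermutationPlan(n_perm=20, seed=1),
        )
        assert (res["score"] == 0.0).all()
        assert (res["p"] == 1.0).all()


class TestSetBasedTest:
    def test_single_snp_set_equals_direct_permutation_p(self, small_study):
        study = small_study["genotypes"]
        assoc = small_study["assoc"]
        # pick the strongest SNP so the selection is non-empty
        snp = assoc.sort_values("p")["snp"].iloc[0]
        gene = small_study["snp_map"].snp_to_genes[snp][0]
        snp_map = SnpGeneMap({gene: [snp]}, {snp: [gene]})
        sets = GeneSetCollection({"solo": (gene,)})
        B, seed = 199, 11
        res = set_based_test(study, assoc, snp_map, sets, 0.5, 0.05, 5,
                             PermutationPlan(n_perm=B, seed=seed))
        # oracle: permute labels with the same generator, recompute the
        # 2x2 allele-table chi-square with scipy, and count exceedances
        rng = np.random.default_rng(seed)
        labels = _permuted_case_matrix(study.is_case, B, rng)
        i = study.snp_ids.index(snp)
        dosage = study.dosage[i]
        obs = float(assoc.set_index("snp").loc[snp, "chi2"])
        thr = stats.chi2.isf(0.05, df=1)
        count = 0
        for b in range(B):
            is_case = labels[:, b]
            a_case, n_case = dosage[is_case].sum(), 2 * is_case.sum()
            a_ctrl, n_ctrl = dosage[~is_case].sum(), 2 * (~is_case).sum()
            table = np.array([[a_case, n_case - a_case],
                              [a_ctrl, n_ctrl - a_ctrl]])
            chi2 = stats.chi2_contingency(table, correction=False)[0]
            count += (chi2 if chi2 > thr else 0.0) >= obs
        expected = (1 + count) / (B + 1)
        assert float(res["p"].iloc[0]) == pytest.approx(expected, abs=1e-12)

    def test_empty_selection_scores_zero_with_p_one(self, small_study):
        res = set_based_test(
            small_study["genotypes"], small_study["assoc"],
            small_study["snp_map"], small_study["sets"], 0.5, 1e-15, 5,
            PermutationPlan(n_perm=20, seed=3),
        )
        assert (res["score"] == 0.0).all()
        assert (res["p"] == 1.0).all()


class TestGseaGwas:
    def test_single_permutation_p_is_half_or_one(self, small_study):
        res = gsea_gwas(
            small_study["genotypes"], small_study["assoc"],
            small_study["snp_map"], small_study["sets"],
            PermutationPlan(n_perm=1, seed=9),
        )
        assert set(np.round(res["p"], 6)) <= {0.5, 1.0}

    def test_planted_pathway_is_recovered(self, small_study):
        res = gsea_gwas(
            small_study["genotypes"], small_study["assoc"],
            small_study["snp_map"], small_study["sets"],
            PermutationPlan(n_perm=200, seed=4),
        )
        planted = small_study["truth"].planted_sets[0]
        assert float(res.loc[res["set"] == planted, "p"].iloc[0]) <= 0.05

    def test_es_within_bounds_and_p_in_range(self, small_study):
        res = gsea_gwas(
            small_study["genotypes"], small_study["assoc"],
            small_study["snp_map"], small_study["sets"],
            PermutationPlan(n_perm=50, seed=2),
        )
        assert res["score"].between(-1, 1).all()
        assert res["p"].between(1 / 51, 1).all()


class TestDeterminism:
    @pytest.mark.parametrize("method", ["gsea", "aligator", "srt", "setbased"])
    def test_identical_seed_gives_identical_tables(self, small_study, method, tmp_path):
        from pathuniter.formats_io import write_results_table

        def run(seed):
            plan = PermutationPlan(
                n_perm=30, seed=seed,
                scheme="snp-resample" if method == "aligator" else "phenotype-swap",
            )
            if method == "gsea":
                return gsea_gwas(small_study["genotypes"], small_study["assoc"],
                                 small_study["snp_map"], small_study["sets"], plan)
            if method == "aligator":
                return aligator(small_study["assoc"], small_study["snp_map"],
                                small_study["sets"], 0.05, plan)
            if method == "srt":
                return snp_ratio_test(small_study["genotypes"], small_study["assoc"],
                                      small_study["snp_map"], small_study["sets"],
                                      0.05, plan)
            return set_based_test(small_study["genotypes"], small_study["assoc"],
                                  small_study["snp_map"], small_study["sets"],
                                  0.5, 0.05, 5, plan)

        a, b = run(7), run(7)
        write_results_table(a, tmp_path / "a.tsv")
        write_results_table(b, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
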