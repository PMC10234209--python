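import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from invpayne import (
    ExpressionEffect, GeneModel, cpm_tmm, low_expression_filter,
    rank_genes_by_fst, rrho, overlap_set_test, region_enrichment_fet,
    synth_expression_design,
)


class TestCpmTmm:
    def counts(self, cols):
        return pd.DataFrame(cols, index=[f"g{i}" for i in
                                         range(len(next(iter(cols.values()))))])

    def test_identical_libraries_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 500, 200)
        expr = cpm_tmm(self.counts({"a": col, "b": col, "c": col}))
        assert np.allclose(expr.tmm_factors, 1.0)

    def test_global_scaling_normalised_away(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 500, 200)
        expr = cpm_tmm(self.counts({"a": col, "b": 2 * col}))
        assert np.allclose(expr.cpm["a"], expr.cpm["b"], rtol=1e-6)
        assert expr.tmm_factors[expr.reference_sample] == 1.0

    def test_cpm_units(self):
        counts = self.counts({"a": np.full(5000, 200),
                              "b": np.full(5000, 200)})
        expr = cpm_tmm(counts)
        assert expr.lib_sizes["a"] == 10**6
        assert np.allclose(expr.cpm["a"], 200.0)

    def test_zero_counts_stay_zero(self):
        rng = np.random.default_rng(2)
        c = rng.integers(0, 50, (100, 3))
        c[0] = 0
        counts = pd.DataFrame(c, columns=list("abc"))
        expr = cpm_tmm(counts)
        assert (expr.cpm.iloc[0] == 0).all()

    def test_all_zero_library_rejected(self):
        counts = self.counts({"a": np.array([1, 2]), "b": np.array([0, 0])})
        with pytest.raises(ValueError, match="all-zero"):
            cpm_tmm(counts)


class TestLowExpressionFilter:
    def make_expr(self, n_low_samples):
        # gene "low" sits at exactly 2 CPM in n_low_samples libraries
        n_genes, n_samples = 1000, 54
        counts = pd.DataFrame(
            np.full((n_genes, n_samples), 1000),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n_samples)])
        lib = counts.sum(axis=0).iloc[0]
        low_val = int(2 * lib / 1e6)
        counts.iloc[0, :n_low_samples] = low_val
        return cpm_tmm(counts)

    def test_rule_as_printed(self):
        removed = self.make_expr(9)
        assert "g0" not in low_expression_filter(removed)
        kept = self.make_expr(8)
        assert "g0" in low_expression_filter(kept)

    def test_all_high_identity(self):
        expr = self.make_expr(0)
        assert len(low_expression_filter(expr)) == 1000

    def test_conventional_dialect(self):
        expr = self.make_expr(8)
        kept = low_expression_filter(expr, keep_mode=True)
        assert "g0" in kept  # > 2 CPM in 46 >= 9 samples


class TestGeneRanking:
    def test_single_snp_and_top_decile_mean(self):
        genes = [GeneModel("a", "3R", 10_000, 12_000),
                 GeneModel("b", "3R", 50_000, 52_000)]
        pos = np.array([11_000] + [51_000 + i for i in range(10)])
        vals = np.array([0.5] + [1.0] + [0.0] * 9)
        theta = pd.Series(vals, index=pos)
        ranked = rank_genes_by_fst(theta, genes)
        scores = ranked.set_index("gene_id")["score"]
        assert scores["a"] == pytest.approx(0.5)
        assert scores["b"] == pytest.approx(1.0)  # top 10% of ten SNPs

    def test_tie_breaks_by_gene_id(self):
        genes = [GeneModel(g, "3R", 10_000, 12_000) for g in ("zz", "aa")]
        theta = pd.Series([0.7], index=np.array([11_000]))
        ranked = rank_genes_by_fst(theta, genes)
        assert list(ranked["gene_id"]) == ["aa", "zz"]

    def test_genes_without_snps_excluded(self):
        genes = [GeneModel("far", "3R", 900_000, 902_000)]
        theta = pd.Series([0.7], index=np.array([11_000]))
        assert len(rank_genes_by_fst(theta, genes)) == 0


class TestRRHO:
    def test_identical_rankings_diagonal(self):
        universe = [f"g{i}" for i in range(100)]
        grid = rrho(universe, universe, step=10)
        i10 = 0  # first threshold = 10
        assert grid.overlap[i10, i10] == 10
        assert grid.neg_log_p[i10, i10] == pytest.approx(
            -math.log10(1 / math.comb(100, 10)))
        # bottom-right cell contains everything: p = 1
        assert grid.neg_log_p[-1, -1] == pytest.approx(0.0)
        assert grid.optimal_genes <= set(universe)

    def test_cells_match_fisher_exact_upper_tail(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(60)]
        other = list(rng.permutation(universe))
        grid = rrho(universe, other, step=1)
        th = grid.thresholds
        for _ in range(50):
            a, b = rng.integers(0, len(th), size=2)
            i, j, k = th[a], th[b], grid.overlap[a, b]
            table = [[k, i - k], [j - k, 60 - i - j + k]]
            _, p = stats.fisher_exact(table, alternative="greater")
            assert 10 ** (-grid.neg_log_p[a, b]) == pytest.approx(p)

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError, match="universes"):
            rrho(["a", "b"], ["a", "c"])

    def test_independent_rankings_stay_below_bonferroni(self):
        universe = [f"g{i}" for i in range(200)]
        m = math.ceil(200 / 10)
        bound = -math.log10(0.05 / m**2)
        exceed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            other = list(rng.permutation(universe))
            grid = rrho(universe, other, step=10)
            exceed += grid.neg_log_p.max() > bound
        assert exceed <= 2


class TestOverlapAndRegionTests:
    def test_disjoint_sets_large_background(self):
        bg = set(range(1000))
        res = overlap_set_test([set(range(10)), set(range(10, 20))], bg)
        assert res.observed == 0
        assert res.p == pytest.approx(1.0)

    def test_sets_equal_background(self):
        bg = set(range(30))
        res = overlap_set_test([bg, bg], bg)
        assert res.observed == 30 and res.p == pytest.approx(1.0)

    def test_region_enrichment_detects_concentration(self):
        genes = [GeneModel(f"g{i}", "3R", i * 10_000, i * 10_000 + 2000)
                 for i in range(1, 101)]
        inside = {g.gene_id for g in genes if g.start < 200_000}
        res = region_enrichment_fet(inside, genes, (1, 200_000))
        assert res["p"] < 1e-6
        null = region_enrichment_fet({"g1", "g50", "g99"}, genes,
                                     (1, 500_000))
        assert null["p"] > 0.05

    def test_region_null_type_one_error(self):
        genes = [GeneModel(f"g{i}", "3R", i * 10_000, i * 10_000 + 2000)
                 for i in range(1, 101)]
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            pick = set(rng.choice([g.gene_id for g in genes], 20,
                                  replace=False).tolist())
            hits += region_enrichment_fet(pick, genes,
                                          (1, 300_000))["p"] < 0.05
        assert hits / 200 == pytest.approx(0.05, abs=0.035)

    def test_empty_set_rejected(self):
        genes = [GeneModel("g", "3R", 1, 10)]
        with pytest.raises(ValueError, match="empty"):
            region_enrichment_fet(set(), genes, (1, 5))


class TestExpressionRecovery:
    def test_interaction_only_genes_recovered_at_cold_temperature(self):
        planted = [ExpressionEffect(f"g{i:05d}", interaction_lfc=2.0)
                   for i in range(20)]
        counts, design, gene_table = synth_expression_design(
            400, planted, seed=7)
        expr = cpm_tmm(counts)
        log_cpm = np.log2(expr.cpm + 0.5)

        def contrast(temp):
            fi = design[(design.group == "FI")
                        & (design.temperature == temp)]["sample_id"]
            fs = design[(design.group == "FS")
                        & (design.temperature == temp)]["sample_id"]
            return (log_cpm[fi].mean(axis=1) - log_cpm[fs].mean(axis=1))

        score = contrast(18).abs() - contrast(25).abs()
        top = set(score.sort_values(ascending=False).index[:20])
        recovered = len(top & {e.gene_id for e in planted}) / 20
        assert recovered >= 0.9

    def test_null_design_rrho_stays_null(self):
        # no effects anywhere: genomic and transcriptomic rankings are
        # independent noise, so RRHO finds nothing beyond Bonferroni
        exceed = 0
        for seed in range(10):
            counts, design, _ = synth_expression_design(200, seed=100 + seed)
            expr = cpm_tmm(counts)
            log_cpm = np.log2(expr.cpm + 0.5)
            fi = design[design.group == "FI"]["sample_id"]
            fs = design[design.group == "FS"]["sample_id"]
            de_rank = (log_cpm[fi].mean(axis=1)
                       - log_cpm[fs].mean(axis=1)).abs()
            list_a = list(de_rank.sort_values(ascending=False).index)
            rng = np.random.default_rng(seed)
            list_b = list(rng.permutation(list_a))
            grid = rrho(list_a, list_b, step=10)
            m = math.ceil(200 / 10)
            exceed += grid.neg_log_p.max() > -math.log10(0.05 / m**2)
        assert exceed <= 1
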