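import itertools

import numpy as np
import pandas as pd
import pytest

from invpayne import (
    HaplotypeMatrix, SampleInfo, wc_fst_site, wc_fst_components, fst_series,
    build_comparison_plans, windowed_fst, windowed_theta, kst_region,
    inverted_cross_continent_fst, fst_anova_tukey,
    merge_populations, MISSING,
)

from conftest import karyotype_ids


def brute_force_theta(counts, sizes):
    """Independent variance-components arithmetic (plain Python loops)."""
    r = len(sizes)
    ps = [c / n for c, n in zip(counts, sizes)]
    n_tot = sum(sizes)
    p_bar = sum(c for c in counts) / n_tot
    msp = sum(n * (p - p_bar) ** 2 for n, p in zip(sizes, ps)) / (r - 1)
    msg = sum(n * p * (1 - p) for n, p in zip(sizes, ps)) / sum(
        n - 1 for n in sizes)
    nc = (n_tot - sum(n * n for n in sizes) / n_tot) / (r - 1)
    denom = msp + (nc - 1) * msg
    return float("nan") if denom == 0 else (msp - msg) / denom


class TestWcFst:
    @pytest.mark.parametrize("c1,c2,expected", [
        ((10, 10), (0, 10), 1.0),              # fixed difference
        ((5, 10), (5, 10), -1 / 9),            # identical intermediate
        ((9, 10), (1, 10), 3.1 / 4.1)])        # strong differentiation
    def test_component_arithmetic_examples(self, c1, c2, expected):
        assert wc_fst_site(c1, c2).theta == pytest.approx(expected)

    def test_undefined_when_jointly_monomorphic(self):
        assert np.isnan(wc_fst_site((0, 10), (0, 10)).theta)

    def test_brute_force_oracle_random_sites(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sizes = rng.integers(2, 30, size=int(rng.integers(2, 4)))
            counts = [int(rng.integers(0, n + 1)) for n in sizes]
            got = wc_fst_components(np.array(counts, float),
                                    sizes.astype(float))[3]
            want = brute_force_theta(counts, list(map(int, sizes)))
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want)

    def test_population_order_symmetry(self):
        a = wc_fst_site((7, 12), (3, 18)).theta
        b = wc_fst_site((3, 18), (7, 12)).theta
        assert a == pytest.approx(b)

    def test_series_matches_per_site_calls(self):
        rng = np.random.default_rng(5)
        alleles = rng.integers(0, 2, size=(12, 40)).astype(np.int8)
        alleles[rng.random(alleles.shape) < 0.1] = MISSING
        m = HaplotypeMatrix([f"s{i}" for i in range(12)], "3R",
                            np.arange(1, 41), alleles)
        a_ids, b_ids = m.sample_ids[:6], m.sample_ids[6:]
        series = fst_series(m, a_ids, b_ids)
        for j in range(40):
            a = m.alleles[:6, j]
            b = m.alleles[6:, j]
            ca = ((a == 1).sum(), (a != MISSING).sum())
            cb = ((b == 1).sum(), (b != MISSING).sum())
            if ca[1] >= 2 and cb[1] >= 2:
                want = wc_fst_site(ca, cb).theta
                got = series.iloc[j]
                assert (np.isnan(want) and np.isnan(got)) or \
                    got == pytest.approx(want)
            else:
                assert np.isnan(series.iloc[j])


class TestComparisonPlans:
    def make_info(self, with_high=True):
        rows = []
        for i in range(6):
            rows.append((f"FI{i}", "Florida", "NorthAmerica", "INV", "low"))
            rows.append((f"FS{i}", "Florida", "NorthAmerica", "STD", "low"))
            if with_high:
                rows.append((f"MS{i}", "Maine", "NorthAmerica", "STD", "high"))
        rows.append(("H1", "Florida", "NorthAmerica", "HET", "low"))
        return SampleInfo(pd.DataFrame(
            rows, columns=["sample_id", "population", "continent",
                           "karyotype", "latitude_class"]))

    def test_three_plans_for_complete_design(self):
        plans = build_comparison_plans(self.make_info(), seed=1)
        assert sorted(p.label for p in plans) == ["G", "G+K", "K"]
        for p in plans:
            assert not set(p.ids_a) & set(p.ids_b)
            assert "H1" not in p.ids_a + p.ids_b  # HET never enters

    def test_missing_high_latitude_gives_only_karyotype_plan(self):
        plans = build_comparison_plans(self.make_info(with_high=False), seed=1)
        assert [p.label for p in plans] == ["K"]

    def test_equal_karyotype_pools(self):
        info = self.make_info()
        info.table = pd.concat([info.table, pd.DataFrame(
            [(f"FIx{i}", "Florida", "NorthAmerica", "INV", "low")
             for i in range(4)],
            columns=info.table.columns)], ignore_index=True)
        plans = build_comparison_plans(SampleInfo(info.table), seed=1)
        k = next(p for p in plans if p.label == "K")
        assert len(k.ids_a) == len(k.ids_b)


class TestWindowedFst:
    def test_fixed_difference_window_and_empty_window(self):
        theta = pd.Series([1.0], index=np.array([150_000]))
        w = windowed_theta(theta, "3R", span=(1, 300_000))
        assert np.isnan(w["value"].iloc[0])
        assert w["value"].iloc[1] == pytest.approx(1.0)
        assert np.isnan(w["value"].iloc[2])

    def test_negative_estimates_retained_in_mean(self):
        theta = pd.Series([-1 / 9, 1 / 3], index=np.array([10, 20]))
        w = windowed_theta(theta, "3R", span=(1, 100_000))
        assert w["value"].iloc[0] == pytest.approx((1 / 3 - 1 / 9) / 2)


class TestKst:
    def haplos(self, rows):
        rows = np.asarray(rows, dtype=np.int8)
        return HaplotypeMatrix([f"s{i}" for i in range(rows.shape[0])], "3R",
                               np.arange(1, rows.shape[1] + 1), rows)

    def test_identical_groups_near_zero(self):
        m = self.haplos([[0, 1, 0], [1, 0, 1]] * 4)
        res = kst_region(m, [f"s{i}" for i in range(4)],
                         [f"s{i}" for i in range(4, 8)],
                         n_perm=200, seed=1)
        assert abs(res["KST"]) < 0.25
        assert res["p"] > 0.2

    def test_private_fixed_differences_detected(self):
        m = self.haplos([[1, 1, 0, 0]] * 4 + [[0, 0, 1, 1]] * 4)
        res = kst_region(m, [f"s{i}" for i in range(4)],
                         [f"s{i}" for i in range(4, 8)],
                         n_perm=1000, seed=1)
        assert res["KST"] > 0
        assert res["p"] <= 0.03  # permutation floor for 4+4 labels

    def test_toy_value_matches_brute_force(self):
        rng = np.random.default_rng(9)
        rows = rng.integers(0, 2, size=(8, 12)).astype(np.int8)
        m = self.haplos(rows)
        ids_a = [f"s{i}" for i in range(4)]
        ids_b = [f"s{i}" for i in range(4, 8)]
        res = kst_region(m, ids_a, ids_b, n_perm=10, seed=1)
        # brute force with explicit pair loops
        def mean_pairs(idx):
            ds = [np.sum(rows[i] != rows[j])
                  for i, j in itertools.combinations(idx, 2)]
            return np.mean(ds)
        k1, k2 = mean_pairs(range(4)), mean_pairs(range(4, 8))
        kt = mean_pairs(range(8))
        ks = (4 * k1 + 4 * k2) / 8
        assert res["KST"] == pytest.approx(1 - ks / kt)


class TestCrossContinent:
    def test_duplicated_population_gives_near_zero_theta(self, lowflux_pops):
        pop = lowflux_pops[2]
        inv_ids = karyotype_ids(pop, "INV")
        m = pop.haplotypes.take_samples(inv_ids)
        half_a = m.take_samples(m.sample_ids[:25])
        half_b = m.take_samples(m.sample_ids[25:50])
        out = inverted_cross_continent_fst({"A": half_a, "B": half_b},
                                           span=(1, 1_000_000))
        assert abs(out["value"].dropna().mean()) < 0.05

    def test_shared_snp_restriction(self):
        a = HaplotypeMatrix(["a1", "a2", "a3"], "3R", np.array([10, 20, 30]),
                            np.array([[0, 1, 0], [1, 0, 1], [0, 1, 1]],
                                     dtype=np.int8))
        b = HaplotypeMatrix(["b1", "b2", "b3"], "3R", np.array([20, 30, 40]),
                            np.array([[0, 1, 1], [1, 0, 0], [0, 1, 0]],
                                     dtype=np.int8))
        out = inverted_cross_continent_fst({"A": a, "B": b}, window=100)
        assert out["n_snps"].sum() <= 2  # only positions 20 and 30 shared


class TestOnStructuredSimulations:
    def test_karyotype_contrast_exceeds_geography_inside_inversion(
            self, structured_reps):
        # a recent population split leaves little geographic signal, while
        # the old karyotype classes stay strongly diverged inside
        from conftest import BP
        wins = 0
        for s, (src, low_a, low_b, high) in enumerate(structured_reps):
            mat, info = merge_populations(
                {"low": low_a, "high": high},
                meta={"low": {"continent": "NA", "latitude_class": "low"},
                      "high": {"continent": "NA", "latitude_class": "high"}})
            plans = build_comparison_plans(info, seed=s)
            w = windowed_fst(plans, mat, span=(1, 1_000_000))
            inside = w[(w["start"] >= BP[0]) & (w["end"] <= BP[1])]
            mk = inside[inside["plan"] == "K"]["value"].mean()
            mg = inside[inside["plan"] == "G"]["value"].mean()
            wins += mk > mg
        assert wins >= 15

    def test_shared_inversion_origin_lowers_inv_inv_divergence(
            self, structured_reps):
        from conftest import BP
        wins = 0
        for s, (src, low_a, low_b, high) in enumerate(structured_reps):
            mat, info = merge_populations({"A": low_a, "B": low_b})
            ids = lambda pop, lbl, k: karyotype_ids(pop, k, prefix=lbl)
            th_ii = fst_series(mat, ids(low_a, "A", "INV"),
                               ids(low_b, "B", "INV"))
            th_is = fst_series(mat, ids(low_a, "A", "INV"),
                               ids(low_b, "B", "STD"))
            pos = th_ii.index.to_numpy()
            inside = (pos >= BP[0]) & (pos <= BP[1])
            wins += (np.nanmean(th_ii[inside]) < np.nanmean(th_is[inside]))
        assert wins >= 15


class TestAnovaTukey:
    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_seeds = 200
        for _ in range(n_seeds):
            w = pd.DataFrame({
                "value": rng.normal(0.1, 0.05, 60),
                "plan": ["K"] * 20 + ["G"] * 20 + ["G+K"] * 20})
            rejections += fst_anova_tukey(w)["p"] < 0.05
        assert rejections / n_seeds == pytest.approx(0.05, abs=0.02)

    def test_shifted_label_flagged_by_tukey(self):
        rng = np.random.default_rng(12)
        w = pd.DataFrame({
            "value": np.concatenate([rng.normal(0.1, 0.05, 20),
                                     rng.normal(0.1, 0.05, 20),
                                     rng.normal(0.4, 0.05, 20)]),
            "plan": ["K"] * 20 + ["G"] * 20 + ["G+K"] * 20})
        res = fst_anova_tukey(w)
        assert res["p"] < 1e-6
        tk = res["tukey"]
        gk_rows = tk[(tk["group1"] == "G+K") | (tk["group2"] == "G+K")]
        assert gk_rows["reject"].all()

    def test_single_window_per_label_rejected(self):
        w = pd.DataFrame({"value": [0.1, 0.2], "plan": ["K", "G"]})
        with pytest.raises(ValueError, match="two windows"):
            fst_anova_tukey(w)
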