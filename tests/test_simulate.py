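import numpy as np
import pytest

from invpayne import (
    SimParams, simulate_inversion_population, simulate_derived_population,
    synth_hemiclone_counts, synth_pool_counts, synth_expression_design,
    HaplotypeMatrix, site_pi_series,
)
from invpayne.differentiation import fst_series

from conftest import karyotype_ids


def small_params(**overrides):
    kw = dict(N=30, q=0.5, L=500, chrom_length=100_000,
              breakpoints=(25_000, 75_000), mu=4e-5, r_rate=0.0,
              phi_bp=0.0, phi_center=0.0, s_bal=0.0, clamp=True,
              T=300, seed=1)
    kw.update(overrides)
    return SimParams(**kw)


class TestSimParams:
    @pytest.mark.parametrize("bad", [dict(q=0.0), dict(q=1.2),
                                     dict(mu=-1e-5), dict(T=0),
                                     dict(breakpoints=(0, 50_000)),
                                     dict(breakpoints=(80_000, 20_000))])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            small_params(**bad)

    def test_phi_profile_is_piecewise_by_breakpoint_distance(self):
        p = small_params(phi_bp=1e-6, phi_center=1e-4, phi_flank=5000)
        pos = np.array([25_000, 29_000, 31_000, 50_000, 69_000, 74_000])
        phi = p.phi_profile(pos)
        assert list(phi) == [1e-6, 1e-6, 1e-4, 1e-4, 1e-4, 1e-6]


class TestEngine:
    def test_determinism_bit_identical(self):
        a = simulate_inversion_population(small_params(seed=9))
        b = simulate_inversion_population(small_params(seed=9))
        assert (a.haplotypes.alleles == b.haplotypes.alleles).all()
        assert (a.haplotypes.positions == b.haplotypes.positions).all()
        assert (a.karyotypes == b.karyotypes).all()

    def test_population_invariants(self):
        pop = simulate_inversion_population(small_params(seed=3))
        assert np.all(np.diff(pop.haplotypes.positions) > 0)
        assert set(pop.karyotypes) == {"INV", "STD"}
        # clamp holds the inversion frequency at the target
        assert pop.inversion_frequency == pytest.approx(0.5, abs=0.01)
        assert not pop.provenance["inversion_lost"]

    def test_drift_loss_is_flagged_not_silent(self):
        # tiny population, no clamp, no selection: loss is near-certain
        p = small_params(N=5, clamp=False, T=500, seed=2)
        pop = simulate_inversion_population(p)
        q = pop.inversion_frequency
        assert (q in (0.0, 1.0)) == pop.provenance["inversion_lost"]
        assert pop.provenance["inversion_lost"]

    def test_no_exchange_creates_fixed_differences_with_fat_one(self):
        # phi = 0 and r = 0: classes accumulate private variation; sites
        # fixed within one class and absent in the other have F_AT exactly 1
        pop = simulate_inversion_population(small_params(T=800, seed=4))
        m = pop.haplotypes
        inv = m.take_samples(karyotype_ids(pop, "INV")).alleles
        std = m.take_samples(karyotype_ids(pop, "STD")).alleles
        f_inv, f_std = inv.mean(axis=0), std.mean(axis=0)
        fixed_diff = ((f_inv == 1) & (f_std == 0)) | ((f_inv == 0) & (f_std == 1))
        assert fixed_diff.sum() > 0
        theta = fst_series(m, karyotype_ids(pop, "INV"),
                           karyotype_ids(pop, "STD"))
        assert np.allclose(theta.to_numpy()[fixed_diff], 1.0)

    def test_neutral_run_has_no_inversion_machinery(self):
        pop = simulate_inversion_population(
            SimParams(N=40, q=None, breakpoints=None, L=400,
                      chrom_length=100_000, mu=5e-5, r_rate=0.0,
                      clamp=False, T=400, seed=5))
        assert set(pop.karyotypes) == {"STD"}
        assert pop.haplotypes.n_sites > 0


class TestDerivedPopulation:
    def test_identity_when_all_founders_no_generations(self):
        src = simulate_inversion_population(small_params(T=400, seed=6))
        der = simulate_derived_population(src, len(src.karyotypes), 0, seed=1)
        pi_src = site_pi_series(src.haplotypes).sum()
        pi_der = site_pi_series(der.haplotypes).sum()
        assert pi_der == pytest.approx(pi_src)

    def test_source_population_unchanged(self):
        src = simulate_inversion_population(small_params(T=200, seed=6))
        before = src.haplotypes.alleles.copy()
        simulate_derived_population(src, 20, 50, seed=1, recovery_size=60)
        assert (src.haplotypes.alleles == before).all()

    def test_bottleneck_reduces_diversity(self):
        # classic founder-effect expectation, as a strict inequality of
        # means over 20 replicate derivations
        src = simulate_inversion_population(small_params(T=800, seed=8))
        pi_src = site_pi_series(src.haplotypes).sum()
        pi_der = []
        for s in range(20):
            der = simulate_derived_population(src, 20, 200, seed=s,
                                              recovery_size=60)
            pi_der.append(site_pi_series(der.haplotypes).sum())
        assert np.mean(pi_der) < pi_src

    def test_all_standard_founders_lose_inversion(self):
        src = simulate_inversion_population(small_params(T=200, seed=6))
        der = simulate_derived_population(src, 20, 50, seed=2,
                                          recovery_size=60,
                                          founder_karyotype="STD")
        assert der.inversion_frequency == 0.0

    def test_missing_karyotype_in_source_errors(self):
        src = simulate_inversion_population(
            SimParams(N=30, q=None, breakpoints=None, L=200,
                      chrom_length=100_000, mu=2e-5, r_rate=0.0,
                      clamp=False, T=100, seed=1))
        with pytest.raises(ValueError, match="absent"):
            simulate_derived_population(src, 10, 10, seed=1,
                                        founder_karyotype="INV")
        with pytest.raises(ValueError, match="both karyotypes"):
            simulate_derived_population(src, 10, 10, seed=1,
                                        require_both_karyotypes=True)


class TestHemicloneCounts:
    @pytest.fixture
    def maternal(self):
        rng = np.random.default_rng(0)
        return HaplotypeMatrix(
            [f"f{i}" for i in range(4)], "3R",
            np.arange(1, 21) * 100,
            rng.integers(0, 2, size=(4, 20)).astype(np.int8))

    def test_even_depth_no_error_splits_reads_half_half(self, maternal):
        # maternal always 0, sire always 1: every site heterozygous
        mat = HaplotypeMatrix(maternal.sample_ids, "3R", maternal.positions,
                              np.zeros_like(maternal.alleles))
        counts = synth_hemiclone_counts(mat, np.ones(20), error_rate=0.0,
                                        seed=1, fixed_depth=30)
        # maternal allele (ref base) count is Binomial(30, .5); total = 30
        totals = counts[["A", "C", "G", "T"]].sum(axis=1)
        assert (totals == 30).all()
        for _, row in counts.iterrows():
            assert row[["A", "C", "G", "T"]].max() < 30  # both alleles seen

    def test_monoallelic_when_maternal_equals_sire(self, maternal):
        mat = HaplotypeMatrix(maternal.sample_ids, "3R", maternal.positions,
                              np.zeros_like(maternal.alleles))
        counts = synth_hemiclone_counts(mat, np.zeros(20), error_rate=0.0,
                                        seed=1, fixed_depth=20)
        nonzero = (counts[["A", "C", "G", "T"]] > 0).sum(axis=1)
        assert (nonzero == 1).all()

    def test_deterministic_under_seed(self, maternal):
        a = synth_hemiclone_counts(maternal, np.full(20, 0.5), seed=3)
        b = synth_hemiclone_counts(maternal, np.full(20, 0.5), seed=3)
        assert a.equals(b)

    def test_pool_counts_monomorphic_at_freq_extremes(self, maternal):
        pool = synth_pool_counts(maternal, np.zeros(20), depth=100, seed=1)
        assert ((pool[["A", "C", "G", "T"]] > 0).sum(axis=1) == 1).all()


class TestExpressionDesign:
    def test_full_factorial_54_samples(self):
        counts, design, gene_table = synth_expression_design(50, seed=1)
        assert len(design) == 54
        assert counts.shape == (50, 54)
        cells = design.groupby(["group", "temperature"]).size()
        assert (cells == 9).all() and len(cells) == 6
        assert set(design["group"]) == {"FI", "FS", "MS"}
        assert gene_table["inside_inversion"].dtype == bool

    def test_deterministic_under_seed(self):
        a, _, _ = synth_expression_design(30, seed=5)
        b, _, _ = synth_expression_design(30, seed=5)
        assert a.equals(b)

    def test_unknown_effect_gene_rejected(self):
        from invpayne import ExpressionEffect
        with pytest.raises(ValueError, match="unknown genes"):
            synth_expression_design(
                10, [ExpressionEffect("nope", karyotype_lfc=1.0)], seed=1)


class TestMergePopulations:
    def test_union_coordinates_and_monomorphic_reconstruction(self):
        src = simulate_inversion_population(small_params(T=300, seed=12))
        der = simulate_derived_population(src, 20, 100, seed=3,
                                          recovery_size=60)
        from invpayne import merge_populations
        mat, info = merge_populations({"anc": src, "dau": der})
        assert mat.n_samples == len(src.karyotypes) + len(der.karyotypes)
        # sites segregating in the source keep their source configuration
        anc_rows = [i for i, s in enumerate(mat.sample_ids)
                    if s.startswith("anc:")]
        src_pos = {int(p): j for j, p in enumerate(src.positions)}
        for j, p in enumerate(mat.positions):
            if int(p) in src_pos:
                assert (mat.alleles[anc_rows, j]
                        == src.haplotypes.alleles[:, src_pos[int(p)]]).all()
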