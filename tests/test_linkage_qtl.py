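import numpy as np
import pytest

from migkit import linkage as lk
from migkit import simulate as sim


def simulate_f2_pair(r, n, seed):
    """Two F2 markers at recombination fraction r (independent gametes)."""
    rng = np.random.default_rng(seed)
    g1a = rng.integers(0, 2, n)
    g1b = np.where(rng.random(n) < r, 1 - g1a, g1a)
    g2a = rng.integers(0, 2, n)
    g2b = np.where(rng.random(n) < r, 1 - g2a, g2a)
    return g1a + g2a, g1b + g2b


class TestRecombinationFraction:
    def test_ril_closed_form(self):
        # observed R = 0.2 -> r = R / (2 - 2R) = 0.125
        g1 = np.array([0] * 50 + [2] * 50)
        g2 = np.array([0] * 40 + [2] * 10 + [2] * 40 + [0] * 10)
        assert lk.recombination_fraction(g1, g2, "RIL") == pytest.approx(0.125)

    def test_zero_recombinants(self):
        g = np.array([0, 2] * 20)
        assert lk.recombination_fraction(g, g, "RIL") == 0.0
        f2 = np.array([0, 1, 2] * 20)
        assert lk.recombination_fraction(f2, f2, "F2") < 1e-6

    def test_f2_em_recovery(self):
        estimates = []
        for seed in range(10):
            g1, g2 = simulate_f2_pair(0.1, 500, seed)
            estimates.append(lk.recombination_fraction(g1, g2, "F2"))
        # sd of r-hat is ~ sqrt(r(1-r)/(2n)) per dataset
        sigma = np.sqrt(0.1 * 0.9 / (2 * 500)) / np.sqrt(10)
        assert np.mean(estimates) == pytest.approx(0.1, abs=3 * sigma)

    def test_few_individuals_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            lk.recombination_fraction(np.array([0, 2]), np.array([0, 2]), "RIL")

    def test_monomorphic_rejected(self):
        g = np.zeros(50, dtype=int)
        poly = np.array([0, 2] * 25)
        with pytest.raises(ValueError, match="monomorphic"):
            lk.recombination_fraction(g, poly, "RIL")

    def test_merged_sample_estimate_between_halves(self):
        g1, g2 = simulate_f2_pair(0.15, 400, 42)
        r_a = lk.recombination_fraction(g1[:200], g2[:200], "F2")
        r_b = lk.recombination_fraction(g1[200:], g2[200:], "F2")
        r_all = lk.recombination_fraction(g1, g2, "F2")
        assert min(r_a, r_b) - 1e-9 <= r_all <= max(r_a, r_b) + 1e-9


class TestKosambi:
    def test_zero(self):
        assert lk.kosambi_cM(0.0) == 0.0

    def test_closed_forms(self):
        assert lk.kosambi_cM(0.1) == pytest.approx(25 * np.log(1.5), abs=1e-9)
        assert lk.kosambi_cM(0.25) == pytest.approx(25 * np.log(3.0), abs=1e-9)

    def test_half_is_infinite(self):
        with pytest.raises(ValueError, match="infinite"):
            lk.kosambi_cM(0.5)

    def test_strictly_increasing_and_convex(self):
        grid = np.linspace(0, 0.49, 200)
        d = np.array([lk.kosambi_cM(r) for r in grid])
        assert (np.diff(d) > 0).all()
        assert (np.diff(d, 2) > -1e-9).all()

    def test_kosambi_below_haldane(self):
        for r in np.linspace(0.01, 0.49, 49):
            assert lk.kosambi_cM(r) < lk.haldane_cM(r)


class TestMapSummary:
    def test_f2_printed_totals(self):
        omap = lk.OrderedMap.evenly_spaced(5022.0, 3257)
        total, n, spacing = lk.map_summary(omap)
        assert round(spacing, 2) == 1.54

    def test_ril_printed_totals(self):
        omap = lk.OrderedMap.evenly_spaced(2521.6, 3148)
        _, _, spacing = lk.map_summary(omap)
        assert round(spacing, 2) == 0.80

    def test_construction_example(self):
        omap = lk.OrderedMap.evenly_spaced(10.0, 11)
        total, n, spacing = lk.map_summary(omap)
        assert (total, n) == (10.0, 11)
        assert spacing == pytest.approx(10 / 11)

    def test_single_marker_rejected(self):
        with pytest.raises(ValueError):
            lk.map_summary(lk.OrderedMap.evenly_spaced(0.0, 1))

    def test_decreasing_cm_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="non-decreasing"):
            lk.OrderedMap(groups={"g": pd.DataFrame(
                {"marker": ["a", "b"], "pos_bp": [1, 2], "cM": [1.0, 0.5]})})

    def test_map_length_recovery_f2(self):
        # markers every 5 cM; the chained Kosambi map should recover the
        # simulated length within 10%
        n_markers, step_cM = 21, 5.0
        length_bp = 1_000_000
        cm_per_mb = (n_markers - 1) * step_cM / (length_bp / 1e6)
        parent_a = [("chr1", int(i * length_bp / (n_markers - 1)) + 1, "A", "T")
                    for i in range(n_markers)]
        cross = sim.simulate_cross(parent_a, [], design="F2", n_progeny=500,
                                   cM_per_Mb=cm_per_mb, seed=9,
                                   chrom_lengths={"chr1": length_bp})
        omap = lk.map_from_genotypes(cross.genotypes, cross.marker_chrom,
                                     cross.marker_pos, population="F2")
        total, _, _ = lk.map_summary(omap)
        assert total == pytest.approx((n_markers - 1) * step_cM, rel=0.10)


class TestSegregationDistortion:
    def test_exact_ratio_chi2_zero(self):
        geno = np.array([[0] * 30 + [1] * 60 + [2] * 30])
        out = lk.segregation_distortion(geno, [1, 2, 1])
        assert out.iloc[0].chi2 == pytest.approx(0.0)
        assert out.iloc[0].p == pytest.approx(1.0)

    def test_hand_computed_chi2(self):
        geno = np.array([[0] * 50 + [1] * 50 + [2] * 20])
        out = lk.segregation_distortion(geno, [1, 2, 1])
        assert out.iloc[0].chi2 == pytest.approx(18.333, abs=1e-3)

    def test_missing_excluded(self):
        geno = np.array([[0] * 30 + [1] * 60 + [2] * 30 + [-1] * 40])
        out = lk.segregation_distortion(geno, [1, 2, 1])
        assert out.iloc[0].n == 120
        assert out.iloc[0].chi2 == pytest.approx(0.0)

    def test_all_missing_undefined(self):
        out = lk.segregation_distortion(np.array([[-1, -1, -1]]), [1, 2, 1])
        assert np.isnan(out.iloc[0].chi2)

    def test_type_i_calibration(self):
        rng = np.random.default_rng(3)
        geno = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(1000, 200))
        out = lk.segregation_distortion(geno, [1, 2, 1])
        frac = (out.p < 0.05).mean()
        assert 0.03 < frac < 0.07


class TestLodScan:
    def test_constant_phenotype_all_zero(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        profile = lk.lod_scan(geno, np.full(50, 3.14))
        assert (profile.table.lod == 0).all()

    def test_noise_free_ril_r2_one(self):
        rng = np.random.default_rng(1)
        geno = (rng.integers(0, 2, size=(5, 60)) * 2).astype(np.int8)
        y = (geno[2].astype(float) - 1.0) * 2.0
        profile = lk.lod_scan(geno, y)
        assert profile.table.r2[2] == pytest.approx(1.0, abs=1e-9)
        assert profile.peak_index == 2

    def test_monomorphic_marker_flagged_lod_zero(self):
        geno = np.vstack([np.zeros(50, dtype=np.int8),
                          np.array([0, 2] * 25, dtype=np.int8)])
        y = np.random.default_rng(2).normal(size=50)
        profile = lk.lod_scan(geno, y)
        assert profile.table.monomorphic[0]
        assert profile.table.lod[0] == 0.0

    def test_effect_recovery_f2(self):
        effect = 2.0
        estimates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            geno = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25],
                              size=(1, 300)).astype(np.int8)
            y = effect * (geno[0] - 1.0) + rng.normal(0, 1.0, 300)
            profile = lk.lod_scan(geno, y)
            estimates.append(profile.table.effect[0])
        sigma = 1.0 / np.sqrt(300 * 0.5) / np.sqrt(10)
        assert np.mean(estimates) == pytest.approx(effect, abs=3 * sigma)

    def test_missing_genotypes_tolerated(self):
        rng = np.random.default_rng(4)
        geno = rng.choice([-1, 0, 2], p=[0.2, 0.4, 0.4],
                          size=(10, 80)).astype(np.int8)
        y = rng.normal(size=80)
        profile = lk.lod_scan(geno, y)
        assert (profile.table.n <= 80).all()
        assert np.isfinite(profile.table.lod).all()


class TestPermutationThreshold:
    def test_alpha_one_gives_minimum(self):
        rng = np.random.default_rng(5)
        geno = rng.integers(0, 3, size=(30, 60)).astype(np.int8)
        y = rng.normal(size=60)
        thr = lk.permutation_threshold(geno, y, n_perm=100, alpha=1.0, seed=1)
        perm_rng = np.random.default_rng(1)
        y_sorted = np.sort(y)
        maxima = lk.max_lod(geno, np.stack(
            [perm_rng.permutation(y_sorted) for _ in range(100)], axis=1))
        assert thr == pytest.approx(maxima.min())

    def test_invariant_to_fixed_relabeling(self):
        rng = np.random.default_rng(6)
        geno = rng.integers(0, 3, size=(30, 60)).astype(np.int8)
        y = rng.normal(size=60)
        thr = lk.permutation_threshold(geno, y, n_perm=150, alpha=0.05, seed=2)
        y_shuffled = y[rng.permutation(60)]
        thr2 = lk.permutation_threshold(geno, y_shuffled, n_perm=150,
                                        alpha=0.05, seed=2)
        assert thr == thr2

    def test_observed_scan_unaffected_by_threshold_seed(self):
        rng = np.random.default_rng(7)
        geno = rng.integers(0, 3, size=(10, 60)).astype(np.int8)
        y = rng.normal(size=60)
        p1 = lk.qtl_scan(geno, y, n_perm=100, seed=1)
        p2 = lk.qtl_scan(geno, y, n_perm=100, seed=2)
        assert np.allclose(p1.table.lod, p2.table.lod)

    def test_null_calibration_coarse(self):
        rng = np.random.default_rng(8)
        hits = 0
        n_datasets = 60
        for i in range(n_datasets):
            geno = rng.integers(0, 3, size=(50, 80)).astype(np.int8)
            y = rng.normal(size=80)
            thr = lk.permutation_threshold(geno, y, n_perm=100, alpha=0.05,
                                           seed=1000 + i)
            if lk.max_lod(geno, y[:, None])[0] > thr:
                hits += 1
        # binomial 99.9% band around 0.05 with n = 60
        assert hits <= 12
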