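import numpy as np
import pytest
from scipy import stats

from migkit import simulate as sim
from migkit.genotype_qc import HET, MISSING


class TestSimulateGenome:
    def test_zero_density_no_loci(self):
        genome = sim.simulate_genome(50_000, 1, ssr_density=0, seed=0)
        assert genome.ssr_loci == []

    def test_length_and_alphabet(self):
        genome = sim.simulate_genome(50_000, 3, ssr_density=50, seed=0)
        assert genome.length_bp == 50_000
        assert len(genome.sequences) == 3
        for seq in genome.sequences.values():
            assert set(seq) <= set("ACGT")

    def test_loci_within_bounds_and_disjoint(self, small_genome):
        by_chrom = {}
        for locus in small_genome.ssr_loci:
            assert 0 <= locus.start < locus.end <= len(
                small_genome.sequences[locus.chrom]
            )
            by_chrom.setdefault(locus.chrom, []).append((locus.start, locus.end))
        for intervals in by_chrom.values():
            intervals.sort()
            assert all(a[1] <= b[0] for a, b in zip(intervals, intervals[1:]))

    def test_locus_count_poisson_interval(self):
        # 1 Mb at 100 / Mb: count should fall in the Poisson 99% interval
        genome = sim.simulate_genome(1_000_000, 1, ssr_density=100, seed=21)
        lo, hi = stats.poisson.ppf([0.005, 0.995], 100)
        assert lo <= len(genome.ssr_loci) <= hi

    def test_count_proportional_to_length(self):
        counts = {}
        for length in (500_000, 1_000_000):
            total = sum(
                len(sim.simulate_genome(length, 1, ssr_density=100,
                                        seed=30 + i).ssr_loci)
                for i in range(4)
            )
            counts[length] = total
        ratio = counts[1_000_000] / counts[500_000]
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_genome(5_000, 1, 10, seed=0)

    def test_impossible_density_errors(self):
        with pytest.raises(RuntimeError, match="cannot place"):
            sim.simulate_genome(10_000, 1, ssr_density=50_000, seed=0)

    def test_deterministic(self):
        a = sim.simulate_genome(20_000, 1, 100, seed=5)
        b = sim.simulate_genome(20_000, 1, 100, seed=5)
        assert a.sequences == b.sequences
        assert a.ssr_loci == b.ssr_loci


class TestSimulatePanel:
    def test_pi_zero_identical(self, small_genome):
        panel = sim.simulate_panel(small_genome, 3, 0.0, seed=0)
        assert all(len(v) == 0 for v in panel.variants.values())

    def test_pi_out_of_range(self, small_genome):
        with pytest.raises(ValueError):
            sim.simulate_panel(small_genome, 2, 0.2, seed=0)

    def test_pairwise_difference_binomial_interval(self):
        genome = sim.simulate_genome(1_000_000, 1, ssr_density=0, seed=1)
        panel = sim.simulate_panel(genome, 2, 0.0025, seed=2)
        a, b = (set((c, p, alt) for c, p, _, alt in v)
                for v in panel.variants.values())
        diff = len(a ^ b)
        lo, hi = stats.poisson.ppf([0.005, 0.995], 2500)
        assert lo <= diff <= hi

    def test_each_pair_satisfies_bound(self):
        genome = sim.simulate_genome(500_000, 1, ssr_density=0, seed=3)
        panel = sim.simulate_panel(genome, 4, 0.0025, seed=4)
        lo, hi = stats.poisson.ppf([0.001, 0.999], 0.0025 * 500_000)
        names = panel.accessions
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a = set((c, p, alt) for c, p, _, alt in panel.variants[names[i]])
                b = set((c, p, alt) for c, p, _, alt in panel.variants[names[j]])
                assert lo <= len(a ^ b) <= hi

    def test_ref_matches_genome(self, small_genome, panel):
        for variants in panel.variants.values():
            for chrom, pos, ref, alt in variants[:50]:
                assert small_genome.sequences[chrom][pos - 1] == ref
                assert alt != ref


class TestSimulateCross:
    def test_identical_parents_error(self, panel):
        v = panel.variants[panel.accessions[0]]
        with pytest.raises(ValueError, match="no segregating"):
            sim.simulate_cross(v, v, "F2", 10, 1.0, seed=0)

    def test_f2_marginal_ratio(self):
        parent_a = [("chr1", 500_000, "A", "T")]
        cross = sim.simulate_cross(parent_a, [], "F2", 400, 2.0, seed=1,
                                   chrom_lengths={"chr1": 1_000_000})
        counts = [(cross.genotypes == g).sum() for g in (0, 1, 2)]
        chi2, p = stats.chisquare(counts, f_exp=[100, 200, 100])
        assert chi2 < stats.chi2.ppf(0.99, df=2)

    def test_ril_residual_heterozygosity(self):
        parent_a = [("chr1", int(p), "A", "T")
                    for p in np.linspace(1, 900_000, 40)]
        cross = sim.simulate_cross(parent_a, [], "RIL", 300, 0.1, seed=2,
                                   chrom_lengths={"chr1": 1_000_000},
                                   generation=6)
        het = (cross.genotypes == 1).mean()
        expect = 0.5 ** 5
        # markers on one chromosome are correlated; bound via per-individual
        # independence only
        sigma = np.sqrt(expect * (1 - expect) / cross.n_progeny)
        assert abs(het - expect) < 3 * sigma

    def test_zero_distance_markers_no_recombinants(self):
        parent_a = [("chr1", 1000, "A", "T"), ("chr1", 1000 + 0, "C", "G")]
        # same position -> distance 0; use two distinct keys one base apart
        parent_a = [("chr1", 1000, "A", "T"), ("chr1", 1001, "C", "G")]
        cross = sim.simulate_cross(parent_a, [], "F2", 200, 5.0, seed=3,
                                   chrom_lengths={"chr1": 2_000_000})
        g = cross.genotypes
        assert np.array_equal(g[0], g[1])

    def test_design_validation(self, panel):
        names = panel.accessions
        with pytest.raises(ValueError, match="design"):
            sim.simulate_cross(panel.variants[names[0]],
                               panel.variants[names[1]], "BC1", 10, 1.0, seed=0)


class TestSimulateMigseqDepths:
    def test_no_loci_errors(self, panel):
        bare = sim.simulate_genome(50_000, 1, ssr_density=0, seed=0)
        with pytest.raises(ValueError, match="no amplifiable"):
            sim.simulate_migseq_depths(bare, panel, sim.CoverageModel(), 1000,
                                       seed=0)

    def test_depth_zero_outside_amplified_loci(self, small_genome, panel):
        tables, _ = sim.simulate_migseq_depths(
            small_genome, panel, sim.CoverageModel(), 10_000, seed=1
        )
        pbd = next(iter(tables.values()))
        covered = sum(int((a > 0).sum()) for a in pbd.depths.values())
        assert 0 < covered < small_genome.length_bp * 0.2

    def test_overdispersion_zero_poisson_depths(self, small_genome, panel):
        model = sim.CoverageModel(overdispersion=0.0)
        tables, _ = sim.simulate_migseq_depths(small_genome, panel, model,
                                               30_000, seed=2)
        # pool depths at anchors of isolated loci (no amplicon overlap) over
        # all samples: with equal weights these are i.i.d. Poisson
        loci = sorted(small_genome.ssr_loci, key=lambda l: (l.chrom, l.start))
        gap = model.insert_range[1] + 1
        isolated = [
            l for i, l in enumerate(loci)
            if (i == 0 or loci[i - 1].chrom != l.chrom
                or l.start - loci[i - 1].start > gap)
            and (i == len(loci) - 1 or loci[i + 1].chrom != l.chrom
                 or loci[i + 1].start - l.start > gap)
        ]
        depths = np.array([
            pbd.depths[l.chrom][l.start]
            for pbd in tables.values() for l in isolated
        ])
        ratio = depths.var() / depths.mean()
        assert ratio == pytest.approx(1.0, abs=0.35)

    def test_doubling_reads_doubles_mapped_bases(self, small_genome, panel):
        model = sim.CoverageModel(overdispersion=0.5)
        totals = []
        for n in (15_000, 30_000):
            tables, _ = sim.simulate_migseq_depths(small_genome, panel, model,
                                                   n, seed=3)
            totals.append(sum(t.total_mapped_bases() for t in tables.values()))
        assert totals[1] / totals[0] == pytest.approx(2.0, rel=0.1)

    def test_het_ad_conservation(self, small_genome, panel, ril_cross):
        model = sim.CoverageModel(base_error_rate=0.0)
        _, m = sim.simulate_migseq_depths(small_genome, ril_cross, model,
                                          30_000, seed=4)
        het_cells = m.gt == HET
        assert (m.ad.sum(axis=2)[het_cells] == m.dp[het_cells]).all()
        both_seen = (m.ad[..., 0] > 0) & (m.ad[..., 1] > 0)
        assert both_seen[het_cells & (m.dp >= 10)].mean() > 0.9

    def test_zero_depth_cells_missing(self, coverage):
        _, m = coverage
        assert (m.gt[m.dp == 0] == MISSING).all()

    def test_mapped_bases_monotone_in_genome_size(self):
        totals = []
        for length in (100_000, 200_000, 400_000):
            genome = sim.simulate_genome(length, 1, ssr_density=150, seed=6)
            panel = sim.simulate_panel(genome, 2, 0.001, seed=7)
            tables, _ = sim.simulate_migseq_depths(
                genome, panel, sim.CoverageModel(), 30_000, seed=8
            )
            pbd = next(iter(tables.values()))
            totals.append(sum(int((a > 0).sum()) for a in pbd.depths.values()))
        assert totals[0] < totals[1] < totals[2]


class TestSimulatePhenotype:
    def test_no_qtl_no_noise_constant(self, ril_cross):
        y = sim.simulate_phenotype(ril_cross, [], noise_sd=0.0, seed=0)
        assert np.allclose(y, y[0])

    def test_coding_identity(self, ril_cross):
        marker = (str(ril_cross.marker_chrom[0]), int(ril_cross.marker_pos[0]))
        y = sim.simulate_phenotype(ril_cross, [(marker, 2.0)], noise_sd=0.0,
                                   seed=0)
        g = ril_cross.genotypes[0]
        aa = y[g == 0]
        bb = y[g == 2]
        assert bb.mean() - aa.mean() == pytest.approx(4.0)

    def test_unknown_marker_errors(self, ril_cross):
        with pytest.raises(KeyError, match="unknown marker"):
            sim.simulate_phenotype(ril_cross, [(("chrX", 1), 1.0)], seed=0)

    def test_lod_peak_at_causal_marker(self):
        from migkit import linkage as lk

        parent_a = [("chr1", int(p), "A", "T")
                    for p in np.linspace(1, 990_000, 12)]
        cross = sim.simulate_cross(parent_a, [], "RIL", 250, 30.0, seed=10,
                                   chrom_lengths={"chr1": 1_000_000})
        marker = (str(cross.marker_chrom[5]), int(cross.marker_pos[5]))
        y = sim.simulate_phenotype(cross, [(marker, 2.0)], noise_sd=1.0,
                                   seed=11)
        profile = lk.lod_scan(cross.genotypes, y)
        assert profile.peak_index == 5


def test_truth_tables_round_trip(tmp_path, small_genome):
    from migkit import io as mio

    fasta = tmp_path / "g.fasta"
    mio.write_fasta(small_genome.sequences, str(fasta))
    assert mio.read_fasta(str(fasta)) == small_genome.sequences

    bed = tmp_path / "loci.bed"
    mio.write_bed(small_genome.ssr_loci, str(bed))
    back = mio.read_bed(str(bed))
    assert [(l.chrom, l.start, l.end) for l in back] == [
        (l.chrom, l.start, l.end) for l in small_genome.ssr_loci
    ]
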