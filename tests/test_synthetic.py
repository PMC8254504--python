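"""Ground-truth simulators: crossover process, sequencing emulator,
tetrad model and spot renderer."""

import numpy as np
import pytest
from scipy import stats

import meiorec as mr
from meiorec.synthetic import PlacementError
from meiorec.tetrads import classify_intervals


class TestCrossoverProcess:
    def test_empty_interval(self, rng):
        assert mr.simulate_crossovers(0.0, 1.0, rng).size == 0

    def test_parameter_validation(self, rng):
        with pytest.raises(ValueError):
            mr.simulate_crossovers(-1.0, 1.0, rng)
        with pytest.raises(ValueError):
            mr.simulate_crossovers(100.0, 0.5, rng)

    def test_poisson_mean_count(self, rng):
        """At nu=1 the process is Poisson with mean L/100."""
        reps = 10_000
        counts = np.array([mr.simulate_crossovers(100.0, 1.0, rng).size for _ in range(reps)])
        # Poisson(1): sd = 1, so a 3-sigma band on the mean
        assert abs(counts.mean() - 1.0) < 3.0 / np.sqrt(reps)

    def test_poisson_count_distribution(self, rng):
        """Chi-square goodness of fit of the nu=1 count law to Poisson(L/100)."""
        reps = 10_000
        lam = 2.0
        counts = np.array([mr.simulate_crossovers(200.0, 1.0, rng).size for _ in range(reps)])
        kmax = 8
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        expected = stats.poisson.pmf(np.arange(kmax), lam) * reps
        expected = np.append(expected, reps - expected.sum())  # tail class
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=kmax)
        assert p > 0.01

    def test_interference_underdispersion(self, rng):
        """At nu=5 the count over 3 mean spacings is underdispersed."""
        reps = 10_000
        counts = np.array([mr.simulate_crossovers(300.0, 5.0, rng).size for _ in range(reps)])
        assert abs(counts.mean() - 3.0) < 0.1
        assert counts.var() < counts.mean()

    def test_stationarity_uniform_positions(self, rng):
        """A stationary renewal process has uniformly distributed event
        positions; the equilibrium first-arrival draw makes this hold even
        for strong interference."""
        pos = np.concatenate(
            [mr.simulate_crossovers(100.0, 5.0, rng) for _ in range(4000)]
        )
        assert stats.kstest(pos / 100.0, "uniform").pvalue > 0.01


class TestZygosity:
    def _truth(self, cos, phase="HET"):
        t = mr.MeiosisTruth()
        t.co_positions_bp["c1"] = np.asarray(cos, dtype=np.int64)
        t.start_phase["c1"] = phase
        return t

    def test_no_crossovers(self):
        t = self._truth([])
        for pos in (1, 10_000, 10**7):
            assert mr.zygosity_at(t, "c1", pos) == "HET"

    def test_single_flip(self):
        t = self._truth([5_000_000])
        assert mr.zygosity_at(t, "c1", 4_999_999) == "HET"
        assert mr.zygosity_at(t, "c1", 6_000_000) == "HOM_COL"

    def test_parity(self):
        t = self._truth([2_000_000, 8_000_000])
        assert mr.zygosity_at(t, "c1", 9_000_000) == "HET"
        assert mr.zygosity_at(t, "c1", 5_000_000) == "HOM_COL"

    def test_unknown_chromosome(self):
        with pytest.raises(KeyError):
            mr.zygosity_at(self._truth([]), "nope", 1)


class TestBackcrossCounts:
    def test_no_alt_reads_at_hom_sites_without_error(self, small_genome, rng):
        params = mr.SimParams(coverage_mean=4.0, error_rate=0.0)
        truth = mr.MeiosisTruth()
        for c in small_genome:
            truth.co_positions_bp[c.name] = np.empty(0, dtype=np.int64)
            truth.start_phase[c.name] = "HOM_COL"
        counts = mr.simulate_backcross_counts(truth, small_genome, params, rng)
        assert (counts.table["alt"] == 0).all()
        # depth conservation: totals follow Poisson(4)
        total = (counts.table["ref"] + counts.table["alt"]).to_numpy()
        assert abs(total.mean() - 4.0) < 0.1

    def test_het_sites_pool_to_half(self, small_genome, rng):
        """Pooled h over many error-free heterozygous sites approaches 0.5."""
        params = mr.SimParams(coverage_mean=5.0, error_rate=0.0)
        truth = mr.MeiosisTruth()
        for c in small_genome:
            truth.co_positions_bp[c.name] = np.empty(0, dtype=np.int64)
            truth.start_phase[c.name] = "HET"
        counts = mr.simulate_backcross_counts(truth, small_genome, params, rng)
        h = mr.pooled_heterozygosity(counts.table["ref"].sum(), counts.table["alt"].sum())
        assert abs(h - 0.5) < 0.01

    def test_determinism(self, small_genome):
        params = mr.SimParams(coverage_mean=3.0, error_rate=0.005)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            truth = mr.simulate_meiosis(small_genome, params, rng)
            counts = mr.simulate_backcross_counts(truth, small_genome, params, rng)
            out.append((truth, counts))
        t1, c1 = out[0]
        t2, c2 = out[1]
        for name in t1.co_positions_bp:
            assert np.array_equal(t1.co_positions_bp[name], t2.co_positions_bp[name])
            assert t1.start_phase[name] == t2.start_phase[name]
        assert c1.table.equals(c2.table)


class TestTetradSimulator:
    def test_zero_distance_all_parental(self, rng):
        td = mr.simulate_tetrads(0.0, 0.0, 1.0, 500, rng)
        for interval in (("m1", "m2"), ("m2", "m3")):
            labels, valid = classify_intervals(td, *interval)
            assert valid.all()
            assert (labels == "PD").all()

    def test_two_to_two_segregation_always(self, rng):
        td = mr.simulate_tetrads(20.0, 20.0, 1.0, 2000, rng)
        for m in ("m1", "m2", "m3"):
            cols = [f"s{s}_{m}" for s in (1, 2, 3, 4)]
            assert (td[cols].sum(axis=1) == 2).all()

    @pytest.mark.parametrize("d", [2.0, 6.0, 10.0])
    def test_perkins_recovery(self, d, rng):
        n = 100_000
        td = mr.simulate_tetrads(d, 4.0, 1.0, n, rng)
        res = mr.perkins_distance(td, ("m1", "m2"))
        p = d / 50.0
        se = 50.0 * np.sqrt(p * (1 - p) / n)
        assert abs(res.cM - d) < 3 * se

    def test_tetratype_marginal_frequency(self, rng):
        n = 50_000
        d = 8.0
        td = mr.simulate_tetrads(d, 3.0, 1.0, n, rng)
        labels, _ = classify_intervals(td, "m1", "m2")
        tt_freq = (labels == "TT").mean()
        se = np.sqrt((d / 50) * (1 - d / 50) / n)
        assert abs(tt_freq - 2 * d / 100) < 3 * se

    def test_infeasible_joint_probability(self, rng):
        # S * (d1/50) * (d2/50) > min marginal
        with pytest.raises(ValueError):
            mr.simulate_tetrads(40.0, 2.0, 30.0, 10, rng)
        with pytest.raises(ValueError):
            mr.simulate_tetrads(60.0, 2.0, 1.0, 10, rng)


class TestPollenExpansion:
    def test_parental_ditype_expansion(self, rng):
        td = mr.simulate_tetrads(0.0, 0.0, 1.0, 1, rng)
        pollen = mr.tetrads_to_pollen(td, ("m1", "m2"))
        both = (pollen["mA"] & pollen["mB"]).sum()
        neither = (~pollen["mA"] & ~pollen["mB"]).sum()
        assert (both, neither) == (2, 2)

    def test_tetratype_gives_two_single_marker_pollen(self):
        from conftest import build_tetrad_table

        td = build_tetrad_table({("TT", "PD"): 1})
        pollen = mr.tetrads_to_pollen(td, ("m1", "m2"))
        singles = (pollen["mA"] ^ pollen["mB"]).sum()
        assert len(pollen) == 4 and singles == 2

    def test_pollen_distance_identity(self):
        """900 PD + 100 TT tetrads give 200 single-marker pollen of 4,000,
        i.e. 5.0 cM — the TT/2 identity between assays."""
        from conftest import build_tetrad_table

        td = build_tetrad_table({("PD", "PD"): 900, ("TT", "PD"): 100})
        pollen = mr.tetrads_to_pollen(td, ("m1", "m2"))
        res = mr.single_pollen_distance(pollen)
        assert (res.n, res.recombinant) == (4000, 200)
        assert res.cM == pytest.approx(5.0)

    def test_pollen_tetrad_consistency_on_simulated_meioses(self, rng):
        """On the same NPD-free simulated meioses, the single-pollen distance
        equals the tetrad Perkins distance exactly."""
        td = mr.simulate_tetrads(7.0, 3.0, 0.5, 20_000, rng)
        tet = mr.perkins_distance(td, ("m1", "m2"))
        pol = mr.single_pollen_distance(mr.tetrads_to_pollen(td, ("m1", "m2")))
        assert pol.cM == pytest.approx(tet.cM)


class TestSpotRenderer:
    def test_no_spots_no_noise_is_constant(self):
        gt = mr.render_spot_image(shape=(64, 64), n_spots=0, noise_sd=0.0,
                                  background=500.0, rng=np.random.default_rng(1))
        assert (gt.image == 500).all()

    def test_center_pixel_amplitude(self):
        gt = mr.render_spot_image(
            shape=(64, 64), n_spots=1, amplitude=10_000.0, background=500.0,
            noise_sd=0.0, centers=np.array([[32, 32]]),
        )
        assert abs(int(gt.image[32, 32]) - 10_500) <= 1

    def test_sixteen_bit_range_enforced(self):
        with pytest.raises(ValueError):
            mr.render_spot_image(amplitude=65_000.0, background=1000.0)
        gt = mr.render_spot_image(shape=(32, 32), n_spots=1, amplitude=60_000.0,
                                  background=5000.0, noise_sd=3000.0,
                                  rng=np.random.default_rng(2))
        assert gt.image.max() <= 65_535 and gt.image.dtype == np.uint16

    def test_infeasible_packing_raises(self):
        with pytest.raises(PlacementError):
            mr.render_spot_image(shape=(40, 40), n_spots=200, sigma_px=2.0,
                                 rng=np.random.default_rng(3))

    def test_minimum_separation_respected(self):
        gt = mr.render_spot_image(shape=(256, 256), n_spots=40, sigma_px=2.0,
                                  rng=np.random.default_rng(4))
        c = gt.true_centers
        d2 = ((c[:, None, :] - c[None, :, :]) ** 2).sum(-1)
        d2[np.diag_indices(len(c))] = np.inf
        assert np.sqrt(d2.min()) >= 12.0

    def test_determinism(self):
        a = mr.render_spot_image(n_spots=20, rng=np.random.default_rng(5))
        b = mr.render_spot_image(n_spots=20, rng=np.random.default_rng(5))
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.true_centers, b.true_centers)
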