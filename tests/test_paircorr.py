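"""Pair-correlation functions, random-labeling envelopes and EOM."""

import numpy as np
import pytest

from ncd import (
    EOMCurve,
    PCFCurve,
    PointPattern,
    RadialBins,
    Window,
    bpcf,
    eom,
    eom_average,
    mean_eom_short,
    mean_g_short,
    pcf,
    rl_envelope,
)
from ncd.errors import GeometryError, InsufficientDataError, ParameterError
from ncd.synthetic import gen_poisson, gen_random_label_mix, gen_thomas

from _oracles import brute_bpcf, brute_pcf


BINS = RadialBins.linear(r_max=200.0, width=20.0)


class TestRadialBins:
    def test_from_spec(self):
        rb = RadialBins.from_spec("0:1000:10")
        assert rb.n_bins == 100
        assert rb.centers[0] == 5.0

    @pytest.mark.parametrize("edges", [[0.0], [10.0, 10.0], [-5.0, 10.0]])
    def test_invalid_edges_rejected(self, edges):
        with pytest.raises(ParameterError):
            RadialBins(np.asarray(edges))


class TestPcfOracle:
    @pytest.mark.parametrize("mode", ["periodic", "translation", "none"])
    def test_matches_brute_force(self, rng, small_window, mode):
        pts = rng.uniform(0, 2000, size=(30, 2))
        pat = PointPattern(pts, small_window)
        expected = brute_pcf(pts, small_window, BINS.edges, mode)
        got = pcf(pat, BINS, mode).g
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    @pytest.mark.parametrize("mode", ["periodic", "translation"])
    def test_bivariate_matches_brute_force(self, rng, small_window, mode):
        pa = rng.uniform(0, 2000, size=(25, 2))
        pb = rng.uniform(0, 2000, size=(20, 2))
        a, b = PointPattern(pa, small_window), PointPattern(pb, small_window)
        expected = brute_bpcf(pa, pb, small_window, BINS.edges, mode)
        np.testing.assert_allclose(bpcf(a, b, BINS, mode).g, expected, rtol=1e-10)

    def test_two_points_single_occupied_bin(self):
        # two points 50 nm apart: only the 40-60 nm annulus is non-zero, with
        # g = 2 * A / (n (n-1) * annulus_area) from the expected-count oracle
        win = Window.square(1000.0)
        pat = PointPattern(np.array([[475.0, 500.0], [525.0, 500.0]]), win)
        curve = pcf(pat, BINS, "periodic")
        annulus = np.pi * (60.0**2 - 40.0**2)
        expected = 2 * win.area_nm2 / (2 * 1 * annulus)
        k = np.flatnonzero(curve.g)[0]
        assert curve.bins.centers[k] == 50.0
        assert curve.g[k] == pytest.approx(expected)
        assert np.count_nonzero(curve.g) == 1

    def test_single_point_insufficient(self):
        pat = PointPattern(np.array([[5.0, 5.0]]), Window.square(100.0))
        with pytest.raises(InsufficientDataError):
            pcf(pat, BINS)


class TestCalibration:
    def test_poisson_is_flat(self):
        vals = []
        for s in range(15):
            p = gen_poisson(100.0, Window.square(5000.0), seed=s)
            c = pcf(p, RadialBins.linear(500.0, 10.0), "periodic")
            sel = (c.bins.centers >= 20) & (c.bins.centers <= 500)
            vals.append(c.g[sel].mean())
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1.0) < 3 * se

    def test_independent_patterns_give_flat_g12(self):
        vals = []
        for s in range(15):
            a = gen_poisson(60.0, Window.square(5000.0), seed=2 * s)
            b = gen_poisson(60.0, Window.square(5000.0), seed=2 * s + 1)
            vals.append(bpcf(a, b, RadialBins.linear(500.0, 10.0), "periodic").g.mean())
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1.0) < 3 * se


class TestBpcf:
    def test_symmetry(self, rng, small_window):
        a = PointPattern(rng.uniform(0, 2000, size=(40, 2)), small_window)
        b = PointPattern(rng.uniform(0, 2000, size=(25, 2)), small_window)
        np.testing.assert_allclose(
            bpcf(a, b, BINS, "translation").g, bpcf(b, a, BINS, "translation").g
        )

    def test_self_bivariate_relates_to_univariate(self):
        # b identical to a: away from r=0 the only difference is the
        # n*(n-1) vs n*n normalization; the self pairs land in the first bin
        a = gen_thomas(2.0, 10.0, 30.0, Window.square(3000.0), seed=4)
        g11 = pcf(a, BINS, "periodic").g
        g12 = bpcf(a, a.with_points(a.points.copy()), BINS, "periodic").g
        n = a.n
        np.testing.assert_allclose(g12[1:], g11[1:] * (n - 1) / n, rtol=1e-10)
        self_pair_term = n * a.window.area_nm2 / (n * n * BINS.annulus_areas[0])
        assert g12[0] == pytest.approx(g11[0] * (n - 1) / n + self_pair_term)

    def test_translated_copy_short_range_flat(self, rng):
        win = Window.square(4000.0)
        a = gen_thomas(3.0, 10.0, 30.0, win, seed=9)
        shifted = (a.points + np.array([2000.0, 2000.0])) % win.sizes
        b = PointPattern(shifted, win)
        g12 = bpcf(a, b, BINS, "periodic").g
        expected = brute_bpcf(a.points, shifted, win, BINS.edges, "periodic")
        np.testing.assert_allclose(g12, expected, rtol=1e-10)
        assert abs(g12.mean() - 1.0) < 0.35  # independent at short range

    def test_mismatched_windows_rejected(self, rng, small_window):
        a = PointPattern(rng.uniform(0, 2000, size=(10, 2)), small_window)
        b = PointPattern(rng.uniform(0, 1000, size=(10, 2)), Window.square(1000.0))
        with pytest.raises(GeometryError):
            bpcf(a, b, BINS)


class TestEnvelope:
    def test_deterministic_under_seed(self, rng, small_window):
        a = PointPattern(rng.uniform(0, 2000, size=(40, 2)), small_window)
        b = PointPattern(rng.uniform(0, 2000, size=(30, 2)), small_window)
        e1 = rl_envelope(a, b, BINS, n_sims=19, seed=7)
        e2 = rl_envelope(a, b, BINS, n_sims=19, seed=7)
        np.testing.assert_array_equal(e1.lo, e2.lo)
        np.testing.assert_array_equal(e1.hi, e2.hi)
        np.testing.assert_array_equal(e1.mean_sim, e2.mean_sim)

    def test_single_simulation_collapses(self, rng, small_window):
        a = PointPattern(rng.uniform(0, 2000, size=(20, 2)), small_window)
        b = PointPattern(rng.uniform(0, 2000, size=(20, 2)), small_window)
        env = rl_envelope(a, b, BINS, n_sims=1, seed=3)
        np.testing.assert_array_equal(env.lo, env.hi)
        np.testing.assert_array_equal(env.lo, env.mean_sim)

    def test_bad_nsims_rejected(self, rng, small_window):
        a = PointPattern(rng.uniform(0, 2000, size=(5, 2)), small_window)
        with pytest.raises(ParameterError):
            rl_envelope(a, a, BINS, n_sims=0)

    def test_envelope_ordering(self, rng, small_window):
        a = PointPattern(rng.uniform(0, 2000, size=(50, 2)), small_window)
        b = PointPattern(rng.uniform(0, 2000, size=(50, 2)), small_window)
        env = rl_envelope(a, b, BINS, n_sims=19, seed=1)
        assert np.all(env.lo <= env.mean_sim + 1e-12)
        assert np.all(env.mean_sim <= env.hi + 1e-12)


class TestEom:
    def _envelope(self, mean):
        g = np.asarray(mean, dtype=float)
        from ncd import RLEnvelope

        return RLEnvelope(BINS, g - 0.5, g + 0.5, g, n_sims=19)

    def test_observed_at_rl_mean_gives_one(self):
        mean = np.full(BINS.n_bins, 5.0)
        curve = PCFCurve(BINS, mean.copy(), kind="g12")
        np.testing.assert_allclose(eom(curve, self._envelope(mean)).eom, 1.0)

    def test_flat_observed_gives_zero(self):
        mean = np.full(BINS.n_bins, 5.0)
        curve = PCFCurve(BINS, np.ones(BINS.n_bins), kind="g12")
        np.testing.assert_allclose(eom(curve, self._envelope(mean)).eom, 0.0)

    def test_halfway_gives_half(self):
        mean = np.full(BINS.n_bins, 5.0)
        curve = PCFCurve(BINS, np.full(BINS.n_bins, 3.0), kind="g12")
        np.testing.assert_allclose(eom(curve, self._envelope(mean)).eom, 0.5)

    def test_degenerate_bins_are_nan(self):
        mean = np.full(BINS.n_bins, 5.0)
        mean[3] = 1.01  # inside the degeneracy tolerance
        curve = PCFCurve(BINS, np.full(BINS.n_bins, 2.0), kind="g12")
        vals = eom(curve, self._envelope(mean)).eom
        assert np.isnan(vals[3]) and np.isfinite(np.delete(vals, 3)).all()

    def test_bin_mismatch_rejected(self):
        other = RadialBins.linear(100.0, 20.0)
        curve = PCFCurve(other, np.ones(other.n_bins), kind="g12")
        with pytest.raises(ParameterError):
            eom(curve, self._envelope(np.full(BINS.n_bins, 5.0)))

    def test_mixing_fraction_sweep_is_monotone(self):
        # mean short-range EOM grows with the fraction of co-labeled clusters
        means = []
        bins = RadialBins.linear(150.0, 10.0)
        for frac in (0.0, 0.5, 1.0):
            vals = []
            for rep in range(6):
                a, b = gen_random_label_mix(
                    frac, window=Window.square(5000.0), seed=1000 + rep
                )
                env = rl_envelope(a, b, bins, 19, seed=rep, edge_correction="periodic")
                curve = eom(bpcf(a, b, bins, "periodic"), env)
                vals.append(mean_eom_short(curve))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestSummaries:
    def test_mean_g_short_constant(self):
        bins = RadialBins.linear(100.0, 10.0)
        assert mean_g_short(PCFCurve(bins, np.full(10, 7.0))) == 7.0

    def test_mean_g_short_selects_bins(self):
        bins = RadialBins(np.array([0.0, 50.0, 100.0, 150.0]))  # centers 25/75/125
        curve = PCFCurve(bins, np.array([2.0, 4.0, 9.0]))
        assert mean_g_short(curve, 100.0) == pytest.approx(3.0)

    def test_mean_g_short_no_bins_rejected(self):
        bins = RadialBins(np.array([200.0, 300.0]))
        with pytest.raises(ParameterError):
            mean_g_short(PCFCurve(bins, np.array([1.0])), 100.0)

    def test_poisson_short_range_summary_is_one(self):
        vals = []
        for s in range(10):
            p = gen_poisson(100.0, Window.square(5000.0), seed=100 + s)
            vals.append(mean_g_short(pcf(p, RadialBins.linear(200.0, 10.0), "periodic")))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)


class TestEomAverage:
    def _curve(self, vals):
        return EOMCurve(BINS, np.asarray(vals, dtype=float))

    def test_identical_curves_average_to_themselves(self):
        c = self._curve(np.linspace(0, 1, BINS.n_bins))
        avg = eom_average([c, self._curve(c.eom.copy())])
        np.testing.assert_allclose(avg.eom, c.eom)

    def test_mean_of_zero_and_one(self):
        avg = eom_average([self._curve(np.zeros(BINS.n_bins)), self._curve(np.ones(BINS.n_bins))])
        np.testing.assert_allclose(avg.eom, 0.5)
        assert np.all(avg.n_cells == 2)

    def test_undefined_bins_are_skipped_per_curve(self):
        a = np.zeros(BINS.n_bins)
        a[0] = np.nan
        avg = eom_average([self._curve(a), self._curve(np.ones(BINS.n_bins))])
        assert avg.eom[0] == 1.0 and avg.n_cells[0] == 1
        assert avg.eom[1] == 0.5 and avg.n_cells[1] == 2

    def test_empty_collection_rejected(self):
        with pytest.raises(ParameterError):
            eom_average([])
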