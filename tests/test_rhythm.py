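"""Chi-square periodogram and (group) cosinor."""
import numpy as np
import pytest

from circasleep import (
    ParameterError,
    StructureError,
    chi2_periodogram,
    compare_group_cosinor,
    cosinor_fit,
    group_cosinor,
    make_schedule,
    simulate_activity,
)
from circasleep.rhythm import circular_distance_deg


class TestPeriodogram:
    def test_constant_series_zero_qp(self):
        pg = chi2_periodogram(np.full(3000, 5.0), bin_h=1.0 / 60.0)
        assert (pg.qp == 0).all()
        assert not pg.significant.any()

    @pytest.mark.parametrize("period", [21.0, 22.0])
    def test_detects_entrained_period(self, period):
        sched = make_schedule(period, 0.5, n_days=14)
        act = simulate_activity(sched, period, seed=3)
        pg = chi2_periodogram(act.distance, bin_h=1.0 / 60.0)
        assert abs(pg.peak_period_h - period) <= 1.0 / 60.0 + 1e-9
        assert pg.peak_significant

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000) + np.cos(np.arange(2000) / 50.0)
        a = chi2_periodogram(x, bin_h=1.0 / 6.0)
        b = chi2_periodogram(3.0 * x + 7.0, bin_h=1.0 / 6.0)
        np.testing.assert_allclose(a.qp, b.qp, rtol=1e-9)

    def test_period_grid_finer_than_bins_rejected(self):
        with pytest.raises(ParameterError):
            chi2_periodogram(np.ones(100), bin_h=1.0, period_range_h=(1.5, 30.0))

    def test_threshold_is_chi2_quantile(self):
        from scipy import stats

        pg = chi2_periodogram(
            np.random.default_rng(1).standard_normal(2016), bin_h=1.0 / 6.0
        )
        i = 10
        expected = stats.chi2.ppf(0.99, pg.df[i])
        assert pg.threshold[i] == pytest.approx(expected)


class TestCosinor:
    def test_exact_recovery(self):
        t = np.arange(0, 48, 1 / 6)
        y = 2 + 1 * np.cos(2 * np.pi * t / 24 + np.radians(40))
        f = cosinor_fit(t, y, 24.0)
        assert f.mesor == pytest.approx(2.0, abs=1e-9)
        assert f.amplitude == pytest.approx(1.0, abs=1e-9)
        assert f.theta_deg == pytest.approx(40.0, abs=1e-9)
        assert f.acrophase_deg == pytest.approx(320.0, abs=1e-9)

    def test_doubling_scales_mesor_amplitude_not_phase(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 48, 1 / 6)
        y = 2 + np.cos(2 * np.pi * t / 24 + 0.5) + 0.1 * rng.standard_normal(t.size)
        f1 = cosinor_fit(t, y, 24.0)
        f2 = cosinor_fit(t, 2 * y, 24.0)
        assert f2.mesor == pytest.approx(2 * f1.mesor)
        assert f2.amplitude == pytest.approx(2 * f1.amplitude)
        assert circular_distance_deg(f2.theta_deg, f1.theta_deg) < 1e-9

    def test_missing_bins_dropped(self):
        t = np.arange(0, 48, 1 / 6)
        y = 2 + np.cos(2 * np.pi * t / 24)
        y[::5] = np.nan
        f = cosinor_fit(t, y, 24.0)
        assert f.amplitude == pytest.approx(1.0, abs=1e-9)
        assert f.n == np.isfinite(y).sum()

    def test_singular_design_rejected(self):
        t = np.full(20, 3.0)  # all observations at one phase
        with pytest.raises(ParameterError, match="singular"):
            cosinor_fit(t, np.ones(20), 24.0)

    def test_acrophase_matches_peak_time(self):
        # peak placed 6 h after lights-off -> acrophase 90 deg for a 24-h cycle
        t = np.arange(0, 48, 1 / 6)
        y = 1 + np.cos(2 * np.pi * (t - 6.0) / 24)
        f = cosinor_fit(t, y, 24.0)
        assert f.acrophase_deg == pytest.approx(90.0, abs=1e-6)
        assert f.acrophase_h == pytest.approx(6.0, abs=1e-6)


class TestGroupCosinor:
    t = np.arange(0, 48, 1 / 6)

    def _fit(self, rng, amp=1.0, noise=0.3):
        y = 2 + amp * np.cos(2 * np.pi * self.t / 24 + np.radians(40))
        y = y + noise * rng.standard_normal(self.t.size)
        return cosinor_fit(self.t, y, 24.0)

    def test_identical_fits_reproduced(self):
        y = 2 + np.cos(2 * np.pi * self.t / 24 + 0.3)
        fits = [cosinor_fit(self.t, y, 24.0)] * 4
        g = group_cosinor(fits)
        assert g.amplitude == pytest.approx(fits[0].amplitude, rel=1e-9)
        assert circular_distance_deg(g.theta_deg, fits[0].theta_deg) < 1e-9

    def test_needs_three_fits(self):
        y = 2 + np.cos(2 * np.pi * self.t / 24)
        with pytest.raises(StructureError):
            group_cosinor([cosinor_fit(self.t, y, 24.0)] * 2)

    def test_mixed_period_rejected(self):
        y = 2 + np.cos(2 * np.pi * self.t / 24)
        f24 = cosinor_fit(self.t, y, 24.0)
        f21 = cosinor_fit(self.t, y, 21.0)
        with pytest.raises(StructureError):
            group_cosinor([f24, f24, f21])

    def test_confidence_region_coverage(self):
        """The 95% bivariate region covers the true (beta, gamma) in about
        95% of replicates (n=6 subjects)."""
        rng = np.random.default_rng(1)
        truth_beta = 1.0 * np.cos(np.radians(40))
        truth_gamma = -1.0 * np.sin(np.radians(40))
        cover = 0
        n_rep = 200
        for _ in range(n_rep):
            g = group_cosinor([self._fit(rng) for _ in range(6)])
            cover += g.covers(truth_beta, truth_gamma, 0.95)
        assert 0.88 <= cover / n_rep <= 0.99

    def test_amplitude_difference_power(self):
        """A = 1 vs A = 0 with n = 6 is detected in most replicates."""
        rng = np.random.default_rng(2)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            ga = group_cosinor([self._fit(rng, amp=1.0) for _ in range(6)])
            gb = group_cosinor([self._fit(rng, amp=0.0) for _ in range(6)])
            if compare_group_cosinor(ga, gb)["p"] < 0.05:
                hits += 1
        assert hits / n_rep > 0.8

    def test_zero_amplitude_test_calibrated_direction(self):
        rng = np.random.default_rng(3)
        g1 = group_cosinor([self._fit(rng, amp=1.0) for _ in range(6)])
        g0 = group_cosinor([self._fit(rng, amp=0.0, noise=0.5) for _ in range(6)])
        assert g1.p_zero_amplitude < 0.01
        assert g0.p_zero_amplitude > g1.p_zero_amplitude
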