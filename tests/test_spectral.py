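"""State spectra, filter bank, band power, cluster-corrected comparison."""
import numpy as np
import pytest

from circasleep import (
    Hypnogram,
    Recording,
    StructureError,
    compare_spectra,
    make_schedule,
    state_spectra,
)
from circasleep.spectral import (
    EDGE,
    AnalyticBandSeries,
    StateSpectrum,
    analytic_band,
    band_power_series,
    epoch_psd,
    filterbank_hilbert,
)

FS = 200.0


def _rec(x, schedule=None):
    return Recording(eeg=x, emg=np.zeros_like(x), fs=FS, schedule=schedule)


class TestEpochPSD:
    def test_sine_peak_on_grid(self):
        t = np.arange(80000) / FS
        f, p = epoch_psd(_rec(np.sin(2 * np.pi * 10.0 * t)))
        assert f[np.argmax(p.mean(axis=0))] == pytest.approx(10.0, abs=200.0 / 512)

    def test_resolution(self):
        f, _ = epoch_psd(_rec(np.zeros(1600)))
        assert np.diff(f)[0] == pytest.approx(200.0 / 512)
        assert f[-1] <= 50.0


class TestStateSpectra:
    sched = make_schedule(24.0, 0.5, n_days=1)

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(800 * 200)
        hyp = Hypnogram(states=np.full(200, "W"))
        a = state_spectra(_rec(x, self.sched), hyp)["W"].psd
        b = state_spectra(_rec(2 * x, self.sched), hyp)["W"].psd
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_missing_state_flagged(self):
        x = np.random.default_rng(1).standard_normal(800 * 30)
        hyp = Hypnogram(states=np.full(30, "W"))
        with pytest.warns(UserWarning, match="no N epochs"):
            sp = state_spectra(_rec(x, self.sched), hyp)
        assert sp["N"].missing and np.isnan(sp["N"].psd).all()
        assert not sp["W"].missing

    def test_white_noise_flat(self):
        """Normalized PSD of unfiltered white noise is flat within 10% over
        1-45 Hz."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal(800 * 2000)
        hyp = Hypnogram(states=np.full(2000, "W"))
        sp = state_spectra(_rec(x, self.sched), hyp, last_n_days=None)["W"]
        sel = (sp.freqs >= 1.0) & (sp.freqs <= 45.0)
        band = sp.psd[sel]
        assert band.max() / band.mean() < 1.10
        assert band.min() / band.mean() > 0.90


class TestFilterBank:
    def test_sine_phase_and_power(self):
        t = np.arange(8000) / FS
        x = np.cos(2 * np.pi * 8.0 * t)
        ph, pw = analytic_band(x, 7.5, 8.5, FS)
        mid = slice(EDGE, 8000 - EDGE)
        # power approximately constant at (amplitude/... )^2
        assert pw[mid].std() / pw[mid].mean() < 0.02
        # phase advances 2*pi*8 per second
        slope = np.median(np.diff(np.unwrap(ph[mid]))) * FS
        assert slope == pytest.approx(2 * np.pi * 8.0, rel=1e-3)
        # convention: phase of cos(2 pi 8 t) equals 2 pi 8 t (wrapped)
        k = 3000
        expected = np.angle(np.exp(1j * 2 * np.pi * 8.0 * t[k]))
        assert np.angle(np.exp(1j * (ph[k] - expected))) == pytest.approx(0.0, abs=0.05)

    def test_stopband(self):
        t = np.arange(8000) / FS
        x = np.sin(2 * np.pi * 8.0 * t)
        _, p8 = analytic_band(x, 7.5, 8.5, FS)
        _, p20 = analytic_band(x, 19.5, 20.5, FS)
        mid = slice(EDGE, 8000 - EDGE)
        assert p20[mid].mean() < 0.01 * p8[mid].mean()

    def test_out_of_band_invariance(self):
        rng = np.random.default_rng(3)
        t = np.arange(8000) / FS
        x = np.sin(2 * np.pi * 8.0 * t) + 0.1 * rng.standard_normal(8000)
        y = x + np.sin(2 * np.pi * 30.0 * t)
        mid = slice(EDGE, 8000 - EDGE)
        _, px = analytic_band(x, 7.5, 8.5, FS)
        _, py = analytic_band(y, 7.5, 8.5, FS)
        assert abs(py[mid].mean() - px[mid].mean()) / px[mid].mean() < 0.01

    def test_too_short_raises(self):
        with pytest.raises(StructureError):
            filterbank_hilbert(_rec(np.zeros(2000)), centers=[8.0])

    def test_parseval_consistency(self):
        """Sum of bank band powers approximates broadband variance within
        15% for band-limited noise (FIR overlap caveat)."""
        rng = np.random.default_rng(4)
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [5.0, 40.0], btype="bandpass", fs=FS, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(40000))
        fb = filterbank_hilbert(_rec(x), centers=np.arange(2.0, 51.0))
        mid = fb.valid_mask()
        total = (fb.power[:, mid] / 2.0).sum(axis=0).mean()  # analytic power = 2x variance
        var = x[mid].var()
        assert abs(total - var) / var < 0.15


class TestBandPower:
    def _abs(self, power, fs=FS):
        n = power.size
        return AnalyticBandSeries(
            bands=np.array([[7.5, 8.5]]),
            power=power.reshape(1, n).astype(np.float32),
            phase=None,
            fs=fs,
        )

    def test_constant_power_no_norm(self):
        n = int(3600 * FS)
        bp = band_power_series(self._abs(np.full(n, 4.0)), (7.5, 8.5), bin_s=600.0)
        vals = bp.value[np.isfinite(bp.value)]
        assert np.allclose(vals, 4.0)

    def test_median_ld12_norm_halves(self):
        n = int(3600 * FS)
        a = band_power_series(self._abs(np.full(n, 4.0)), (7.5, 8.5), bin_s=600.0)
        b = band_power_series(
            self._abs(np.full(n, 4.0)), (7.5, 8.5), bin_s=600.0,
            norm="median_ld12", norm_value=4.0,
        )
        np.testing.assert_allclose(b.value, a.value / 4.0)

    def test_missing_bins_not_fabricated(self):
        n = int(1800 * FS)
        mask = np.zeros(n, dtype=bool)
        mask[: n // 3] = True  # only the first 10 min in-state
        bp = band_power_series(
            self._abs(np.full(n, 2.0)), (7.5, 8.5), state_mask=mask, bin_s=600.0
        )
        assert np.isfinite(bp.value[0])
        assert np.isnan(bp.value[1:]).all()

    def test_unknown_norm(self):
        with pytest.raises(Exception, match="norm"):
            band_power_series(
                self._abs(np.full(int(600 * FS), 1.0)), (7.5, 8.5), norm="weird"
            )


class TestCompareSpectra:
    @staticmethod
    def _subject_spectra(rng, n_subjects, boost=None):
        out = []
        freqs = None
        for _ in range(n_subjects):
            x = rng.standard_normal(800 * 200)
            if boost is not None:
                from scipy.signal import butter, sosfiltfilt

                sos = butter(4, [2.0, 4.0], btype="bandpass", fs=FS, output="sos")
                x = x + boost * sosfiltfilt(sos, rng.standard_normal(x.size))
            f, p = epoch_psd(_rec(x))
            freqs = f
            out.append(StateSpectrum(state="W", freqs=f, psd=p.mean(axis=0),
                                     n_epochs=p.shape[0]))
        return freqs, out

    def test_identical_conditions_no_clusters(self):
        rng = np.random.default_rng(5)
        _, a = self._subject_spectra(rng, 4)
        res = compare_spectra(a, a, n_perm=200, seed=0)
        assert res.clusters == []

    def test_injected_delta_power_detected(self):
        rng = np.random.default_rng(6)
        freqs, a = self._subject_spectra(rng, 6)
        _, b = self._subject_spectra(rng, 6, boost=0.6)
        res = compare_spectra(a, b, n_perm=500, seed=1)
        sig = res.significant(0.05)
        assert sig, "expected a significant cluster"
        lo, hi = sig[0].bounds(res.t_map.shape)[0]
        assert freqs[lo] <= 4.0 and freqs[hi] >= 2.0

    def test_unpaired_rejected(self):
        rng = np.random.default_rng(7)
        _, a = self._subject_spectra(rng, 4)
        _, b = self._subject_spectra(rng, 3)
        with pytest.raises(StructureError):
            compare_spectra(a, b)
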