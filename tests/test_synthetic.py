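"""Generator ground truth: schedules, hypnograms, signals, activity."""
import numpy as np
import pytest
from scipy import stats

from circasleep import (
    Hypnogram,
    ParameterError,
    make_schedule,
    preprocess,
    simulate_activity,
    simulate_eeg_emg,
    simulate_hypnogram,
)
from circasleep.pac import pacz
from circasleep.spectral import analytic_band, epoch_psd
from circasleep.synthetic import (
    SimParams,
    stationary_distribution,
    swa_power_envelope,
)


class TestSchedule:
    def test_ld12_alternates_dark_then_light(self):
        s = make_schedule(24.0, 0.5, n_days=7)
        assert s.duration_h == 168.0
        assert not s.is_photophase(0.0)  # lights off at t=0
        assert not s.is_photophase(11.99)
        assert s.is_photophase(12.01)
        assert s.is_photophase(23.99)
        assert not s.is_photophase(24.01)  # next cycle starts dark

    def test_21h_tiling_drifts_3h_per_day(self):
        s = make_schedule(21.0, 0.5, n_days=14)
        # cycle boundary after one cycle is at 21 h, i.e. 3 h before midnight
        assert not s.is_photophase(21.5)  # second cycle, scotophase
        assert s.is_photophase(10.6)  # 10.5 h into first cycle -> light
        assert np.array_equal(s.cycle_index([0.0, 20.9, 21.1]), [0, 0, 1])

    def test_dd_all_scotophase(self):
        s = make_schedule(None, n_days=7)
        assert s.duration_h == 168.0
        t = np.linspace(0, 168, 1000)
        assert not s.is_photophase(t).any()

    def test_partition_fraction(self):
        s = make_schedule(22.0, 0.4, n_days=11)
        t = np.arange(0, s.duration_h, 0.01)
        frac = s.is_photophase(t).mean()
        assert frac == pytest.approx(0.4, abs=0.01)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"period_h": -5.0},
            {"period_h": 24.0, "photofraction": 1.5},
            {"period_h": 24.0, "n_days": 0},
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ParameterError):
            make_schedule(**{"photofraction": 0.5, "n_days": 1, **kwargs})


class TestHypnogram:
    def test_identity_matrix_stays_wake(self, ld12):
        params = SimParams()
        params.transitions = {
            k: np.eye(3) for k in ("photophase", "scotophase")
        }
        hyp = simulate_hypnogram(ld12, params, seed=0)
        assert (hyp.states == "W").all()

    def test_wake_to_rem_forbidden(self, ld12):
        params = SimParams()
        params.transitions["photophase"][0] = [0.9, 0.05, 0.05]
        with pytest.raises(ParameterError, match="REM"):
            simulate_hypnogram(ld12, params, seed=0)

    def test_determinism(self, ld12, default_params):
        a = simulate_hypnogram(ld12, default_params, seed=42)
        b = simulate_hypnogram(ld12, default_params, seed=42)
        assert np.array_equal(a.states, b.states)
        assert not np.array_equal(
            a.states, simulate_hypnogram(ld12, default_params, seed=43).states
        )

    def test_phase_dependent_fractions_match_stationary(self, default_params):
        """Sleep-favoring photophase rates produce more NREM in the light,
        and long-run fractions agree with the chains' stationary laws."""
        sched = make_schedule(24.0, 0.5, n_days=10)
        hyp = simulate_hypnogram(sched, default_params, seed=7)
        photo = sched.is_photophase(hyp.epoch_times_h())
        for phase, mask in (("photophase", photo), ("scotophase", ~photo)):
            pi = stationary_distribution(default_params.transitions[phase])
            counts = np.array([(hyp.states[mask] == s).sum() for s in "WNR"])
            chi2 = stats.chisquare(counts, pi * counts.sum())
            # agreement up to Markov-chain autocorrelation: compare fractions
            assert np.allclose(counts / counts.sum(), pi, atol=0.03), (
                phase, counts / counts.sum(), pi, chi2)
        frac_n_photo = (hyp.states[photo] == "N").mean()
        frac_n_scoto = (hyp.states[~photo] == "N").mean()
        assert frac_n_photo > frac_n_scoto


class TestEEG:
    def test_determinism(self, ld12, default_params):
        hyp = Hypnogram(states=np.full(60, "W"))
        a = simulate_eeg_emg(hyp, ld12, default_params, seed=3)
        b = simulate_eeg_emg(hyp, ld12, default_params, seed=3)
        assert np.array_equal(a.eeg, b.eeg) and np.array_equal(a.emg, b.emg)

    def test_length_mismatch_raises(self, ld12, default_params):
        n_too_many = int(25 * 3600 / 4)
        hyp = Hypnogram(states=np.full(n_too_many, "W"))
        with pytest.raises(Exception, match="longer than the schedule"):
            simulate_eeg_emg(hyp, ld12, default_params, seed=0)

    @pytest.mark.parametrize(
        "state,band", [("N", (1.0, 4.0)), ("R", (7.0, 9.5))]
    )
    def test_state_spectral_signature(self, ld12, state, band):
        """Pure-NREM signal peaks in the SWA band, pure-REM in theta."""
        hyp = Hypnogram(states=np.full(150, state))
        rec = simulate_eeg_emg(hyp, ld12, SimParams(), seed=9)
        freqs, psd = epoch_psd(rec)
        mean = psd.mean(axis=0)
        peak = freqs[(freqs > 0.5)][np.argmax(mean[freqs > 0.5])]
        assert band[0] <= peak <= band[1]

    def test_emg_rms_ordering(self, ld12, default_params):
        states = np.array(["W"] * 50 + ["N"] * 50 + ["R"] * 50)
        rec = simulate_eeg_emg(Hypnogram(states=states), ld12, default_params, seed=1)
        seg = rec.emg.reshape(150, 800)
        rms = np.sqrt((seg**2).mean(axis=1))
        w, n, r = rms[:50].mean(), rms[50:100].mean(), rms[100:].mean()
        assert w > n > r

    def test_swa_envelope_obeys_decay_and_buildup(self, ld12):
        """With noise off, the imposed NREM SWA envelope equals the decay
        law times the logistic onset rise, checked against a direct
        per-sample recomputation."""
        params = SimParams(noise_sd=0.0, swa_decay=(2.0, 0.5, 1.0))
        states = np.array((["W"] * 30 + ["N"] * 60) * 3)
        hyp = Hypnogram(states=states)
        env = swa_power_envelope(hyp, params, fs=200.0)

        # independent oracle: loop over samples
        fs = 200.0
        swa0, tau, swa_inf = params.swa_decay
        bmin, bmax, log_t50, slope = params.buildup
        codes = np.repeat([0 if s == "W" else 1 for s in states], 800)
        t_sleep = 0.0
        age = 0.0
        expect = np.full(codes.size, np.nan)
        for i, c in enumerate(codes):
            if c == 1:
                # age = samples since episode onset / fs (0 at the onset
                # sample, clamped to one sample inside the logistic)
                age = age + 1.0 / fs if i > 0 and codes[i - 1] == 1 else 0.0
                t_sleep += 1.0 / fs
                d = swa0 * np.exp(-(t_sleep / 3600.0) / tau) + swa_inf
                g = 1.0 / (1.0 + 10.0 ** ((log_t50 - np.log10(max(age, 1 / fs))) * slope))
                r0 = bmin / bmax
                expect[i] = d * (r0 + (1 - r0) * g)
        assert np.allclose(env, expect, equal_nan=True, atol=1e-9)

    def test_coupling_monotone_in_kappa(self, ld12):
        """Median wake theta-gamma PACz is non-decreasing in kappa."""
        seeds = range(20)
        kappas = [0.0, 0.2, 0.4, 0.8]
        hyp = Hypnogram(states=np.full(45, "W"))  # 3 min
        z = np.zeros((len(seeds), len(kappas)))
        for i, seed in enumerate(seeds):
            for j, k in enumerate(kappas):
                params = SimParams(coupling_kappa=k)
                rec = preprocess(simulate_eeg_emg(hyp, ld12, params, seed=100 + seed))
                ph, _ = analytic_band(rec.eeg, 7.5, 8.5, rec.fs)
                _, pw = analytic_band(rec.eeg, 28.0, 46.0, rec.fs)
                sl = slice(800, 800 + 12000)
                z[i, j] = pacz(ph[sl], pw[sl], n_surrogates=200, seed=seed)
        med = np.median(z, axis=0)
        assert np.all(np.diff(med) >= 0), med
        rho, p = stats.spearmanr(
            np.repeat(kappas, len(list(seeds))), z.T.ravel()
        )
        assert rho > 0 and p < 1e-6


class TestActivity:
    def test_constant_when_noise_free(self, ld12):
        act = simulate_activity(ld12, 24.0, amplitude=0.0, mesor=2.0, seed=0,
                                noise_sd=0.0)
        assert np.allclose(act.distance, 2.0)

    def test_nonnegative_and_deterministic(self, ld12):
        a = simulate_activity(ld12, 24.0, seed=5)
        b = simulate_activity(ld12, 24.0, seed=5)
        assert (a.distance >= 0).all()
        assert np.array_equal(a.distance, b.distance)

    def test_concentrated_in_scotophase(self, ld12):
        act = simulate_activity(ld12, 24.0, amplitude=1.0, mesor=1.0, seed=2)
        photo = ld12.is_photophase(act.t_h())
        assert act.distance[~photo].mean() > act.distance[photo].mean()

    def test_invalid_params(self, ld12):
        with pytest.raises(ParameterError):
            simulate_activity(ld12, -24.0)
        with pytest.raises(ParameterError):
            simulate_activity(ld12, 24.0, amplitude=-1.0)
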