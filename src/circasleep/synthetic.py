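"""Synthetic schedules, hypnograms, EEG/EMG signals, and activity traces.

Every statistical structure the downstream analyses assume is generated here
with known ground truth:

* vigilance states follow a phase-of-day-dependent first-order Markov chain
  on 4-s epochs (REM entered only from NREM, the biological constraint);
* EEG is a sum of state-dependent narrowband oscillations — slow-wave
  activity (SWA, ~1-4 Hz) in NREM, theta (7-9.5 Hz) in REM and wake, and a
  30-45 Hz gamma component in wake — plus Gaussian broadband noise;
* gamma amplitude in wake is modulated by the instantaneous theta phase with
  depth ``kappa`` (theta-gamma phase-amplitude coupling);
* theta/gamma base amplitudes carry a sinusoidal modulation at the zeitgeber
  period (the circadian rhythm the cosinor analysis estimates);
* the NREM SWA power envelope follows the two-process decay
  ``SWA0 * exp(-t_sleep/tau) + SWAinf`` over accumulated NREM time, times a
  logistic rise over ~50 s at each NREM-episode onset;
* EMG is band-limited (20-90 Hz) noise with state-dependent RMS
  (wake : NREM : REM = 5 : 1 : 0.5);
* locomotor activity is a rectified cosine at the entrained period plus
  noise, peaking mid-scotophase.

Narrowband carriers are frequency-modulated (center +/- ~0.5 Hz) rather than
pure sines so that filter-bank phase estimation and surrogate tests downstream
are non-degenerate.  All generators take an explicit seed and use a single
local RNG stream; identical inputs give bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .core import (
    EPOCH_S,
    FS,
    NREM,
    REM,
    STATES,
    WAKE,
    ActivitySeries,
    Hypnogram,
    LightSchedule,
    ParameterError,
    Recording,
    StructureError,
)

__all__ = [
    "SimParams",
    "make_schedule",
    "simulate_hypnogram",
    "simulate_eeg_emg",
    "simulate_activity",
    "swa_power_envelope",
    "stationary_distribution",
]

#: default per-epoch transition matrices, rows/cols ordered (W, N, R).
#: Photophase (rest phase of a nocturnal animal) favors sleep; scotophase
#: favors wake.  Row-stochastic; W->R is structurally zero.
_TRANS_PHOTO = np.array(
    [
        [0.920, 0.080, 0.000],
        [0.040, 0.930, 0.030],
        [0.050, 0.050, 0.900],
    ]
)
_TRANS_SCOTO = np.array(
    [
        [0.970, 0.030, 0.000],
        [0.080, 0.905, 0.015],
        [0.070, 0.030, 0.900],
    ]
)


def _default_transitions() -> Dict[str, np.ndarray]:
    return {"photophase": _TRANS_PHOTO.copy(), "scotophase": _TRANS_SCOTO.copy()}


def _default_band_amp() -> Dict[str, Dict[str, float]]:
    # Oscillation amplitudes (a.u.) per state; SWA in NREM is further shaped
    # by the homeostatic envelope.
    return {
        "W": {"swa": 0.15, "theta": 1.00, "gamma": 0.50},
        "N": {"swa": 2.00, "theta": 0.30, "gamma": 0.10},
        "R": {"swa": 0.10, "theta": 1.20, "gamma": 0.15},
    }


def _default_circadian() -> Dict[str, Tuple[float, float]]:
    # band -> (relative modulation depth, acrophase as cycle fraction after
    # lights-off).  0.25 = mid-scotophase for a symmetric cycle.
    return {"theta": (0.4, 0.25), "gamma": (0.4, 0.25)}


@dataclass
class SimParams:
    """Ground-truth parameters of the synthetic experiment.

    Attributes
    ----------
    transitions:
        Per-epoch state-transition matrices, one per phase of day
        ("photophase" / "scotophase"); rows (from-state) must sum to 1 and the
        W->R entry must be 0.
    band_amp:
        state -> {band -> oscillation amplitude}.
    coupling_kappa:
        Depth of theta-phase modulation of gamma amplitude in wake, in [0, 1];
        0 produces statistically uncoupled theta phase and gamma amplitude.
    circadian_mod:
        band -> (relative amplitude, acrophase as fraction of the zeitgeber
        cycle after lights-off) for the theta/gamma base amplitudes.
    swa_decay:
        (SWA0, tau_h, SWAinf): two-process decay of the relative NREM SWA
        power envelope over accumulated NREM time.
    buildup:
        (min, max, log10_t50_s, slope): logistic rise of SWA power at each
        NREM-episode onset; defaults reach >95% of the range by 50 s.
    noise_sd:
        SD of the broadband Gaussian EEG noise (a.u.).
    emg_rms:
        state -> target EMG RMS (a.u.).
    """

    transitions: Dict[str, np.ndarray] = field(default_factory=_default_transitions)
    band_amp: Dict[str, Dict[str, float]] = field(default_factory=_default_band_amp)
    coupling_kappa: float = 0.6
    circadian_mod: Dict[str, Tuple[float, float]] = field(
        default_factory=_default_circadian
    )
    swa_decay: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    buildup: Tuple[float, float, float, float] = (0.05, 1.0, 1.0, 2.0)  # t50 = 10 s
    noise_sd: float = 0.30
    emg_rms: Dict[str, float] = field(
        default_factory=lambda: {"W": 1.0, "N": 0.2, "R": 0.1}
    )
    theta_f0: float = 8.0
    gamma_f0: float = 37.5
    swa_f0: float = 2.5

    def validate(self) -> None:
        for phase, mat in self.transitions.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (3, 3):
                raise ParameterError(f"{phase}: transition matrix must be 3x3")
            if np.any(mat < 0) or np.any(mat > 1):
                raise ParameterError(f"{phase}: probabilities must lie in [0, 1]")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ParameterError(f"{phase}: transition rows must sum to 1")
            if mat[WAKE, REM] != 0.0:
                raise ParameterError(
                    f"{phase}: direct W->R transitions are not allowed "
                    "(REM is entered only from NREM)"
                )
        if not 0.0 <= self.coupling_kappa <= 1.0:
            raise ParameterError("coupling_kappa must lie in [0, 1]")
        swa0, tau, swainf = self.swa_decay
        if tau <= 0:
            raise ParameterError("swa_decay tau must be > 0")
        if swa0 < 0 or swainf < 0:
            raise ParameterError("swa_decay levels must be >= 0")
        bmin, bmax, _, _ = self.buildup
        if bmax < bmin:
            raise ParameterError("buildup max must be >= min")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------

def make_schedule(
    period_h: Optional[float],
    photofraction: float = 0.5,
    n_days: int = 1,
    lights_off_clock_h: float = 8.5,
) -> LightSchedule:
    """Build a light-dark schedule (``period_h=None`` for constant darkness).

    The schedule covers ``n_days`` astronomic (24-h) days, tiled by cycles of
    ``period_h`` hours that each begin with the scotophase at the (wall-clock)
    lights-off time.  For a shortened cycle the lights-off boundary therefore
    drifts earlier by ``24 - period_h`` hours per astronomic day.
    """
    return LightSchedule(
        period_h=period_h,
        photofraction=photofraction,
        n_days=n_days,
        lights_off_clock_h=lights_off_clock_h,
    )


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    mat = np.asarray(matrix, dtype=float)
    w, v = np.linalg.eig(mat.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Hypnogram
# ---------------------------------------------------------------------------

def simulate_hypnogram(
    schedule: LightSchedule,
    params: SimParams,
    seed: int,
    start_state: str = "W",
    duration_h: Optional[float] = None,
) -> Hypnogram:
    """Draw a hypnogram from the phase-of-day-dependent Markov chain.

    ``duration_h`` (default: the schedule's full span) lets a recording
    cover only the leading part of the schedule, e.g. a whole number of
    zeitgeber cycles.
    """
    params.validate()
    if duration_h is None:
        duration_h = schedule.duration_h
    if duration_h > schedule.duration_h + 1e-9:
        raise StructureError("requested duration exceeds the schedule span")
    rng = np.random.default_rng(seed)
    n_epochs = int(np.floor(duration_h * 3600.0 / EPOCH_S))
    t_h = np.arange(n_epochs) * EPOCH_S / 3600.0
    photo = schedule.is_photophase(t_h)

    cum = {
        phase: np.cumsum(np.asarray(mat, dtype=float), axis=1)
        for phase, mat in params.transitions.items()
    }
    cum_photo, cum_scoto = cum["photophase"], cum["scotophase"]
    u = rng.random(n_epochs)

    states = np.empty(n_epochs, dtype=np.int64)
    s = STATES.index(start_state)
    for i in range(n_epochs):
        rows = cum_photo if photo[i] else cum_scoto
        s = int(np.searchsorted(rows[s], u[i], side="right"))
        states[i] = s
    return Hypnogram(
        states=np.array(STATES)[states], epoch_s=EPOCH_S, provenance="simulated"
    )


# ---------------------------------------------------------------------------
# EEG / EMG
# ---------------------------------------------------------------------------

def _smooth_jitter(rng: np.random.Generator, n: int, fs: float, sd_hz: float,
                   clip_hz: float, rate_hz: float = 1.0) -> np.ndarray:
    """Slowly varying frequency jitter: coarse Gaussian noise held constant
    over ``1/rate_hz`` windows, scaled to ``sd_hz``, clipped at
    ``+/- clip_hz``.  Piecewise-constant instantaneous frequency gives a
    piecewise-linear carrier phase — smooth enough for the filter bank while
    keeping generation cheap on multi-hour signals."""
    hold = max(int(round(fs / rate_hz)), 1)
    n_coarse = -(-n // hold)
    coarse = np.clip(rng.standard_normal(n_coarse) * sd_hz, -clip_hz, clip_hz)
    return np.repeat(coarse, hold)[:n]


def _fm_phase(rng: np.random.Generator, n: int, fs: float, f0: float,
              jitter_sd: float = 0.25, jitter_clip: float = 0.5) -> np.ndarray:
    """Instantaneous phase of a frequency-modulated carrier around ``f0``."""
    f_inst = f0 + _smooth_jitter(rng, n, fs, jitter_sd, jitter_clip)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    return phase0 + 2.0 * np.pi * np.cumsum(f_inst) / fs


def _nrem_episode_age_s(state_codes: np.ndarray, fs: float) -> np.ndarray:
    """Seconds since the onset of the current NREM episode (0 elsewhere)."""
    n = state_codes.size
    is_n = state_codes == NREM
    prev = np.concatenate(([False], is_n[:-1]))
    onset = is_n & ~prev
    idx = np.arange(n)
    last_onset = np.maximum.accumulate(np.where(onset, idx, -1))
    age = np.where(is_n & (last_onset >= 0), idx - last_onset, 0)
    return age / fs


def swa_power_envelope(
    hypnogram: Hypnogram, params: SimParams, fs: float = FS
) -> np.ndarray:
    """Per-sample relative SWA power envelope the generator imposes in NREM.

    Returns ``(SWA0 * exp(-t_sleep/tau) + SWAinf) * g(t_episode)`` on NREM
    samples and NaN elsewhere, where ``t_sleep`` is accumulated NREM time and
    ``g`` the logistic onset rise scaled to plateau at 1.
    """
    codes = hypnogram.sample_states(fs)
    is_n = codes == NREM
    swa0, tau_h, swainf = params.swa_decay
    t_sleep_h = np.cumsum(is_n)[is_n] / fs / 3600.0
    decay = swa0 * np.exp(-t_sleep_h / tau_h) + swainf

    bmin, bmax, log_t50, slope = params.buildup
    age_s = np.maximum(_nrem_episode_age_s(codes, fs)[is_n], 1.0 / fs)
    logistic = 1.0 / (1.0 + 10.0 ** ((log_t50 - np.log10(age_s)) * slope))
    r0 = bmin / bmax if bmax > 0 else 0.0
    rise = r0 + (1.0 - r0) * logistic

    env = np.full(codes.size, np.nan)
    env[is_n] = decay * rise
    return env


def simulate_eeg_emg(
    hypnogram: Hypnogram,
    schedule: LightSchedule,
    params: SimParams,
    seed: int,
    fs: float = FS,
) -> Recording:
    """Synthesize the EEG/EMG recording matching a hypnogram and schedule."""
    params.validate()
    n_epoch_samples = int(round(hypnogram.epoch_s * fs))
    n = len(hypnogram) * n_epoch_samples
    expected_epochs = int(np.floor(schedule.duration_h * 3600.0 / hypnogram.epoch_s))
    if len(hypnogram) > expected_epochs:
        raise StructureError(
            f"hypnogram ({len(hypnogram)} epochs) is longer than the schedule "
            f"({expected_epochs} epochs)"
        )
    rng = np.random.default_rng(seed)
    codes = hypnogram.sample_states(fs)

    def state_amp(band: str) -> np.ndarray:
        lut = np.array([params.band_amp[s][band] for s in STATES])
        return lut[codes]

    period = 24.0 if schedule.is_dd else schedule.period_h

    def circadian(band: str) -> np.ndarray:
        if band not in params.circadian_mod:
            return np.ones(1)
        depth, acro_frac = params.circadian_mod[band]
        if depth == 0.0:
            return np.ones(1)
        # hours-scale modulation: evaluate per second and hold, not per sample
        hold = int(fs)
        t_coarse = np.arange(-(-n // hold)) / 3600.0
        coarse = 1.0 + depth * np.cos(2.0 * np.pi * (t_coarse / period - acro_frac))
        return np.repeat(coarse, hold)[:n]

    # --- theta (carrier phase reused for gamma-amplitude coupling) ---
    theta_phase = _fm_phase(rng, n, fs, params.theta_f0)
    eeg = state_amp("theta") * circadian("theta") * np.cos(theta_phase)

    # --- gamma, amplitude-modulated by theta phase during wake ---
    gamma_phase = _fm_phase(rng, n, fs, params.gamma_f0, jitter_sd=1.0,
                            jitter_clip=2.0)
    gamma_amp = state_amp("gamma") * circadian("gamma")
    if params.coupling_kappa > 0:
        mod = 1.0 + params.coupling_kappa * np.cos(theta_phase)
        gamma_amp = gamma_amp * np.where(codes == WAKE, mod, 1.0)
    eeg += gamma_amp * np.cos(gamma_phase)
    del gamma_amp, gamma_phase

    # --- SWA with the homeostatic envelope in NREM ---
    swa_phase = _fm_phase(rng, n, fs, params.swa_f0, jitter_sd=0.3,
                          jitter_clip=0.6)
    env = swa_power_envelope(hypnogram, params, fs)
    swa_scale = np.where(np.isnan(env), 1.0, np.sqrt(np.nan_to_num(env)))
    eeg += state_amp("swa") * swa_scale * np.cos(swa_phase)
    del swa_phase, env, swa_scale

    if params.noise_sd > 0:
        eeg += params.noise_sd * rng.standard_normal(n)

    # --- EMG: 20-90 Hz noise, state-dependent RMS ---
    from scipy.signal import butter, sosfiltfilt

    sos = butter(4, [20.0, 90.0], btype="bandpass", fs=fs, output="sos")
    emg = sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(emg**2))
    if rms > 0:
        emg /= rms
    lut = np.array([params.emg_rms[s] for s in STATES])
    emg *= lut[codes]

    return Recording(eeg=eeg, emg=emg, fs=fs, t0_h=0.0, schedule=schedule)


# ---------------------------------------------------------------------------
# Activity
# ---------------------------------------------------------------------------

def simulate_activity(
    schedule: LightSchedule,
    entrained_period_h: float,
    amplitude: float = 1.0,
    mesor: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.3,
    acrophase_frac: Optional[float] = None,
) -> ActivitySeries:
    """Rectified-cosine locomotor activity in 1-min bins.

    The cosine peaks ``acrophase_frac`` of a cycle after lights-off
    (default mid-scotophase), concentrating activity in the dark.
    """
    if entrained_period_h <= 0:
        raise ParameterError("entrained_period_h must be > 0")
    if amplitude < 0 or mesor < 0:
        raise ParameterError("amplitude and mesor must be >= 0")
    if acrophase_frac is None:
        acrophase_frac = (1.0 - schedule.photofraction) / 2.0
    rng = np.random.default_rng(seed)
    n_bins = int(np.floor(schedule.duration_h * 60.0))
    t_min = np.arange(n_bins) + 0.5
    t_h = t_min / 60.0
    y = mesor + amplitude * np.cos(
        2.0 * np.pi * (t_h / entrained_period_h - acrophase_frac)
    )
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(n_bins)
    return ActivitySeries(t_min=t_min, distance=np.maximum(y, 0.0))
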