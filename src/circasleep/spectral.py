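"""State-specific power spectra, filter-bank analytic signals, band power.

Spectra use the acquisition pipeline's FFT settings: 4-s epochs at 200 Hz
(800 samples) analyzed with 512-point Hann windows at 50% overlap and
averaged within the epoch (Welch), giving a 0.39-Hz grid over 0-50 Hz.
Per-state spectra are normalized by the median total (0-50 Hz) power across
all epochs of the same zeitgeber cycle and averaged over the last two cycles.

The analytic decomposition runs a bank of narrow linear-phase FIR band-pass
filters (default 1-Hz-wide bands centered 2-100 Hz, 1501 taps) followed by a
Hilbert transform, yielding instantaneous phase and power per band; the
half-filter-length edges are flagged invalid and excluded from every
downstream statistic.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import firwin, welch

from ._cluster import ClusterTestResult, paired_cluster_test
from .core import (
    ConfigurationError,
    Hypnogram,
    ParameterError,
    Recording,
    StructureError,
)

__all__ = [
    "StateSpectrum",
    "AnalyticBandSeries",
    "BandPowerSeries",
    "epoch_psd",
    "state_spectra",
    "filterbank_hilbert",
    "band_power_series",
    "median_band_power",
    "compare_spectra",
    "BAND_EDGES",
]

NPERSEG = 512
FMAX = 50.0
FIR_TAPS = 1501  # odd for an integer group delay; nominal length 1500
EDGE = FIR_TAPS // 2

#: default band edges (Hz); the acquisition never defines alpha/beta/gamma
#: numerically, so these are package configuration, not measurement facts.
BAND_EDGES: Dict[str, Tuple[float, float]] = {
    "swa": (1.0, 4.0),
    "theta": (7.0, 9.5),
    "alpha": (9.5, 15.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 45.0),
}


# ---------------------------------------------------------------------------
# Per-epoch PSD and state spectra
# ---------------------------------------------------------------------------

def epoch_psd(rec: Recording, epoch_s: float = 4.0):
    """Welch PSD of every 4-s epoch, restricted to 0-50 Hz.

    Returns ``(freqs, psd)`` with ``psd`` of shape ``(n_epochs, n_freqs)``.
    """
    epoch_len = int(round(epoch_s * rec.fs))
    n_epochs = rec.n_samples // epoch_len
    x = rec.eeg[: n_epochs * epoch_len].reshape(n_epochs, epoch_len)
    freqs, psd = welch(
        x,
        fs=rec.fs,
        window="hann",
        nperseg=NPERSEG,
        noverlap=NPERSEG // 2,
        detrend=False,
        axis=-1,
    )
    keep = freqs <= FMAX
    return freqs[keep], psd[:, keep]


@dataclass
class StateSpectrum:
    state: str
    freqs: np.ndarray
    psd: np.ndarray  #: normalized mean PSD per frequency
    n_epochs: int
    missing: bool = False


def state_spectra(
    rec: Recording,
    hypnogram: Hypnogram,
    last_n_days: Optional[int] = 2,
) -> Dict[str, StateSpectrum]:
    """Normalized per-state spectra averaged over the last ``last_n_days``
    zeitgeber cycles.

    Each epoch's PSD is divided by the median total (0-50 Hz) power over all
    epochs of the same cycle, then averaged within each vigilance state.
    States with no epochs are returned flagged missing.
    """
    if rec.schedule is None:
        raise ConfigurationError("recording has no schedule attached")
    freqs, psd = epoch_psd(rec)
    n_epochs = min(psd.shape[0], len(hypnogram))
    psd = psd[:n_epochs]
    states = hypnogram.states[:n_epochs]
    t_h = rec.t0_h + np.arange(n_epochs) * hypnogram.epoch_s / 3600.0
    cyc = rec.schedule.cycle_index(t_h)

    total = psd.sum(axis=1)
    norm = np.empty(n_epochs)
    for c in np.unique(cyc):
        m = cyc == c
        med = np.median(total[m])
        norm[m] = med if med > 0 else 1.0
    psd_n = psd / norm[:, None]

    if last_n_days is not None:
        cycles = np.unique(cyc)
        keep_cycles = set(cycles[-last_n_days:])
        sel = np.isin(cyc, list(keep_cycles))
    else:
        sel = np.ones(n_epochs, dtype=bool)

    out: Dict[str, StateSpectrum] = {}
    for s in ("W", "N", "R"):
        m = sel & (states == s)
        if not m.any():
            warnings.warn(f"no {s} epochs in the selected window", stacklevel=2)
            out[s] = StateSpectrum(
                state=s,
                freqs=freqs,
                psd=np.full(freqs.size, np.nan),
                n_epochs=0,
                missing=True,
            )
        else:
            out[s] = StateSpectrum(
                state=s, freqs=freqs, psd=psd_n[m].mean(axis=0), n_epochs=int(m.sum())
            )
    return out


# ---------------------------------------------------------------------------
# Filter bank + Hilbert
# ---------------------------------------------------------------------------

@dataclass
class AnalyticBandSeries:
    """Instantaneous phase and power per band from the FIR filter bank."""

    bands: np.ndarray  #: (n_bands, 2) low/high edges, Hz
    power: np.ndarray  #: (n_bands, n_samples), squared magnitude
    phase: Optional[np.ndarray]  #: (n_bands, n_samples), radians in (-pi, pi]
    fs: float
    t0_h: float = 0.0
    edge: int = EDGE  #: samples flagged edge-invalid at each end

    @property
    def centers(self) -> np.ndarray:
        return self.bands.mean(axis=1)

    @property
    def n_samples(self) -> int:
        return self.power.shape[1]

    def valid_mask(self) -> np.ndarray:
        m = np.zeros(self.n_samples, dtype=bool)
        m[self.edge : self.n_samples - self.edge] = True
        return m

    def band_index(self, lo: float, hi: float) -> np.ndarray:
        """Indices of bands whose centers fall within [lo, hi]."""
        c = self.centers
        idx = np.flatnonzero((c >= lo) & (c <= hi))
        if idx.size == 0:
            raise ParameterError(f"no filter-bank band inside [{lo}, {hi}] Hz")
        return idx


def design_bandpass(lo: float, hi: float, fs: float, numtaps: int = FIR_TAPS):
    """Linear-phase Hamming-windowed FIR band-pass."""
    return firwin(numtaps, [lo, hi], pass_zero=False, fs=fs, window="hamming")


def _quadrature_taps(lo: float, hi: float, fs: float,
                     numtaps: int = FIR_TAPS) -> np.ndarray:
    """Complex quadrature kernel of the band-pass: the Hamming lowpass
    prototype modulated to the band center.

    A windowed-sinc band-pass factors exactly as
    ``2 * cos(w_c (k - D)/fs) * lowpass(k)``; replacing the cosine with the
    complex exponential gives a time-limited kernel whose response sits only
    at positive frequencies (negative-frequency content at the window's
    stopband level), so convolution with it yields the band's analytic
    signal directly.
    """
    fc = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    lp = firwin(numtaps, half, fs=fs, window="hamming")
    k = np.arange(numtaps) - numtaps // 2
    return 2.0 * lp * np.exp(1j * 2.0 * np.pi * fc * k / fs)


def _analytic_oa(x: np.ndarray, taps_c: np.ndarray, fft_size: int = 1 << 15):
    """Convolution with the complex quadrature kernel via overlap-add.

    Small FFT blocks keep transforms cache-friendly, which matters on long
    (multi-hour) recordings where one monolithic FFT is memory-bound.  The
    kernel is (approximately) one-sided, so each block needs only the real
    input's positive-frequency spectrum.  Output is aligned "same" with the
    linear-phase group delay compensated.
    """
    n = x.size
    m = taps_c.size
    delay = m // 2
    seg_len = fft_size - m + 1
    if seg_len <= 0:
        raise ValueError("fft_size must exceed the filter length")
    h_pos = np.fft.fft(taps_c, fft_size)[: fft_size // 2 + 1]
    n_bins = h_pos.size
    spec = np.zeros(fft_size, dtype=np.complex128)
    out = np.zeros(n + m - 1, dtype=np.complex128)
    for start in range(0, n, seg_len):
        seg = x[start : start + seg_len]
        spec[:n_bins] = np.fft.rfft(seg, fft_size) * h_pos
        y = np.fft.ifft(spec)
        stop = min(start + fft_size, out.size)
        out[start:stop] += y[: stop - start]
    return out[delay : delay + n]


def analytic_signal(x: np.ndarray, lo: float, hi: float, fs: float) -> np.ndarray:
    """Complex analytic signal of one FIR band (group delay compensated)."""
    return _analytic_oa(np.asarray(x, dtype=float), _quadrature_taps(lo, hi, fs))


def analytic_band(x: np.ndarray, lo: float, hi: float, fs: float):
    """Phase and power of one band: FIR band-pass followed by the Hilbert
    transform."""
    a = analytic_signal(x, lo, hi, fs)
    return np.angle(a), np.abs(a) ** 2


def filterbank_hilbert(
    rec: Recording,
    bands: Optional[Sequence[Tuple[float, float]]] = None,
    centers: Optional[Sequence[float]] = None,
    keep_phase: bool = True,
) -> AnalyticBandSeries:
    """Analytic decomposition of the EEG over a bank of FIR band-passes.

    By default the bank spans 1-Hz-wide bands centered 2-100 Hz in 1-Hz
    steps; pass ``centers`` for a sub-grid or ``bands`` for arbitrary
    (lo, hi) edges.  ``keep_phase=False`` drops phase storage (halves memory)
    for power-only analyses.
    """
    x = rec.eeg
    if x.size < 2 * FIR_TAPS:
        raise StructureError(
            f"recording ({x.size} samples) shorter than twice the filter "
            f"length ({FIR_TAPS})"
        )
    if bands is None:
        if centers is None:
            centers = np.arange(2.0, 101.0, 1.0)
        bands = [(c - 0.5, c + 0.5) for c in centers]
    bands_arr = np.asarray(bands, dtype=float)
    n_b = bands_arr.shape[0]
    power = np.empty((n_b, x.size), dtype=np.float32)
    phase = np.empty((n_b, x.size), dtype=np.float32) if keep_phase else None
    for i, (lo, hi) in enumerate(bands_arr):
        ph, pw = analytic_band(x, lo, hi, rec.fs)
        power[i] = pw
        if phase is not None:
            phase[i] = ph
    return AnalyticBandSeries(
        bands=bands_arr, power=power, phase=phase, fs=rec.fs, t0_h=rec.t0_h
    )


# ---------------------------------------------------------------------------
# Band-power time series
# ---------------------------------------------------------------------------

@dataclass
class BandPowerSeries:
    band: Tuple[float, float]
    bin_s: float
    t_h: np.ndarray  #: bin centers, hours since first lights-off
    value: np.ndarray  #: NaN where the bin is missing
    n_valid: np.ndarray  #: qualifying samples per bin
    norm: str = "none"

    def dropna(self):
        m = np.isfinite(self.value)
        return self.t_h[m], self.value[m]


def erode_state_mask(mask: np.ndarray, margin: int = EDGE) -> np.ndarray:
    """Shrink every True run of a state mask by ``margin`` samples per side.

    Band-pass filtering smears energy over the filter's impulse response, so
    samples within half a filter length of a state transition carry power
    from the neighboring state.  When the hypnogram itself has circadian
    structure this contamination is rhythmic and can fake (or mask) a
    band-power rhythm; eroding the mask removes it at the cost of some data.
    """
    m = np.asarray(mask, dtype=bool)
    if margin <= 0 or not m.any():
        return m.copy()
    n = m.size
    out = np.zeros(n, dtype=bool)
    changes = np.flatnonzero(np.diff(m.astype(np.int8)))
    starts = np.concatenate(([0], changes + 1))
    ends = np.concatenate((changes + 1, [n]))
    for s, e in zip(starts, ends):
        if m[s] and e - s > 2 * margin:
            out[s + margin : e - margin] = True
    return out


def median_band_power(
    abs_: AnalyticBandSeries,
    band: Tuple[float, float],
    sample_mask: Optional[np.ndarray] = None,
) -> float:
    """Median instantaneous power in ``band`` over (masked) valid samples.

    This is the subject-wise reference used to normalize band-power series
    against the baseline LD12/12 condition.
    """
    idx = abs_.band_index(*band)
    m = abs_.valid_mask()
    if sample_mask is not None:
        m = m & sample_mask
    p = abs_.power[idx][:, m].mean(axis=0)
    return float(np.median(p))


def band_power_series(
    abs_: AnalyticBandSeries,
    band: Tuple[float, float],
    state_mask: Optional[np.ndarray] = None,
    bin_s: float = 600.0,
    norm: str = "none",
    norm_value: Optional[float] = None,
    photophase_mask: Optional[np.ndarray] = None,
    min_fraction: float = 0.5,
) -> BandPowerSeries:
    """Binned mean band power over in-state, edge-valid samples.

    Bins with fewer than ``min_fraction`` qualifying samples are missing
    (NaN), never filled from out-of-state samples.  ``norm`` is one of
    ``none``, ``median_ld12`` (divide by ``norm_value``, the subject's median
    power in this band under the baseline schedule) or ``median_photophase``
    (divide by the median over qualifying photophase samples, which requires
    ``photophase_mask``).
    """
    if norm not in {"none", "median_ld12", "median_photophase"}:
        raise ParameterError(f"unknown norm: {norm!r}")
    idx = abs_.band_index(*band)
    p = abs_.power[idx].mean(axis=0)
    n = p.size
    qual = abs_.valid_mask()
    if state_mask is not None:
        if state_mask.size != n:
            raise StructureError("state_mask length does not match the series")
        qual = qual & state_mask

    bin_len = int(round(bin_s * abs_.fs))
    n_bins = n // bin_len
    qual2 = qual[: n_bins * bin_len].reshape(n_bins, bin_len)
    p2 = p[: n_bins * bin_len].reshape(n_bins, bin_len)
    n_valid = qual2.sum(axis=1)
    with np.errstate(invalid="ignore"):
        value = np.where(qual2, p2, 0.0).sum(axis=1) / np.maximum(n_valid, 1)
    value = np.where(n_valid >= min_fraction * bin_len, value, np.nan)

    if norm == "median_ld12":
        if norm_value is None or norm_value <= 0:
            raise ParameterError("norm='median_ld12' requires a positive norm_value")
        value = value / norm_value
    elif norm == "median_photophase":
        if photophase_mask is None:
            raise ParameterError("norm='median_photophase' requires photophase_mask")
        m = qual & photophase_mask[:n]
        if not m.any():
            raise ParameterError("no qualifying photophase samples to normalize by")
        med = float(np.median(p[m]))
        value = value / (med if med > 0 else 1.0)

    t_h = abs_.t0_h + (np.arange(n_bins) + 0.5) * bin_s / 3600.0
    return BandPowerSeries(
        band=tuple(band), bin_s=bin_s, t_h=t_h, value=value, n_valid=n_valid,
        norm=norm,
    )


# ---------------------------------------------------------------------------
# Condition comparison of spectra
# ---------------------------------------------------------------------------

def compare_spectra(
    cond_a: List[StateSpectrum],
    cond_b: List[StateSpectrum],
    thresh_p: float = 0.01,
    cluster_p: float = 0.05,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> ClusterTestResult:
    """Cluster-corrected paired comparison of per-subject spectra.

    Per-frequency paired t-values thresholded at ``thresh_p`` form contiguous
    frequency clusters whose integrated t is referred to a sign-flip
    permutation null (same engine as the comodulogram comparison, with 1-D
    adjacency).  Clusters with ``p < cluster_p`` are the significant ones.
    """
    if len(cond_a) != len(cond_b):
        raise StructureError("conditions must contain the same subjects, paired")
    a = np.stack([s.psd for s in cond_a])
    b = np.stack([s.psd for s in cond_b])
    result = paired_cluster_test(a, b, thresh_p=thresh_p, n_perm=n_perm, seed=seed)
    return result
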