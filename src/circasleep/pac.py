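"""Theta-gamma phase-amplitude coupling (PAC).

The coupling statistic is the mean-vector-length modulation index

    MI = | sum_t a_t * exp(i * phi_t) | / n

between the instantaneous phase ``phi`` of a slow (carrier) band and the
instantaneous power ``a`` of a fast (modulated) band.  Raw MI depends on the
power scale and on the data length, so it is z-scored (PACz) against a
surrogate distribution obtained by cutting the power series at a random
point and swapping the halves — a misalignment that preserves the power
autocorrelation while destroying any phase-locked modulation.

Comodulograms hold the median PACz over 1-min bins of one vigilance state,
separately for photophase and scotophase, on a phase-frequency (2-20 Hz) by
amplitude-frequency (2-50 Hz) grid.  Phase comes from the 1-Hz filter bank;
the amplitude series for a cell is extracted with a band wide enough to
carry the modulation sidebands — half-width ``f_phase + 1`` Hz around the
amplitude center, assembled as the coherent sum of the bank's 1-Hz analytic
signals.  (A filter of bandwidth B limits its envelope to fluctuations below
~B, so a uniform 1-Hz amplitude band is physically unable to represent an
8-Hz theta-locked envelope; widening the amplitude band with the phase
frequency is the standard remedy.)  Cells whose widened amplitude band would
touch the phase band are meaningless and left missing.

Conditions are compared cell-wise with paired t-tests corrected by
cluster-mass permutation (sign flips of the subject difference matrices;
4-connected clusters).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from ._cluster import ClusterTestResult, paired_cluster_test
from .core import (
    Hypnogram,
    LightSchedule,
    ParameterError,
    Recording,
    StructureError,
)
from .spectral import EDGE, AnalyticBandSeries, analytic_signal

__all__ = [
    "pac_mi",
    "pacz",
    "Comodulogram",
    "comodulogram",
    "cluster_compare",
    "DEFAULT_PHASE_CENTERS",
    "DEFAULT_AMP_CENTERS",
]

#: default comodulogram grid: carrier phase up to 20 Hz, modulated amplitude
#: across the explored 2-50 Hz range.
DEFAULT_PHASE_CENTERS = np.arange(2.0, 21.0, 1.0)
DEFAULT_AMP_CENTERS = np.arange(2.0, 51.0, 1.0)


def pac_mi(phase: np.ndarray, amp: np.ndarray) -> float:
    """Mean-vector-length modulation index |sum a_t e^{i phi_t}| / n."""
    phase = np.asarray(phase, dtype=float)
    amp = np.asarray(amp, dtype=float)
    if phase.shape != amp.shape or phase.ndim != 1:
        raise StructureError(
            f"phase and amp must be 1-D of equal length, got {phase.shape} "
            f"and {amp.shape}"
        )
    if phase.size == 0:
        raise StructureError("empty input")
    return float(np.abs(np.dot(amp, np.exp(1j * phase))) / phase.size)


def pacz(
    phase: np.ndarray,
    amp: np.ndarray,
    n_surrogates: int = 200,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Surrogate-normalized PAC: (MI_obs - mean MI_surr) / sd MI_surr.

    Surrogates misalign power against phase by a circular cut-and-swap at a
    random point, preserving the power autocorrelation.  All cut offsets are
    evaluated at once through the circular cross-correlation of the power
    series with ``exp(i phi)`` (an FFT identity, exact up to rounding), and
    ``n_surrogates`` random offsets are drawn from it.

    Returns NaN (with a warning) when the surrogate distribution has zero
    spread, e.g. for constant power.
    """
    if n_surrogates < 50:
        raise ParameterError("n_surrogates must be >= 50")
    phase = np.asarray(phase, dtype=float)
    amp = np.asarray(amp, dtype=float)
    if phase.shape != amp.shape or phase.ndim != 1:
        raise StructureError("phase and amp must be 1-D of equal length")
    n = phase.size
    if n < 2:
        raise StructureError("need at least 2 samples")

    # r[c] = sum_t amp[(t+c) mod n] * exp(i phase[t]); r[0] is the observed sum
    z = np.exp(1j * phase)
    r = np.fft.ifft(np.conj(np.fft.fft(np.conj(z))) * np.fft.fft(amp))
    mi_all = np.abs(r) / n
    mi_obs = mi_all[0]

    if rng is None:
        rng = np.random.default_rng(seed)
    cuts = rng.integers(1, n, size=n_surrogates)
    mi_surr = mi_all[cuts]
    sd = mi_surr.std(ddof=1)
    if sd <= 1e-12 * max(abs(mi_obs), mi_surr.mean(), 1e-300):
        warnings.warn("zero surrogate variance; PACz undefined", stacklevel=2)
        return float("nan")
    return float((mi_obs - mi_surr.mean()) / sd)


# ---------------------------------------------------------------------------
# Comodulogram
# ---------------------------------------------------------------------------

@dataclass
class Comodulogram:
    """Median PACz per (phase frequency, amplitude frequency) cell."""

    phase_centers: np.ndarray
    amp_centers: np.ndarray
    pacz: np.ndarray  #: (n_phase, n_amp); NaN where no qualifying bin
    n_bins: np.ndarray  #: bins contributing per cell
    state: str = ""
    day_phase: str = ""  #: "photophase" | "scotophase"

    def argmax_cell(self):
        """(phase_center, amp_center) of the maximum median PACz."""
        if not np.isfinite(self.pacz).any():
            raise StructureError("all-missing comodulogram")
        flat = np.nanargmax(self.pacz)
        i, j = np.unravel_index(flat, self.pacz.shape)
        return float(self.phase_centers[i]), float(self.amp_centers[j])


def _qualifying_bins(
    mask: np.ndarray, fs: float, bin_s: float, min_fraction: float
) -> List[np.ndarray]:
    """Per 1-min bin, indices of qualifying samples; empty list entry means
    the bin is dropped."""
    n = mask.size
    bin_len = int(round(bin_s * fs))
    out = []
    for b in range(n // bin_len):
        sl = slice(b * bin_len, (b + 1) * bin_len)
        idx = np.flatnonzero(mask[sl]) + b * bin_len
        if idx.size >= min_fraction * bin_len:
            out.append(idx)
        else:
            out.append(np.empty(0, dtype=int))
    return out


def comodulogram(
    source: Union[Recording, AnalyticBandSeries],
    hypnogram: Hypnogram,
    schedule: LightSchedule,
    state: str = "W",
    phase_centers: Optional[Sequence[float]] = None,
    amp_centers: Optional[Sequence[float]] = None,
    bin_s: float = 60.0,
    n_surrogates: int = 200,
    seed: Optional[int] = None,
    last_n_cycles: Optional[int] = 2,
    min_fraction: float = 0.5,
    max_bins_per_phase: Optional[int] = None,
) -> Dict[str, Comodulogram]:
    """State-specific comodulograms for photophase and scotophase.

    PACz is computed in 1-min bins restricted to in-state, edge-valid samples
    (bins under ``min_fraction`` in-state are dropped) over the last
    ``last_n_cycles`` zeitgeber cycles, and the median over bins is taken
    separately per phase of day.  Phase uses the 1-Hz band at each phase
    center; amplitude at center ``f_a`` paired with phase ``f_p`` uses the
    coherent sum of 1-Hz analytic bands within ``f_a +/- (f_p + 1)`` Hz, so
    the envelope can carry the modulation (see the module docstring).  Cells
    with ``f_a - (f_p + 1) <= f_p + 0.5`` (amplitude band touching the phase
    band) are left missing.

    ``source`` may be a (preprocessed) :class:`Recording`, in which case
    each 1-Hz band is filtered on demand and only its per-bin samples are
    retained — the memory-friendly path — or a precomputed full-grid
    :class:`AnalyticBandSeries` with ``keep_phase=True``.
    ``max_bins_per_phase`` caps the number of 1-min bins per phase of day
    (evenly subsampled) to bound runtime on long recordings.

    Returns ``{"photophase": ..., "scotophase": ...}``; matrices are
    all-NaN (with a warning) when no bin qualifies.
    """
    pc = np.asarray(
        DEFAULT_PHASE_CENTERS if phase_centers is None else phase_centers, float
    )
    ac = np.asarray(
        DEFAULT_AMP_CENTERS if amp_centers is None else amp_centers, float
    )

    fs, t0_h, n = source.fs, source.t0_h, source.n_samples

    codes = hypnogram.sample_states(fs)[:n]
    state_code = "WNR".index(state)
    mask = np.zeros(n, dtype=bool)
    mask[: codes.size] = codes == state_code
    mask[:EDGE] = False
    mask[n - EDGE :] = False

    t_h = t0_h + np.arange(n) / fs / 3600.0
    if last_n_cycles is not None:
        cyc = schedule.cycle_index(t_h)
        mask &= np.isin(cyc, np.unique(cyc)[-last_n_cycles:])

    bins = _qualifying_bins(mask, fs, bin_s, min_fraction)
    keep = [i for i, idx in enumerate(bins) if idx.size]
    bin_start_h = t0_h + np.array(keep) * bin_s / 3600.0 if keep else np.array([])
    bin_photo = (
        schedule.is_photophase(bin_start_h) if keep else np.array([], dtype=bool)
    )
    if max_bins_per_phase is not None and len(keep):
        chosen = np.zeros(len(keep), dtype=bool)
        for val in (True, False):
            idx_dp = np.flatnonzero(bin_photo == val)
            if idx_dp.size > max_bins_per_phase:
                sel = np.linspace(0, idx_dp.size - 1, max_bins_per_phase)
                idx_dp = idx_dp[np.unique(np.round(sel).astype(int))]
            chosen[idx_dp] = True
        keep = [k for k, c in zip(keep, chosen) if c]
        bin_photo = bin_photo[chosen]
    bin_idx = [bins[i] for i in keep]

    n_bins = len(bin_idx)
    out_shape = (pc.size, ac.size)
    if n_bins == 0:
        warnings.warn(
            f"no qualifying {state} bins; comodulogram is all-missing",
            stacklevel=2,
        )
        return {
            dp: Comodulogram(
                phase_centers=pc,
                amp_centers=ac,
                pacz=np.full(out_shape, np.nan),
                n_bins=np.zeros(out_shape, dtype=int),
                state=state,
                day_phase=dp,
            )
            for dp in ("photophase", "scotophase")
        }

    # Per-bin complex analytic signal of every needed 1-Hz band, computed
    # once; wide amplitude bands are coherent sums of these.
    def halfwidth(fp: float) -> float:
        return fp + 1.0

    needed = set(float(c) for c in pc)
    max_hw = max(halfwidth(fp) for fp in pc)
    for ca in ac:
        for c in np.arange(np.ceil(ca - max_hw), np.floor(ca + max_hw) + 1):
            if c >= 2.0:
                needed.add(float(c))

    analytic_cache: Dict[float, List[np.ndarray]] = {}

    def bin_analytic(c: float) -> List[np.ndarray]:
        if c not in analytic_cache:
            if isinstance(source, AnalyticBandSeries):
                if source.phase is None:
                    raise ParameterError(
                        "AnalyticBandSeries source needs keep_phase=True"
                    )
                row = source.band_index(c - 0.5, c + 0.5)[0]
                a_full = np.sqrt(source.power[row].astype(float)) * np.exp(
                    1j * source.phase[row].astype(float)
                )
                analytic_cache[c] = [a_full[idx] for idx in bin_idx]
            else:
                a_full = analytic_signal(source.eeg, c - 0.5, c + 0.5, fs)
                analytic_cache[c] = [a_full[idx] for idx in bin_idx]
        return analytic_cache[c]

    rng = np.random.default_rng(seed)
    pz = np.full((pc.size, ac.size, n_bins), np.nan)
    for i, cp in enumerate(pc):
        hw = halfwidth(cp)
        phases = [np.angle(a) for a in bin_analytic(cp)]
        for j, ca in enumerate(ac):
            if ca - hw <= cp + 0.5:
                continue  # amplitude band would touch the carrier band
            members = [
                c
                for c in np.arange(np.ceil(ca - hw), np.floor(ca + hw) + 1)
                if c >= 2.0
            ]
            amps = []
            for k in range(n_bins):
                acc = np.zeros_like(bin_analytic(members[0])[k])
                for c in members:
                    acc = acc + bin_analytic(c)[k]
                amps.append(np.abs(acc) ** 2)
            for k in range(n_bins):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pz[i, j, k] = pacz(
                        phases[k], amps[k], n_surrogates=n_surrogates, rng=rng
                    )

    result = {}
    for dp, sel in (("photophase", bin_photo), ("scotophase", ~bin_photo)):
        vals = pz[:, :, sel]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            med = np.nanmedian(vals, axis=2) if sel.any() else np.full(out_shape, np.nan)
        nb = np.isfinite(vals).sum(axis=2) if sel.any() else np.zeros(out_shape, int)
        result[dp] = Comodulogram(
            phase_centers=pc,
            amp_centers=ac,
            pacz=med,
            n_bins=nb,
            state=state,
            day_phase=dp,
        )
    return result


# ---------------------------------------------------------------------------
# Condition comparison
# ---------------------------------------------------------------------------

def cluster_compare(
    mats_a: Sequence[Union[Comodulogram, np.ndarray]],
    mats_b: Sequence[Union[Comodulogram, np.ndarray]],
    n_perm: int = 500,
    thresh_p: float = 0.01,
    cluster_p: float = 0.05,
    seed: Optional[int] = None,
) -> ClusterTestResult:
    """Paired cluster-mass permutation comparison of per-subject
    comodulograms (condition b vs condition a).

    Cells whose paired t exceeds the two-sided ``thresh_p`` threshold are
    grouped into 4-connected clusters (positive and negative separately);
    each cluster's integrated t is referred to the permutation distribution
    of the maximum absolute cluster mass under subject-wise sign flips.
    Clusters with ``p < cluster_p`` (see
    :meth:`ClusterTestResult.significant`) are the reported ones.
    """
    if len(mats_a) != len(mats_b):
        raise StructureError("conditions must contain the same subjects, paired")

    def to_array(m):
        return m.pacz if isinstance(m, Comodulogram) else np.asarray(m, float)

    a = np.stack([to_array(m) for m in mats_a])
    b = np.stack([to_array(m) for m in mats_b])
    return paired_cluster_test(a, b, thresh_p=thresh_p, n_perm=n_perm, seed=seed)
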