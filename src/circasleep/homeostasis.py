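"""Process-S quantification: SWA decay, onset buildup, and nested F-tests.

In the two-process model, homeostatic sleep pressure tracked by NREM
slow-wave activity (SWA, here the 1-3 Hz band) decays exponentially over
accumulated sleep time,

    SWA(t) = SWA0 * exp(-t / tau) + SWAinf,

with t counted as cumulative NREM time from the first NREM incidence.  At
each wake-to-NREM transition SWA rises over tens of seconds, modeled as a
four-parameter logistic in log10 time,

    y(t) = min + (max - min) / (1 + 10^((log_t50 - log10 t) * Slope)).

Conditions are compared with extra-sum-of-squares F-tests between a null fit
that shares a parameter subset across datasets and an alternative fit with
all parameters separate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .core import EPOCH_S, NREM, ParameterError, StructureError, WAKE, Hypnogram
from .spectral import BandPowerSeries

__all__ = [
    "SWADecayFit",
    "swa_decay_fit",
    "BuildupFit",
    "buildup_fit",
    "FTestResult",
    "compare_fits_ftest",
    "nrem_decay_points",
    "transition_locked_swa",
    "decay_model",
    "buildup_model",
]


def decay_model(t_h: np.ndarray, swa0: float, tau_h: float, swa_inf: float):
    return swa0 * np.exp(-np.asarray(t_h, float) / tau_h) + swa_inf


def buildup_model(t_s: np.ndarray, lo: float, hi: float, log_t50: float,
                  slope: float):
    logt = np.log10(np.maximum(np.asarray(t_s, float), 1e-9))
    return lo + (hi - lo) / (1.0 + 10.0 ** ((log_t50 - logt) * slope))


# ---------------------------------------------------------------------------
# Decay fit
# ---------------------------------------------------------------------------

@dataclass
class SWADecayFit:
    swa0: float
    tau_h: float
    swa_inf: float
    rss: float
    df: int
    n: int
    p_model: float  #: F-test of the decay model against a constant
    converged: bool = True
    identifiable: bool = True
    flags: List[str] = field(default_factory=list)

    def predict(self, t_h):
        return decay_model(t_h, self.swa0, self.tau_h, self.swa_inf)


def nrem_decay_points(
    series: BandPowerSeries, hypnogram: Hypnogram
) -> Tuple[np.ndarray, np.ndarray]:
    """Map the non-missing bins of an NREM-masked SWA series onto the
    accumulated-NREM-time axis (hours of NREM slept since the first NREM
    epoch), the time base on which the decay is defined."""
    is_n = hypnogram.codes() == NREM
    epoch_t = hypnogram.epoch_times_h()
    cum_nrem_h = np.concatenate(([0.0], np.cumsum(is_n) * hypnogram.epoch_s / 3600.0))
    edges_t = np.concatenate((epoch_t, [epoch_t[-1] + hypnogram.epoch_s / 3600.0]))
    t_bins, values = series.dropna()
    t_sleep = np.interp(t_bins, edges_t, cum_nrem_h)
    return t_sleep, values


def swa_decay_fit(t_h: np.ndarray, swa: np.ndarray) -> SWADecayFit:
    """Nonlinear least-squares fit of the exponential decay.

    Deterministic starting values (SWA0 = first - last value, SWAinf = last
    value, tau = span / 3) and bounds SWA0 >= 0, tau > 0, SWAinf >= 0.
    Degenerate data (flat series) converge to the SWA0 ~ 0 boundary and are
    flagged unidentifiable rather than silently reported.
    """
    t_h = np.asarray(t_h, dtype=float)
    swa = np.asarray(swa, dtype=float)
    m = np.isfinite(t_h) & np.isfinite(swa)
    t_h, swa = t_h[m], swa[m]
    n = swa.size
    if n < 10:
        raise ParameterError(f"need >= 10 non-missing bins, got {n}")
    order = np.argsort(t_h)
    t_h, swa = t_h[order], swa[order]

    span = max(t_h[-1] - t_h[0], 1e-6)
    p0 = [max(swa[0] - swa[-1], 1e-3), span / 3.0, max(swa[-1], 1e-3)]
    bounds = ([0.0, 1e-6, 0.0], [np.inf, np.inf, np.inf])
    flags: List[str] = []
    converged = True
    try:
        popt, _ = optimize.curve_fit(
            decay_model, t_h, swa, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError:
        converged = False
        flags.append("non-convergence")
        popt = np.asarray(p0, float)
    swa0, tau, swa_inf = (float(v) for v in popt)

    resid = swa - decay_model(t_h, swa0, tau, swa_inf)
    rss = float(resid @ resid)
    df = n - 3
    rss0 = float(np.sum((swa - swa.mean()) ** 2))
    if rss > 0 and df > 0:
        f = ((rss0 - rss) / 2.0) / (rss / df)
        p_model = float(stats.f.sf(max(f, 0.0), 2, df))
    else:
        p_model = 0.0 if rss0 > rss else 1.0

    identifiable = True
    scale = max(np.mean(np.abs(swa)), 1e-12)
    if swa0 <= 1e-6 * scale or swa0 <= 2e-3:
        identifiable = False
        flags.append("swa0-at-zero-boundary: tau unidentifiable")
    if tau > 100.0 * span:
        identifiable = False
        flags.append("tau beyond the observed span")
    return SWADecayFit(
        swa0=swa0,
        tau_h=tau,
        swa_inf=swa_inf,
        rss=rss,
        df=df,
        n=n,
        p_model=p_model,
        converged=converged,
        identifiable=identifiable,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Buildup fit
# ---------------------------------------------------------------------------

@dataclass
class BuildupFit:
    min: float
    max: float
    log_t50: float  #: log10 seconds
    slope: float
    rss: float
    df: int
    n: int
    p_model: float
    converged: bool = True
    identifiable: bool = True
    flags: List[str] = field(default_factory=list)

    def predict(self, t_s):
        return buildup_model(t_s, self.min, self.max, self.log_t50, self.slope)

    def fraction_of_range(self, t_s: float) -> float:
        """(y(t) - min) / (max - min): fraction of the rise completed by t."""
        if self.max == self.min:
            return np.nan
        return float((self.predict(t_s) - self.min) / (self.max - self.min))


def transition_locked_swa(
    swa_power: np.ndarray,
    hypnogram: Hypnogram,
    fs: float,
    min_wake_s: float = 60.0,
    window_s: float = 60.0,
    bin_s: float = 2.0,
    valid: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Average SWA power time-locked to wake-to-NREM transitions.

    Qualifying transitions are NREM onsets preceded by at least
    ``min_wake_s`` of uninterrupted wake and followed by ``window_s`` of
    uninterrupted NREM (so the 0-60-s window is transition-free).  Returns
    (bin centers in s, mean SWA per 2-s bin over transitions, n_transitions);
    fewer than 5 transitions is an error.
    """
    codes = hypnogram.sample_states(fs)
    n = min(codes.size, swa_power.size)
    codes = codes[:n]
    epoch_len = int(round(hypnogram.epoch_s * fs))
    ep_states = codes[::epoch_len]
    n_ep = ep_states.size
    wake_epochs = int(np.ceil(min_wake_s / hypnogram.epoch_s))
    nrem_epochs = int(np.ceil(window_s / hypnogram.epoch_s))

    onsets = []
    for k in range(wake_epochs, n_ep - nrem_epochs):
        if ep_states[k] != NREM or ep_states[k - 1] != WAKE:
            continue
        if np.all(ep_states[k - wake_epochs : k] == WAKE) and np.all(
            ep_states[k : k + nrem_epochs] == NREM
        ):
            onsets.append(k * epoch_len)
    if len(onsets) < 5:
        raise StructureError(
            f"only {len(onsets)} qualifying wake-to-NREM transitions (need >= 5)"
        )

    win = int(round(window_s * fs))
    bin_len = int(round(bin_s * fs))
    n_bins = win // bin_len
    acc = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    for o in onsets:
        seg = swa_power[o : o + win]
        ok = np.isfinite(seg)
        if valid is not None:
            ok = ok & valid[o : o + win]
        seg2 = np.where(ok, seg, 0.0).reshape(n_bins, bin_len)
        ok2 = ok.reshape(n_bins, bin_len)
        acc += seg2.sum(axis=1)
        cnt += ok2.sum(axis=1)
    mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    t_centers = (np.arange(n_bins) + 0.5) * bin_s
    return t_centers, mean, len(onsets)


def buildup_fit(t_s: np.ndarray, y: np.ndarray) -> BuildupFit:
    """Four-parameter logistic fit of the SWA rise after NREM onset.

    Starting values come from the data quartiles: min/max from the extreme
    values, t50 from the first crossing of the midpoint, slope = 2.
    A flat curve (max ~ min) leaves the slope unidentifiable and is flagged.
    """
    t_s = np.asarray(t_s, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(t_s) & np.isfinite(y) & (t_s > 0)
    t_s, y = t_s[m], y[m]
    n = y.size
    if n < 6:
        raise ParameterError(f"need >= 6 points, got {n}")

    lo0, hi0 = float(np.min(y)), float(np.max(y))
    mid = 0.5 * (lo0 + hi0)
    above = np.flatnonzero(y >= mid)
    t50_0 = float(t_s[above[0]]) if above.size else float(np.median(t_s))
    p0 = [lo0, hi0, np.log10(max(t50_0, t_s[0])), 2.0]
    bounds = (
        [-np.inf, -np.inf, np.log10(t_s[0] / 10.0), 0.01],
        [np.inf, np.inf, np.log10(t_s[-1] * 10.0), 50.0],
    )
    flags: List[str] = []
    converged = True
    try:
        popt, _ = optimize.curve_fit(
            buildup_model, t_s, y, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError:
        converged = False
        flags.append("non-convergence")
        popt = np.asarray(p0, float)
    lo, hi, log_t50, slope = (float(v) for v in popt)

    resid = y - buildup_model(t_s, lo, hi, log_t50, slope)
    rss = float(resid @ resid)
    df = n - 4
    rss0 = float(np.sum((y - y.mean()) ** 2))
    if rss > 0 and df > 0:
        f = ((rss0 - rss) / 3.0) / (rss / df)
        p_model = float(stats.f.sf(max(f, 0.0), 3, df))
    else:
        p_model = 0.0 if rss0 > rss else 1.0

    identifiable = True
    spread = max(abs(hi0 - lo0), 1e-12)
    if abs(hi - lo) <= 1e-6 * max(abs(hi), 1.0) or spread <= 1e-9:
        identifiable = False
        flags.append("max ~ min: slope and t50 unidentifiable")
    return BuildupFit(
        min=lo,
        max=hi,
        log_t50=log_t50,
        slope=slope,
        rss=rss,
        df=df,
        n=n,
        p_model=p_model,
        converged=converged,
        identifiable=identifiable,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Extra-sum-of-squares F-test
# ---------------------------------------------------------------------------

_PARAM_NAMES = {
    "decay": ("swa0", "tau_h", "swa_inf"),
    "buildup": ("min", "max", "log_t50", "slope"),
}
_MODELS = {"decay": decay_model, "buildup": buildup_model}
_FITTERS = {"decay": swa_decay_fit, "buildup": buildup_fit}


@dataclass
class FTestResult:
    f: float
    df_num: int
    df_den: int
    p: float
    ss_null: float
    ss_alt: float
    shared: Tuple[str, ...]
    model: str
    degenerate: bool = False


def _fit_params(model: str, data: Tuple[np.ndarray, np.ndarray]) -> Dict[str, float]:
    fit = _FITTERS[model](*data)
    return {name: getattr(fit, name) for name in _PARAM_NAMES[model]}, fit.rss


def compare_fits_ftest(
    data_a: Tuple[np.ndarray, np.ndarray],
    data_b: Tuple[np.ndarray, np.ndarray],
    model: str = "decay",
    shared: Optional[Sequence[str]] = None,
) -> FTestResult:
    """Extra-sum-of-squares F-test between two datasets fit by one model.

    The alternative fits each dataset separately; the null ties the
    parameters listed in ``shared`` (default: all of them, i.e. a single
    common curve) across datasets.  ``F = [(SS_null - SS_alt)/k] /
    [SS_alt/df_alt]`` with k freed parameters.
    """
    if model not in _MODELS:
        raise ParameterError(f"unknown model: {model!r}")
    names = _PARAM_NAMES[model]
    fun = _MODELS[model]
    if shared is None:
        shared = names
    shared = tuple(shared)
    unknown = set(shared) - set(names)
    if unknown:
        raise ParameterError(f"unknown parameter(s) for {model}: {sorted(unknown)}")
    if not shared:
        raise ParameterError("shared must name at least one parameter")

    (pa, ss_a), (pb, ss_b) = _fit_params(model, data_a), _fit_params(model, data_b)
    ss_alt = ss_a + ss_b
    n_tot = sum(np.sum(np.isfinite(np.asarray(d[1], float))) for d in (data_a, data_b))
    p = len(names)
    df_alt = int(n_tot - 2 * p)

    # Null fit: shared parameters common, the rest per-dataset
    free = [nm for nm in names if nm not in shared]
    x0 = (
        [0.5 * (pa[nm] + pb[nm]) for nm in shared]
        + [pa[nm] for nm in free]
        + [pb[nm] for nm in free]
    )

    def unpack(x):
        common = dict(zip(shared, x[: len(shared)]))
        fa = dict(zip(free, x[len(shared) : len(shared) + len(free)]))
        fb = dict(zip(free, x[len(shared) + len(free) :]))
        par_a = {**common, **fa}
        par_b = {**common, **fb}
        return par_a, par_b

    def resid(x):
        par_a, par_b = unpack(x)
        ta, ya = (np.asarray(v, float) for v in data_a)
        tb, yb = (np.asarray(v, float) for v in data_b)
        ma, mb = np.isfinite(ya), np.isfinite(yb)
        ra = ya[ma] - fun(ta[ma], *[par_a[nm] for nm in names])
        rb = yb[mb] - fun(tb[mb], *[par_b[nm] for nm in names])
        return np.concatenate((ra, rb))

    sol = optimize.least_squares(resid, x0, method="lm", max_nfev=20000)
    ss_null = float(np.sum(sol.fun**2))
    ss_null = max(ss_null, ss_alt)  # nested models: null can never fit better

    k = len(shared)
    degenerate = ss_alt <= 0 or df_alt <= 0
    if degenerate:
        return FTestResult(
            f=np.nan, df_num=k, df_den=max(df_alt, 0), p=np.nan,
            ss_null=ss_null, ss_alt=ss_alt, shared=shared, model=model,
            degenerate=True,
        )
    f_stat = ((ss_null - ss_alt) / k) / (ss_alt / df_alt)
    p_val = float(stats.f.sf(f_stat, k, df_alt))
    return FTestResult(
        f=float(f_stat),
        df_num=k,
        df_den=df_alt,
        p=p_val,
        ss_null=ss_null,
        ss_alt=ss_alt,
        shared=shared,
        model=model,
    )
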