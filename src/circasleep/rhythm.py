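"""Rhythm detection and parameterization.

Three complementary statistics:

* the Sokolove-Bushell chi-square periodogram — for each candidate period of
  P whole bins the data are folded into P columns and
  ``Qp = K * sum_h (M_h - M)^2 / s^2`` (K complete cycles, M_h the column
  means, s^2 the population variance of the folded data) is referred to the
  chi-square law with P - 1 df;
* the single-cosinor fit ``y = M + A cos(omega t + theta)`` with the angular
  frequency fixed at the zeitgeber value, linearized to
  ``y = M + beta cos(omega t) + gamma sin(omega t)`` (beta = A cos theta,
  gamma = -A sin theta) and solved by least squares, with a zero-amplitude
  F-test on (beta, gamma);
* the population-mean (group) cosinor: per-subject (beta, gamma) estimates
  are averaged, their between-subject covariance yields a bivariate
  confidence region, a Hotelling-type F-test of zero population amplitude,
  and a two-sample Hotelling test for condition comparisons (Bonferroni over
  condition pairs).

Acrophase convention: the lag of the cosine peak after lights-off, in
degrees, reported in [0, 360); circular distance is used in comparisons.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import ParameterError, StructureError

__all__ = [
    "Chi2Periodogram",
    "chi2_periodogram",
    "CosinorFit",
    "cosinor_fit",
    "GroupCosinor",
    "group_cosinor",
    "compare_group_cosinor",
    "compare_conditions",
    "circular_distance_deg",
]


def circular_distance_deg(a: float, b: float) -> float:
    """Smallest absolute angular distance between two angles in degrees."""
    d = (a - b) % 360.0
    return float(min(d, 360.0 - d))


# ---------------------------------------------------------------------------
# Chi-square periodogram
# ---------------------------------------------------------------------------

@dataclass
class Chi2Periodogram:
    periods_h: np.ndarray
    qp: np.ndarray
    df: np.ndarray  #: P - 1 per candidate period
    threshold: np.ndarray  #: Qp at the chosen significance level
    significant: np.ndarray
    alpha: float
    bin_h: float

    @property
    def peak_period_h(self) -> float:
        return float(self.periods_h[int(np.argmax(self.qp))])

    @property
    def peak_significant(self) -> bool:
        return bool(self.significant[int(np.argmax(self.qp))])


def chi2_periodogram(
    values: np.ndarray,
    bin_h: float,
    period_range_h: Tuple[float, float] = (16.0, 32.0),
    alpha: float = 0.01,
) -> Chi2Periodogram:
    """Sokolove-Bushell chi-square periodogram of a uniformly binned series.

    Candidate periods are every whole number of bins inside
    ``period_range_h``; data are truncated to complete cycles per candidate.
    Qp is invariant to affine transforms of the series; a constant series
    gives Qp = 0 everywhere.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ParameterError("need a 1-D series with at least 4 bins")
    lo, hi = period_range_h
    if lo < 2 * bin_h:
        raise ParameterError(
            f"period grid ({lo} h) finer than twice the bin width ({bin_h} h)"
        )
    p_lo = int(np.ceil(lo / bin_h))
    p_hi = int(np.floor(hi / bin_h))
    p_hi = min(p_hi, x.size // 2)
    if p_hi < p_lo:
        raise ParameterError("period range contains no candidate periods")

    p_bins = np.arange(p_lo, p_hi + 1)
    qp = np.zeros(p_bins.size)
    for i, p in enumerate(p_bins):
        k = x.size // p
        xx = x[: k * p]
        mean = xx.mean()
        ss_tot = np.sum((xx - mean) ** 2)
        if ss_tot == 0:
            continue
        col_means = xx.reshape(k, p).mean(axis=0)
        qp[i] = k * xx.size * np.sum((col_means - mean) ** 2) / ss_tot
    df = p_bins - 1
    threshold = stats.chi2.ppf(1.0 - alpha, df)
    return Chi2Periodogram(
        periods_h=p_bins * bin_h,
        qp=qp,
        df=df,
        threshold=threshold,
        significant=qp > threshold,
        alpha=alpha,
        bin_h=bin_h,
    )


# ---------------------------------------------------------------------------
# Single cosinor
# ---------------------------------------------------------------------------

@dataclass
class CosinorFit:
    """Least-squares cosinor fit at a fixed angular frequency.

    ``theta_deg`` is the model phase in ``y = M + A cos(omega t + theta)``;
    ``acrophase_deg = (-theta) mod 360`` is the peak lag after lights-off.
    """

    mesor: float
    amplitude: float
    theta_deg: float
    period_h: float
    beta: float
    gamma: float
    sigma2: float
    rss: float
    n: int
    p_zero_amplitude: float

    @property
    def omega_deg_per_h(self) -> float:
        return 360.0 / self.period_h

    @property
    def acrophase_deg(self) -> float:
        return float((-self.theta_deg) % 360.0)

    @property
    def acrophase_h(self) -> float:
        return self.acrophase_deg / 360.0 * self.period_h


def cosinor_fit(t_h: np.ndarray, y: np.ndarray, period_h: float) -> CosinorFit:
    """Fit ``y = M + A cos(omega t + theta)`` with omega fixed by the period.

    Missing values (NaN) are dropped (unbalanced least squares); a design
    with all observations at the same cycle phase is singular and raises
    :class:`ParameterError`.
    """
    if period_h <= 0:
        raise ParameterError("period_h must be > 0")
    t_h = np.asarray(t_h, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(y) & np.isfinite(t_h)
    t_h, y = t_h[m], y[m]
    n = y.size
    if n < 4:
        raise ParameterError(f"need >= 4 observations, got {n}")
    omega = 2.0 * np.pi / period_h
    design = np.column_stack(
        [np.ones(n), np.cos(omega * t_h), np.sin(omega * t_h)]
    )
    if np.linalg.matrix_rank(design) < 3:
        raise ParameterError(
            "singular cosinor design (all observations at the same phase)"
        )
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    mesor, beta, gamma = coef
    amplitude = float(np.hypot(beta, gamma))
    theta = float(np.degrees(np.arctan2(-gamma, beta)))
    resid = y - design @ coef
    rss = float(resid @ resid)
    df_den = n - 3
    sigma2 = rss / df_den if df_den > 0 else np.nan
    rss0 = float(np.sum((y - y.mean()) ** 2))
    if rss > 0 and df_den > 0:
        f = ((rss0 - rss) / 2.0) / (rss / df_den)
        p = float(stats.f.sf(f, 2, df_den))
    else:
        p = 0.0 if rss0 > rss else 1.0
    return CosinorFit(
        mesor=float(mesor),
        amplitude=amplitude,
        theta_deg=theta,
        period_h=float(period_h),
        beta=float(beta),
        gamma=float(gamma),
        sigma2=sigma2,
        rss=rss,
        n=n,
        p_zero_amplitude=p,
    )


# ---------------------------------------------------------------------------
# Group (population-mean) cosinor
# ---------------------------------------------------------------------------

@dataclass
class GroupCosinor:
    """Population-mean cosinor over individual fits of one condition."""

    mesor: float
    amplitude: float
    theta_deg: float
    period_h: float
    beta_mean: float
    gamma_mean: float
    cov: np.ndarray  #: 2x2 between-subject covariance of (beta, gamma)
    n: int
    p_zero_amplitude: float  #: Hotelling-type F-test of zero population amplitude
    fits: List[CosinorFit] = field(default_factory=list, repr=False)

    @property
    def acrophase_deg(self) -> float:
        return float((-self.theta_deg) % 360.0)

    def covers(self, beta: float, gamma: float, level: float = 0.95) -> bool:
        """Whether (beta, gamma) lies inside the bivariate confidence region
        of the population mean at the given level."""
        k = self.n
        d = np.array([self.beta_mean - beta, self.gamma_mean - gamma])
        if np.trace(self.cov) <= 1e-300:
            return bool(np.allclose(d, 0.0))
        t2 = k * d @ np.linalg.solve(self.cov, d)
        crit = 2.0 * (k - 1) / (k - 2) * stats.f.ppf(level, 2, k - 2)
        return bool(t2 <= crit)


def group_cosinor(fits: Sequence[CosinorFit]) -> GroupCosinor:
    """Population-mean cosinor from >= 3 individual fits at a common period."""
    if len(fits) < 3:
        raise StructureError(f"need >= 3 individual fits, got {len(fits)}")
    periods = {round(f.period_h, 9) for f in fits}
    if len(periods) != 1:
        raise StructureError(f"fits mix different periods: {sorted(periods)}")
    k = len(fits)
    bg = np.array([[f.beta, f.gamma] for f in fits])
    mean = bg.mean(axis=0)
    cov = np.cov(bg, rowvar=False, ddof=1)
    amplitude = float(np.hypot(*mean))
    theta = float(np.degrees(np.arctan2(-mean[1], mean[0])))
    # Hotelling one-sample T^2 against (0, 0); a degenerate (zero-spread)
    # covariance means the subjects agree exactly
    scale = float(np.trace(cov))
    if scale <= 1e-12 * max(amplitude**2, 1e-300):
        p = 0.0 if amplitude > 0 else 1.0
    else:
        t2 = k * mean @ np.linalg.solve(cov, mean)
        f_stat = (k - 2) / (2.0 * (k - 1)) * t2
        p = float(stats.f.sf(f_stat, 2, k - 2))
    return GroupCosinor(
        mesor=float(np.mean([f.mesor for f in fits])),
        amplitude=amplitude,
        theta_deg=theta,
        period_h=fits[0].period_h,
        beta_mean=float(mean[0]),
        gamma_mean=float(mean[1]),
        cov=cov,
        n=k,
        p_zero_amplitude=p,
        fits=list(fits),
    )


def compare_group_cosinor(a: GroupCosinor, b: GroupCosinor) -> Dict[str, float]:
    """Two-sample Hotelling test on the (beta, gamma) plane: a joint
    amplitude/acrophase difference between two conditions."""
    if not np.isclose(a.period_h, b.period_h):
        raise StructureError("conditions were fit at different periods")
    n1, n2 = a.n, b.n
    d = np.array([a.beta_mean - b.beta_mean, a.gamma_mean - b.gamma_mean])
    pooled = ((n1 - 1) * a.cov + (n2 - 1) * b.cov) / (n1 + n2 - 2)
    t2 = (n1 * n2) / (n1 + n2) * d @ np.linalg.solve(pooled, d)
    df_den = n1 + n2 - 3
    f_stat = df_den / (2.0 * (n1 + n2 - 2)) * t2
    p = float(stats.f.sf(f_stat, 2, df_den))
    return {
        "t2": float(t2),
        "F": float(f_stat),
        "df_num": 2,
        "df_den": df_den,
        "p": p,
        "amplitude_a": a.amplitude,
        "amplitude_b": b.amplitude,
        "acrophase_diff_deg": circular_distance_deg(a.acrophase_deg, b.acrophase_deg),
    }


def compare_conditions(
    groups: Dict[str, GroupCosinor]
) -> pd.DataFrame:
    """All pairwise condition comparisons, Bonferroni-corrected."""
    names = list(groups)
    pairs = [(x, y) for i, x in enumerate(names) for y in names[i + 1 :]]
    rows = []
    for x, y in pairs:
        r = compare_group_cosinor(groups[x], groups[y])
        r["condition_a"] = x
        r["condition_b"] = y
        r["p_bonferroni"] = min(1.0, r["p"] * len(pairs))
        rows.append(r)
    return pd.DataFrame(rows)
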