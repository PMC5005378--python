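"""Rule-based vigilance-state scoring and sleep-architecture statistics.

Scoring applies the classical rodent state definitions as a transparent
three-rule threshold classifier on 4-s epoch features:

* WAKE   — EMG RMS at or above the (auto-calibrated) muscle-tone threshold;
* NREM   — low EMG and a high slow-wave fraction (SWA / total power);
* REM    — low EMG, low SWA, and theta dominance over delta, accepted only
           in sleep context (the preceding non-brief state must be NREM).

Architecture statistics count maximal same-state runs as episodes, per state
and phase of day, and report brief awakenings — wake intrusions of at most
four epochs (16 s) flanked by NREM on both sides — as a fragmentation index
rather than as wake episodes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    Hypnogram,
    LightSchedule,
    ParameterError,
    Recording,
    StructureError,
)
from .spectral import epoch_psd

__all__ = [
    "EpochFeatures",
    "ScoringThresholds",
    "compute_epoch_features",
    "score_epochs",
    "architecture_stats",
    "ArchitectureStats",
    "BRIEF_AWAKENING_MAX_EPOCHS",
]

BRIEF_AWAKENING_MAX_EPOCHS = 4  # <= 16 s, the standard rodent criterion


@dataclass
class EpochFeatures:
    """Per-epoch spectral band powers and EMG RMS."""

    swa_power: np.ndarray  #: PSD sum in 1-4 Hz
    theta_power: np.ndarray  #: PSD sum in 7-9.5 Hz
    total_power: np.ndarray  #: PSD sum in 0-50 Hz
    emg_rms: np.ndarray
    epoch_s: float = 4.0
    t0_h: float = 0.0

    def __len__(self) -> int:
        return self.swa_power.size


def compute_epoch_features(rec: Recording, epoch_s: float = 4.0) -> EpochFeatures:
    freqs, psd = epoch_psd(rec, epoch_s=epoch_s)
    swa = psd[:, (freqs >= 1.0) & (freqs <= 4.0)].sum(axis=1)
    theta = psd[:, (freqs >= 7.0) & (freqs <= 9.5)].sum(axis=1)
    total = psd.sum(axis=1)
    epoch_len = int(round(epoch_s * rec.fs))
    n_epochs = psd.shape[0]
    emg = rec.emg[: n_epochs * epoch_len].reshape(n_epochs, epoch_len)
    emg_rms = np.sqrt(np.mean(emg**2, axis=1))
    return EpochFeatures(
        swa_power=swa,
        theta_power=theta,
        total_power=total,
        emg_rms=emg_rms,
        epoch_s=epoch_s,
        t0_h=rec.t0_h,
    )


@dataclass
class ScoringThresholds:
    """Classifier thresholds; ``emg_threshold=None`` auto-calibrates from the
    bimodal distribution of log EMG RMS."""

    emg_threshold: Optional[float] = None
    swa_ratio_threshold: float = 0.45
    theta_delta_threshold: float = 1.5


def _bimodal_midpoint(log_rms: np.ndarray) -> float:
    """Midpoint of a deterministic two-means split of log EMG RMS."""
    lo, hi = np.percentile(log_rms, [10.0, 90.0])
    m = np.array([lo, hi], dtype=float)
    for _ in range(200):
        assign = np.abs(log_rms[:, None] - m[None, :]).argmin(axis=1)
        new = np.array(
            [
                log_rms[assign == k].mean() if np.any(assign == k) else m[k]
                for k in (0, 1)
            ]
        )
        if np.allclose(new, m, atol=1e-12):
            break
        m = new
    return float(m.mean())


def score_epochs(
    features: EpochFeatures,
    thresholds: Optional[ScoringThresholds] = None,
) -> Hypnogram:
    """Classify epochs into W / N / R.

    Rule order: WAKE on high EMG regardless of EEG; otherwise NREM on a high
    SWA fraction; otherwise REM on theta/delta dominance; otherwise NREM.
    All-zero-feature epochs are labeled WAKE with a warning.  A post-hoc pass
    relabels REM runs whose preceding non-brief state is not NREM to WAKE.
    """
    thr = thresholds or ScoringThresholds()
    n = len(features)
    if n == 0:
        raise StructureError("no epochs to score")

    dead = (
        (features.total_power <= 0)
        & (features.emg_rms <= 0)
    )
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} epoch(s) with all-zero features labeled WAKE",
            stacklevel=2,
        )

    emg_thr = thr.emg_threshold
    if emg_thr is None:
        log_rms = np.log(np.maximum(features.emg_rms, 1e-12))
        emg_thr = float(np.exp(_bimodal_midpoint(log_rms)))

    with np.errstate(divide="ignore", invalid="ignore"):
        swa_ratio = np.where(
            features.total_power > 0, features.swa_power / features.total_power, 0.0
        )
        theta_delta = np.where(
            features.swa_power > 0, features.theta_power / features.swa_power, np.inf
        )
        theta_delta = np.where(features.theta_power > 0, theta_delta, 0.0)

    states = np.full(n, "N", dtype="<U1")
    is_wake = features.emg_rms >= emg_thr
    states[is_wake] = "W"
    sleep = ~is_wake
    is_nrem = sleep & (swa_ratio >= thr.swa_ratio_threshold)
    is_rem = sleep & ~is_nrem & (theta_delta >= thr.theta_delta_threshold)
    states[is_rem] = "R"
    states[dead] = "W"

    _enforce_rem_context(states)
    return Hypnogram(states=states, epoch_s=features.epoch_s, t0_h=features.t0_h,
                     provenance="scored")


def _runs(states: np.ndarray):
    """Run-length encoding: list of (state, start, length)."""
    n = states.size
    starts = np.flatnonzero(np.concatenate(([True], states[1:] != states[:-1])))
    lengths = np.diff(np.concatenate((starts, [n])))
    return [(states[s], int(s), int(ln)) for s, ln in zip(starts, lengths)]


def _enforce_rem_context(states: np.ndarray) -> None:
    """Relabel REM runs to WAKE unless the preceding non-brief state is NREM.

    Brief wake intrusions (<= BRIEF_AWAKENING_MAX_EPOCHS) are looked through
    when establishing sleep context.  Operates in place.
    """
    runs = _runs(states)
    for i, (s, start, length) in enumerate(runs):
        if s != "R":
            continue
        ok = False
        j = i - 1
        while j >= 0:
            ps, _, plen = runs[j]
            if ps == "W" and plen <= BRIEF_AWAKENING_MAX_EPOCHS:
                j -= 1
                continue
            ok = ps in ("N", "R")
            break
        if not ok:
            states[start : start + length] = "W"


# ---------------------------------------------------------------------------
# Architecture statistics
# ---------------------------------------------------------------------------

@dataclass
class ArchitectureStats:
    """Episode counts/durations and time-in-state per state and phase of day."""

    table: pd.DataFrame  #: columns state, phase, episode_count,
    #: total_time_pct, mean_episode_length_s
    brief_awakenings: int = 0
    brief_awakenings_per_h_nrem: float = np.nan  #: primary fragmentation rate
    brief_awakenings_per_pct_nrem: float = np.nan  #: alternative normalization
    n_epochs: int = 0

    def time_fraction(self, state: str, phase: str) -> float:
        row = self.table[
            (self.table.state == state) & (self.table.phase == phase)
        ]
        return float(row.total_time_pct.iloc[0]) / 100.0

    def to_tidy(self) -> pd.DataFrame:
        long = self.table.melt(
            id_vars=["state", "phase"], var_name="metric", value_name="value"
        )
        extra = pd.DataFrame(
            {
                "state": ["W", "W"],
                "phase": ["all", "all"],
                "metric": [
                    "brief_awakenings_per_h_nrem",
                    "brief_awakenings_per_pct_nrem",
                ],
                "value": [
                    self.brief_awakenings_per_h_nrem,
                    self.brief_awakenings_per_pct_nrem,
                ],
            }
        )
        return pd.concat([long, extra], ignore_index=True)


def _brief_awakening_mask(runs) -> np.ndarray:
    """Boolean per run: is a brief awakening (short W flanked by N)."""
    flags = np.zeros(len(runs), dtype=bool)
    for i, (s, _start, length) in enumerate(runs):
        if (
            s == "W"
            and length <= BRIEF_AWAKENING_MAX_EPOCHS
            and 0 < i < len(runs) - 1
            and runs[i - 1][0] == "N"
            and runs[i + 1][0] == "N"
        ):
            flags[i] = True
    return flags


def architecture_stats(
    hypnogram: Hypnogram,
    schedule: LightSchedule,
    last_n_cycles: Optional[int] = None,
) -> ArchitectureStats:
    """Episode statistics per state and phase of day.

    Episodes are maximal same-state runs (assigned to the phase of their
    first epoch); brief awakenings are counted separately and excluded from
    the wake episode list, though they still split NREM episodes.  With
    ``last_n_cycles`` the computation is restricted to the final zeitgeber
    cycles, the convention used for steady-state comparisons.
    """
    if len(hypnogram) == 0:
        raise StructureError("empty hypnogram")
    states = hypnogram.states
    t_h = hypnogram.epoch_times_h()
    if last_n_cycles is not None:
        cyc = schedule.cycle_index(t_h)
        keep = np.isin(cyc, np.unique(cyc)[-last_n_cycles:])
        states = states[keep]
        t_h = t_h[keep]
        if states.size == 0:
            raise StructureError("no epochs left after cycle restriction")
    photo = schedule.is_photophase(t_h)
    phases = np.where(photo, "photophase", "scotophase")

    runs = _runs(states)
    brief = _brief_awakening_mask(runs)

    rows = []
    for phase in ("scotophase", "photophase"):
        in_phase = phases == phase
        n_phase = int(in_phase.sum())
        for s in ("W", "N", "R"):
            eps = [
                (start, length)
                for k, (rs, start, length) in enumerate(runs)
                if rs == s and phases[start] == phase and not (s == "W" and brief[k])
            ]
            n_state_epochs = int(((states == s) & in_phase).sum())
            rows.append(
                {
                    "state": s,
                    "phase": phase,
                    "episode_count": len(eps),
                    "total_time_pct": (
                        100.0 * n_state_epochs / n_phase if n_phase else np.nan
                    ),
                    "mean_episode_length_s": (
                        float(np.mean([ln for _, ln in eps])) * hypnogram.epoch_s
                        if eps
                        else np.nan
                    ),
                }
            )
    table = pd.DataFrame(rows)

    n_brief = int(brief.sum())
    nrem_epochs = int((states == "N").sum())
    nrem_h = nrem_epochs * hypnogram.epoch_s / 3600.0
    nrem_pct = 100.0 * nrem_epochs / states.size
    return ArchitectureStats(
        table=table,
        brief_awakenings=n_brief,
        brief_awakenings_per_h_nrem=n_brief / nrem_h if nrem_h > 0 else np.nan,
        brief_awakenings_per_pct_nrem=n_brief / nrem_pct if nrem_pct > 0 else np.nan,
        n_epochs=int(states.size),
    )
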