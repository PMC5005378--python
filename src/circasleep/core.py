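"""Shared containers and error types.

The analysis operates on four kinds of objects that several modules need to
exchange: a light-dark schedule, a two-channel EEG/EMG recording, a hypnogram
of 4-s vigilance-state epochs, and a 1-min locomotor-activity series.  They
live here so that the thematic modules (synthetic, io, scoring, ...) can share
them without import cycles; each module re-exports the types it "owns".

Time convention: ``t = 0`` is the first lights-off of the experiment, and all
times are measured from it (seconds for signals, hours for schedules).  Sample
indexing is 0-based with half-open ranges throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Vigilance states in canonical order; integer codes are positions.
STATES = ("W", "N", "R")
WAKE, NREM, REM = 0, 1, 2

EPOCH_S = 4.0  #: scoring epoch length, seconds
FS = 200.0  #: acquisition sampling rate, Hz


class CircasleepError(Exception):
    """Base class for package errors."""


class ParameterError(CircasleepError, ValueError):
    """A parameter is outside its valid domain."""


class FormatError(CircasleepError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ConfigurationError(CircasleepError, ValueError):
    """An operation was configured inconsistently (e.g. wrong sampling rate)."""


class StructureError(CircasleepError, ValueError):
    """Inputs that must align structurally (lengths, pairing) do not."""


# ---------------------------------------------------------------------------
# Light schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LightSchedule:
    """A periodic light-dark schedule, or constant darkness (DD).

    Parameters
    ----------
    period_h:
        Zeitgeber cycle length in hours (e.g. 24 for LD12/12, 21 for
        LD10.5/10.5).  ``None`` means constant darkness.
    photofraction:
        Fraction of the cycle that is lit, in [0, 1].  Each cycle starts with
        the scotophase (lights off) followed by the photophase.
    n_days:
        Number of astronomic (24-h) days the schedule covers.
    lights_off_clock_h:
        Wall-clock hour of the first lights-off; metadata only — internal
        time is measured from that instant.
    """

    period_h: Optional[float]
    photofraction: float = 0.5
    n_days: int = 1
    lights_off_clock_h: float = 8.5

    def __post_init__(self) -> None:
        if self.period_h is not None and not self.period_h > 0:
            raise ParameterError(f"period_h must be positive, got {self.period_h}")
        if not 0.0 <= self.photofraction <= 1.0:
            raise ParameterError(
                f"photofraction must lie in [0, 1], got {self.photofraction}"
            )
        if self.n_days < 1:
            raise ParameterError(f"n_days must be >= 1, got {self.n_days}")

    @property
    def is_dd(self) -> bool:
        return self.period_h is None

    @property
    def duration_h(self) -> float:
        return 24.0 * self.n_days

    @property
    def dark_h(self) -> float:
        """Scotophase length within one cycle (the full cycle under DD)."""
        if self.is_dd:
            return np.inf
        return (1.0 - self.photofraction) * self.period_h

    def is_photophase(self, t_h):
        """Vectorized phase-of-day lookup: True where lights are on."""
        t_h = np.asarray(t_h, dtype=float)
        if self.is_dd:
            return np.zeros(t_h.shape, dtype=bool)
        return (t_h % self.period_h) >= self.dark_h

    def phase_labels(self, t_h) -> np.ndarray:
        return np.where(self.is_photophase(t_h), "photophase", "scotophase")

    def cycle_index(self, t_h):
        """0-based index of the zeitgeber cycle containing each time (24-h
        pseudo-cycles under DD)."""
        period = 24.0 if self.is_dd else self.period_h
        return np.floor_divide(np.asarray(t_h, dtype=float), period).astype(int)


# ---------------------------------------------------------------------------
# Recording / hypnogram / activity
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Two-channel EEG/EMG recording on a schedule-aligned time base."""

    eeg: np.ndarray
    emg: np.ndarray
    fs: float = FS
    t0_h: float = 0.0  #: start time, hours since first lights-off
    schedule: Optional[LightSchedule] = None

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.shape != self.emg.shape or self.eeg.ndim != 1:
            raise StructureError(
                "eeg and emg must be 1-D arrays of equal length, got "
                f"{self.eeg.shape} and {self.emg.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.eeg.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs + self.t0_h * 3600.0


@dataclass
class Hypnogram:
    """Vigilance-state labels on contiguous 4-s epochs."""

    states: np.ndarray  #: array of "W" / "N" / "R"
    epoch_s: float = EPOCH_S
    t0_h: float = 0.0
    provenance: str = "scored"  #: "scored" | "simulated"

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="<U1")
        bad = set(np.unique(self.states)) - set(STATES)
        if bad:
            raise StructureError(f"unknown state labels: {sorted(bad)}")

    def __len__(self) -> int:
        return self.states.size

    def codes(self) -> np.ndarray:
        """Integer codes: W=0, N=1, R=2."""
        return ((self.states == "N") + 2 * (self.states == "R")).astype(np.int64)

    def epoch_times_h(self) -> np.ndarray:
        """Start time of each epoch, hours since first lights-off."""
        return self.t0_h + np.arange(len(self)) * self.epoch_s / 3600.0

    def sample_states(self, fs: float) -> np.ndarray:
        """Per-sample state codes at sampling rate ``fs``."""
        return np.repeat(self.codes(), int(round(self.epoch_s * fs)))


@dataclass
class ActivitySeries:
    """Locomotor activity (distance moved) in uniform 1-min bins."""

    t_min: np.ndarray  #: bin centers, minutes since first lights-off
    distance: np.ndarray

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        if self.t_min.shape != self.distance.shape:
            raise StructureError("t_min and distance must have equal length")
        if self.t_min.size > 1:
            steps = np.diff(self.t_min)
            if not np.allclose(steps, 1.0, atol=1e-9):
                raise StructureError("activity series must use 1-min bins")
        if np.any(self.distance < 0):
            raise ParameterError("activity distances must be non-negative")

    def t_h(self) -> np.ndarray:
        return self.t_min / 60.0
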