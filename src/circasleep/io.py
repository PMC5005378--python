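"""Reading/writing recordings and derived series; preprocessing; epoching.

Recordings travel as two-channel ("EEG", "EMG") files, either CSV
(``time_s,eeg,emg``; lossless) or EDF (classic continuous EDF with 16-bit
quantization; 1-s data records, so a recording is truncated to whole seconds
on write).  EDF files are read through :func:`mne.io.read_raw_edf`; the
writer here is a minimal implementation of the EDF record layout.

Preprocessing follows the acquisition chain of the recordings this package
analyzes: a 0.5-Hz high-pass (4th-order Butterworth) and a 49-51-Hz band-stop
notch, both applied forward-backward (zero-phase) because instantaneous phase
is used downstream for coupling analysis.

Epoching cuts a recording into contiguous, non-overlapping 4-s epochs
(half-open sample ranges, trailing partial epoch dropped), each labeled
photophase/scotophase from the schedule at its first sample.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .core import (
    EPOCH_S,
    FS,
    ActivitySeries,
    ConfigurationError,
    FormatError,
    Hypnogram,
    LightSchedule,
    Recording,
)
from .synthetic import SimParams

__all__ = [
    "EpochView",
    "read_recording",
    "write_recording",
    "preprocess",
    "epoch",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
    "read_activity_csv",
    "write_activity_csv",
    "load_params",
    "save_params",
]


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path, format: str = "csv") -> None:
    path = Path(path)
    if format == "csv":
        df = pd.DataFrame(
            {"time_s": rec.times_s(), "eeg": rec.eeg, "emg": rec.emg}
        )
        df.to_csv(path, index=False)
    elif format == "edf":
        _write_edf(rec, path)
    else:
        raise FormatError(f"unknown recording format: {format!r}")


def read_recording(
    path,
    format: str = "csv",
    schedule: Optional[LightSchedule] = None,
) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "csv":
        df = pd.read_csv(path)
        missing = {"time_s", "eeg", "emg"} - set(df.columns)
        if missing:
            raise FormatError(
                f"recording CSV is missing channel column(s): {sorted(missing)}"
            )
        t = df["time_s"].to_numpy(dtype=float)
        if t.size < 2:
            raise FormatError("recording CSV must contain at least 2 samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
            raise FormatError("recording CSV time base is not uniform")
        fs = 1.0 / dt[0]
        return Recording(
            eeg=df["eeg"].to_numpy(dtype=float),
            emg=df["emg"].to_numpy(dtype=float),
            fs=round(fs, 6),
            t0_h=t[0] / 3600.0,
            schedule=schedule,
        )
    if format == "edf":
        return _read_edf(path, schedule)
    raise FormatError(f"unknown recording format: {format!r}")


def _write_edf(rec: Recording, path: Path) -> None:
    """Write a classic continuous EDF file with channels "EEG" and "EMG".

    16-bit quantization over a symmetric physical range per channel; 1-s data
    records (the recording is truncated to whole seconds).
    """
    fs = int(round(rec.fs))
    spr = fs  # samples per record (1-s records)
    n_rec = rec.n_samples // spr
    if n_rec < 1:
        raise FormatError("recording shorter than one EDF data record (1 s)")
    sigs = [rec.eeg[: n_rec * spr], rec.emg[: n_rec * spr]]
    labels = ["EEG", "EMG"]

    dig_min, dig_max = -32768, 32767
    phys_ranges = []
    for x in sigs:
        amp = float(np.max(np.abs(x))) if x.size else 1.0
        amp = amp if amp > 0 else 1.0
        phys_ranges.append((-amp, amp))

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise FormatError(f"EDF header field too long: {text!r}")
        return b.ljust(width)

    ns = len(sigs)
    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),  # local patient id
            f("Startdate X X X X", 80),  # local recording id
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 * (ns + 1)), 8),
            f("", 44),  # reserved (classic EDF)
            f(str(n_rec), 8),
            f("1", 8),  # record duration, s
            f(str(ns), 4),
        ]
    )
    header += b"".join(f(lab, 16) for lab in labels)
    header += b"".join(f("", 80) for _ in sigs)  # transducer
    header += b"".join(f("", 8) for _ in sigs)  # physical dimension
    header += b"".join(f(f"{lo:.6g}", 8) for (lo, _) in phys_ranges)
    header += b"".join(f(f"{hi:.6g}", 8) for (_, hi) in phys_ranges)
    header += b"".join(f(str(dig_min), 8) for _ in sigs)
    header += b"".join(f(str(dig_max), 8) for _ in sigs)
    header += b"".join(f("", 80) for _ in sigs)  # prefiltering
    header += b"".join(f(str(spr), 8) for _ in sigs)
    header += b"".join(f("", 32) for _ in sigs)  # reserved

    digital = []
    for x, (lo, hi) in zip(sigs, phys_ranges):
        gain = (dig_max - dig_min) / (hi - lo)
        d = np.round((x - lo) * gain + dig_min)
        digital.append(np.clip(d, dig_min, dig_max).astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for d in digital:
                fh.write(d[r * spr : (r + 1) * spr].tobytes())


def _read_edf(path: Path, schedule: Optional[LightSchedule]) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    have = set(raw.ch_names)
    missing = {"EEG", "EMG"} - have
    if missing:
        raise FormatError(f"EDF file is missing channel(s): {sorted(missing)}")
    fs = float(raw.info["sfreq"])
    eeg = raw.get_data(picks=["EEG"])[0]
    emg = raw.get_data(picks=["EMG"])[0]
    return Recording(eeg=eeg, emg=emg, fs=fs, t0_h=0.0, schedule=schedule)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(rec: Recording) -> Recording:
    """Zero-phase 0.5-Hz high-pass + 49-51-Hz band-stop on the EEG channel.

    The filters are designed for the 200-Hz acquisition rate; any other rate
    raises :class:`ConfigurationError`.  EMG is passed through unchanged.
    """
    if not np.isclose(rec.fs, FS):
        raise ConfigurationError(
            f"preprocessing filters are designed for fs={FS:g} Hz, got {rec.fs:g}"
        )
    sos_hp = butter(4, 0.5, btype="highpass", fs=rec.fs, output="sos")
    sos_bs = butter(2, [49.0, 51.0], btype="bandstop", fs=rec.fs, output="sos")
    eeg = sosfiltfilt(sos_bs, sosfiltfilt(sos_hp, rec.eeg))
    return Recording(
        eeg=eeg, emg=rec.emg.copy(), fs=rec.fs, t0_h=rec.t0_h, schedule=rec.schedule
    )


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

@dataclass
class EpochView:
    """Contiguous non-overlapping 4-s epochs over a recording.

    Epoch ``k`` covers samples ``[k*epoch_len, (k+1)*epoch_len)``; a trailing
    partial epoch is dropped.  Phase-of-day labels are taken at each epoch's
    first sample.
    """

    n_epochs: int
    epoch_len: int  #: samples per epoch
    fs: float
    t0_h: float
    schedule: Optional[LightSchedule]
    epoch_s: float = EPOCH_S

    def sample_range(self, k: int) -> tuple[int, int]:
        if not 0 <= k < self.n_epochs:
            raise IndexError(f"epoch index {k} out of range")
        return k * self.epoch_len, (k + 1) * self.epoch_len

    def start_times_h(self) -> np.ndarray:
        return self.t0_h + np.arange(self.n_epochs) * self.epoch_s / 3600.0

    def phase_labels(self) -> np.ndarray:
        if self.schedule is None:
            raise ConfigurationError("no schedule attached to the recording")
        return self.schedule.phase_labels(self.start_times_h())

    def is_photophase(self) -> np.ndarray:
        if self.schedule is None:
            raise ConfigurationError("no schedule attached to the recording")
        return self.schedule.is_photophase(self.start_times_h())


def epoch(rec: Recording, epoch_s: float = EPOCH_S) -> EpochView:
    epoch_len = int(round(epoch_s * rec.fs))
    n_epochs = rec.n_samples // epoch_len
    return EpochView(
        n_epochs=n_epochs,
        epoch_len=epoch_len,
        fs=rec.fs,
        t0_h=rec.t0_h,
        schedule=rec.schedule,
        epoch_s=epoch_s,
    )


# ---------------------------------------------------------------------------
# Hypnogram / activity / config I/O
# ---------------------------------------------------------------------------

def write_hypnogram_csv(hyp: Hypnogram, path) -> None:
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(len(hyp)),
            "t_start_s": hyp.t0_h * 3600.0 + np.arange(len(hyp)) * hyp.epoch_s,
            "state": hyp.states,
        }
    )
    df.to_csv(path, index=False)


def read_hypnogram_csv(path, provenance: str = "scored") -> Hypnogram:
    df = pd.read_csv(path)
    missing = {"epoch_index", "t_start_s", "state"} - set(df.columns)
    if missing:
        raise FormatError(f"hypnogram CSV is missing column(s): {sorted(missing)}")
    t = df["t_start_s"].to_numpy(dtype=float)
    epoch_s = float(t[1] - t[0]) if t.size > 1 else EPOCH_S
    return Hypnogram(
        states=df["state"].to_numpy(dtype="<U1"),
        epoch_s=epoch_s,
        t0_h=t[0] / 3600.0 if t.size else 0.0,
        provenance=provenance,
    )


def write_activity_csv(act: ActivitySeries, path) -> None:
    pd.DataFrame({"t_min": act.t_min, "distance": act.distance}).to_csv(
        path, index=False
    )


def read_activity_csv(path) -> ActivitySeries:
    df = pd.read_csv(path)
    missing = {"t_min", "distance"} - set(df.columns)
    if missing:
        raise FormatError(f"activity CSV is missing column(s): {sorted(missing)}")
    return ActivitySeries(
        t_min=df["t_min"].to_numpy(dtype=float),
        distance=df["distance"].to_numpy(dtype=float),
    )


def save_params(params: SimParams, path) -> None:
    """Serialize simulation parameters to JSON or YAML (by extension)."""
    d = dataclasses.asdict(params)
    d["transitions"] = {
        k: np.asarray(v, dtype=float).tolist() for k, v in d["transitions"].items()
    }
    d["circadian_mod"] = {
        k: [float(x) for x in v] for k, v in d["circadian_mod"].items()
    }
    d["swa_decay"] = [float(x) for x in d["swa_decay"]]
    d["buildup"] = [float(x) for x in d["buildup"]]
    d["band_amp"] = {
        s: {b: float(a) for b, a in bands.items()} for s, bands in d["band_amp"].items()
    }
    d["emg_rms"] = {k: float(v) for k, v in d["emg_rms"].items()}
    for key in ("coupling_kappa", "noise_sd", "theta_f0", "gamma_f0", "swa_f0"):
        d[key] = float(d[key])
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        path.write_text(yaml.safe_dump(d))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_params(path) -> SimParams:
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        d = yaml.safe_load(path.read_text())
    else:
        d = json.loads(path.read_text())
    d["transitions"] = {k: np.asarray(v, dtype=float) for k, v in d["transitions"].items()}
    d["circadian_mod"] = {k: tuple(v) for k, v in d["circadian_mod"].items()}
    d["swa_decay"] = tuple(d["swa_decay"])
    d["buildup"] = tuple(d["buildup"])
    return SimParams(**d)
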