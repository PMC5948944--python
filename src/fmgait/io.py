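"""On-disk dialects and in-memory containers for FMG gait data.

Recordings, per-sample phase labels and phase-transition events are all
plain-text CSV (UTF-8, ``.`` decimal, mandatory header row):

* recordings      ``time_s,ch1,...,chK``
* label tracks    ``time_s,phase``
* event lists     ``time_s,phase``

Timestamps are seconds from trial start.  Phase codes are
1 = Initial-Contact, 2 = Mid-Stance, 3 = Pre-Swing, 4 = Swing.  All
intervals are half-open ``[start, next_start)`` so a transition sample
belongs to the phase that begins there.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

PHASES = (1, 2, 3, 4)
PHASE_NAMES = {1: "Initial-Contact", 2: "Mid-Stance", 3: "Pre-Swing", 4: "Swing"}

DEFAULT_FS = 500.0
DEFAULT_N_CHANNELS = 8


class FormatError(ValueError):
    """Malformed header or non-numeric cell in a data file."""


class ValidationError(ValueError):
    """File parsed but violates a container invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FMGRecording:
    """A multichannel force-myography trial.

    Parameters
    ----------
    signal
        Force readings, shape ``(n_samples, n_channels)``, sensor units.
    fs
        Sampling rate in Hz.
    subject_id, trial_id, speed_label
        Free-text trial metadata.
    """

    signal: np.ndarray
    fs: float = DEFAULT_FS
    subject_id: str = ""
    trial_id: str = ""
    speed_label: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be 2-D (n_samples, n_channels)")
        if self.signal.shape[1] < 1:
            raise ValidationError("recording needs at least one channel")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class LabelTrack:
    """Per-sample gait-phase labels aligned to a time axis."""

    labels: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.labels.shape != self.timestamps.shape or self.labels.ndim != 1:
            raise ValidationError("labels and timestamps must be equal-length 1-D")
        if self.labels.size and not np.isin(self.labels, PHASES).all():
            raise ValidationError("labels must take values in {1,2,3,4}")
        if self.labels.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.labels.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelTrack):
            return NotImplemented
        return (np.array_equal(self.labels, other.labels)
                and np.allclose(self.timestamps, other.timestamps))


@dataclass
class EventList:
    """Ordered phase-transition events: phase ``phases[i]`` begins at ``times[i]``.

    Raw (uncorrected) lists may violate the cyclic phase order; corrected
    lists must follow 1→2→3→4→1.
    """

    times: np.ndarray
    phases: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.phases = np.asarray(self.phases, dtype=int)
        if self.times.shape != self.phases.shape or self.times.ndim != 1:
            raise ValidationError("times and phases must be equal-length 1-D")
        if self.phases.size and not np.isin(self.phases, PHASES).all():
            raise ValidationError("phases must take values in {1,2,3,4}")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def __iter__(self):
        return iter(zip(self.times.tolist(), self.phases.tolist()))

    def is_cyclic(self) -> bool:
        """True when successive phases follow the 1→2→3→4→1 order."""
        if len(self) < 2:
            return True
        succ = self.phases[:-1] % 4 + 1
        return bool(np.array_equal(succ, self.phases[1:]))

    @classmethod
    def from_pairs(cls, pairs) -> "EventList":
        pairs = list(pairs)
        if not pairs:
            return cls(np.empty(0), np.empty(0, dtype=int))
        t, p = zip(*pairs)
        return cls(np.asarray(t, float), np.asarray(p, int))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventList):
            return NotImplemented
        return (len(self) == len(other)
                and np.array_equal(self.phases, other.phases)
                and np.allclose(self.times, other.times, atol=1e-9))


@dataclass
class RunConfig:
    """Processing parameters shared across pipeline stages.

    The 125 ms window with 8 ms step yields the 125 Hz feature stream that
    the classifier operates on (at 500 Hz input: 62-sample windows advancing
    by 4 samples).
    """

    window_ms: float = 125.0
    step_ms: float = 8.0
    fs: float = DEFAULT_FS
    feature_set: tuple = ()          # empty = the full default set (features.FEATURE_NAMES)
    ssc_threshold: float = 0.0
    wavelet_level: int = 1
    short_fraction: float = 0.5      # supervisory short-recovery rule
    long_multiple: float = 1.0       # supervisory long-recovery rule
    match_window_fraction: float = 0.33
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_ms <= 0:
            raise ValidationError("window_ms must be positive")
        if not (0 < self.step_ms <= self.window_ms):
            raise ValidationError("step_ms must satisfy 0 < step_ms <= window_ms")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        self.feature_set = tuple(self.feature_set)

    @property
    def window_len(self) -> int:
        return int(round(self.window_ms * self.fs / 1000.0))

    @property
    def step_len(self) -> int:
        return int(round(self.step_ms * self.fs / 1000.0))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path, expected_first: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    if df.columns.size == 0 or df.columns[0] != expected_first:
        raise FormatError(
            f"{path}: expected header starting with {expected_first!r}, "
            f"got {list(df.columns)!r}")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise FormatError(
                f"{path}: non-numeric or missing value in column {col!r} "
                f"at data row {int(bad[0])}")
        out[col] = vals
    return out


def read_recording(path, fs: float | None = None, **meta) -> FMGRecording:
    """Read a recording CSV (``time_s,ch1,...,chK``).

    The sampling rate is inferred from the time column and checked for
    uniformity; for a single-row file it cannot be inferred and ``fs``
    (default 500 Hz) is used instead.
    """
    df = _read_csv(path, "time_s")
    ch_cols = [c for c in df.columns[1:]]
    for i, c in enumerate(ch_cols, start=1):
        if c != f"ch{i}":
            raise FormatError(f"{path}: channel columns must be ch1..chK, got {c!r}")
    if not ch_cols:
        raise FormatError(f"{path}: no channel columns")
    t = df["time_s"].to_numpy(float)
    if len(t) == 0:
        raise ValidationError(f"{path}: empty recording")
    if len(t) >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0) or (dt.max() - dt.min()) > 1e-6 * dt.mean() + 1e-9:
            raise ValidationError(f"{path}: non-uniform sampling implied by time_s")
        inferred = 1.0 / dt.mean()
    else:
        inferred = fs if fs is not None else DEFAULT_FS
    return FMGRecording(df[ch_cols].to_numpy(float), fs=float(inferred), **meta)


def write_recording(rec: FMGRecording, path) -> None:
    df = pd.DataFrame(rec.signal, columns=[f"ch{i+1}" for i in range(rec.n_channels)])
    df.insert(0, "time_s", rec.timestamps)
    df.to_csv(path, index=False, float_format="%.9g")


def read_events(path) -> EventList:
    df = _read_csv(path, "time_s")
    if list(df.columns) != ["time_s", "phase"]:
        raise FormatError(f"{path}: expected header time_s,phase")
    return EventList(df["time_s"].to_numpy(float), df["phase"].to_numpy(int))


def write_events(events: EventList, path) -> None:
    pd.DataFrame({"time_s": events.times, "phase": events.phases}).to_csv(
        path, index=False, float_format="%.9f")


def read_labels(path) -> LabelTrack:
    df = _read_csv(path, "time_s")
    if list(df.columns) != ["time_s", "phase"]:
        raise FormatError(f"{path}: expected header time_s,phase")
    return LabelTrack(df["phase"].to_numpy(int), df["time_s"].to_numpy(float))


def write_labels(track: LabelTrack, path) -> None:
    pd.DataFrame({"time_s": track.timestamps, "phase": track.labels}).to_csv(
        path, index=False, float_format="%.9f")


_CONFIG_FIELDS = {f: t for f, t in [
    ("window_ms", float), ("step_ms", float), ("fs", float),
    ("ssc_threshold", float), ("wavelet_level", int),
    ("short_fraction", float), ("long_multiple", float),
    ("match_window_fraction", float), ("seed", int),
]}


def read_config(path) -> RunConfig:
    """Read a ``key = value`` run-configuration file mirroring RunConfig."""
    kwargs: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key == "feature_set":
            kwargs[key] = tuple(v.strip() for v in val.split(",") if v.strip())
        elif key in _CONFIG_FIELDS:
            kwargs[key] = _CONFIG_FIELDS[key](val)
        else:
            raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
    return RunConfig(**kwargs)


def write_config(cfg: RunConfig, path) -> None:
    lines = []
    for key in _CONFIG_FIELDS:
        lines.append(f"{key} = {getattr(cfg, key)}")
    if cfg.feature_set:
        lines.append("feature_set = " + ",".join(cfg.feature_set))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Label rasterization
# ---------------------------------------------------------------------------

def labels_from_events(events: EventList, timestamps) -> LabelTrack:
    """Rasterize transition events onto a time axis.

    Each timestamp ``t`` receives the phase of the latest event with
    ``time <= t``; timestamps before the first event take the first
    event's phase.
    """
    if len(events) == 0:
        raise ValidationError("labels_from_events requires a non-empty event list")
    timestamps = np.asarray(timestamps, dtype=float)
    idx = np.searchsorted(events.times, timestamps, side="right") - 1
    idx = np.clip(idx, 0, len(events) - 1)
    return LabelTrack(events.phases[idx], timestamps)
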