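"""Six-axis trace ingestion, combined acceleration and low-pass filtering.

A leg-worn MPU6050-class sensor reports tri-axis acceleration and tri-axis
angular velocity at a fixed rate (32 Hz here).  Because the device rotates
with the leg, no single axis tracks gait reliably; the orientation-free
signal is the Euclidean norm of the three acceleration axes (the signal
magnitude vector), low-pass filtered to strip sensor noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .config import IoConfig

__all__ = [
    "ImuSeries",
    "MagnitudeSeries",
    "combine_acceleration",
    "low_pass",
    "read_imu_csv",
    "split_on_gaps",
]


@dataclass(frozen=True)
class ImuSeries:
    """A uniformly sampled six-axis inertial trace.

    Acceleration channels are in m/s^2; gyro channels are in whatever unit
    the input carries (rad/s for the supported CSV dialect).  ``timestamps``
    (seconds) are optional; when present they must be strictly increasing.
    """

    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    gyro_x: np.ndarray
    gyro_y: np.ndarray
    gyro_z: np.ndarray
    fs: float = 32.0
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        chans = [self.acc_x, self.acc_y, self.acc_z,
                 self.gyro_x, self.gyro_y, self.gyro_z]
        for name, ch in zip(self._channel_names(), chans):
            object.__setattr__(self, name, np.asarray(ch, dtype=float))
        n = len(self.acc_x)
        if n < 1:
            raise ValueError("ImuSeries must contain at least one sample")
        if any(len(getattr(self, name)) != n for name in self._channel_names()):
            raise ValueError("all six channels must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.timestamps is not None:
            ts = np.asarray(self.timestamps, dtype=float)
            object.__setattr__(self, "timestamps", ts)
            if len(ts) != n:
                raise ValueError("timestamps length must match channels")
            if n > 1 and not np.all(np.diff(ts) > 0):
                raise ValueError("timestamps must be strictly increasing")

    @staticmethod
    def _channel_names() -> tuple[str, ...]:
        return ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")

    def __len__(self) -> int:
        return len(self.acc_x)

    def slice(self, start: int, stop: int) -> "ImuSeries":
        """Sub-series over sample indices [start, stop)."""
        kw = {name: getattr(self, name)[start:stop] for name in self._channel_names()}
        ts = None if self.timestamps is None else self.timestamps[start:stop]
        return ImuSeries(fs=self.fs, timestamps=ts, **kw)


@dataclass(frozen=True)
class MagnitudeSeries:
    """Combined (orientation-free) acceleration magnitude at ``fs`` Hz."""

    values: np.ndarray
    fs: float = 32.0
    filtered: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")

    def __len__(self) -> int:
        return len(self.values)


def combine_acceleration(series: ImuSeries) -> MagnitudeSeries:
    """Per-sample Euclidean norm of the three acceleration axes.

    acc = sqrt(acc_x^2 + acc_y^2 + acc_z^2); invariant under device
    rotation by construction (up to axis permutation and sign).
    """
    if len(series) == 0:
        raise ValueError("cannot combine an empty series")
    mag = np.sqrt(series.acc_x**2 + series.acc_y**2 + series.acc_z**2)
    return MagnitudeSeries(values=mag, fs=series.fs, filtered=False)


def low_pass(
    signal: MagnitudeSeries | np.ndarray,
    cutoff_hz: float = 5.0,
    order: int = 2,
    fs: float | None = None,
) -> MagnitudeSeries | np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    Forward-backward filtering doubles the effective order and removes
    phase lag, so sample indices of peaks are preserved.  DC content passes
    through unchanged.  Accepts either a :class:`MagnitudeSeries` (returns
    the same, flagged ``filtered=True``) or a bare array (``fs`` required).
    """
    if isinstance(signal, MagnitudeSeries):
        values, srate = signal.values, signal.fs
    else:
        if fs is None:
            raise ValueError("fs is required when filtering a bare array")
        values, srate = np.asarray(signal, dtype=float), fs
    nyq = srate / 2.0
    if not (0 < cutoff_hz < nyq):
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz, got {cutoff_hz}")
    b, a = butter(order, cutoff_hz / nyq, btype="low")
    # filtfilt needs > 3*max(len(a),len(b)) samples; pass short traces through
    padlen = 3 * max(len(a), len(b))
    if len(values) <= padlen:
        warnings.warn(
            f"trace of {len(values)} samples is too short to filter; passing through",
            stacklevel=2,
        )
        out = values.copy()
    else:
        out = filtfilt(b, a, values)
    if isinstance(signal, MagnitudeSeries):
        return MagnitudeSeries(values=out, fs=srate, filtered=True)
    return out


def _parse_time_column(col: pd.Series) -> np.ndarray:
    """Timestamps as float seconds; accepts raw seconds or date-time text."""
    numeric = pd.to_numeric(col, errors="coerce")
    if not numeric.isna().any():
        return numeric.to_numpy(dtype=float)
    parsed = pd.to_datetime(col, errors="coerce")
    if parsed.isna().any():
        bad = col[parsed.isna()].iloc[0]
        raise ValueError(f"unparseable timestamp: {bad!r}")
    return (parsed - parsed.iloc[0]).dt.total_seconds().to_numpy()


def read_imu_csv(
    path: str | Path,
    fs: float = 32.0,
    io: IoConfig | None = None,
) -> ImuSeries:
    """Read a six-axis CSV trace.

    The expected dialect has a header row with a time column plus three
    acceleration (m/s^2) and three gyro columns; the time column holds
    either raw float seconds or "yyyy/m/d h:m:s.ms" style date-times.
    """
    io = io or IoConfig()
    df = pd.read_csv(path, sep=io.delimiter)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    required = [*io.acc_cols, *io.gyro_cols]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    ts = None
    if io.time_col in df.columns:
        ts = _parse_time_column(df[io.time_col])
    ax, ay, az = (df[c].to_numpy(dtype=float) for c in io.acc_cols)
    gx, gy, gz = (df[c].to_numpy(dtype=float) for c in io.gyro_cols)
    return ImuSeries(acc_x=ax, acc_y=ay, acc_z=az,
                     gyro_x=gx, gyro_y=gy, gyro_z=gz, fs=fs, timestamps=ts)


def split_on_gaps(series: ImuSeries, max_gap_factor: float = 2.0) -> list[ImuSeries]:
    """Split a trace at recording gaps longer than ``max_gap_factor``/fs.

    The pipeline treats input as uniformly sampled; a dropped-packet gap
    would silently stretch window arithmetic, so each contiguous run is
    returned as its own series (with a warning when a split occurs).
    Traces without timestamps are returned whole.
    """
    if series.timestamps is None or len(series) < 2:
        return [series]
    dt = np.diff(series.timestamps)
    gap = max_gap_factor / series.fs
    breaks = np.flatnonzero(dt > gap)
    if len(breaks) == 0:
        return [series]
    warnings.warn(
        f"{len(breaks)} recording gap(s) longer than {gap:.3f}s; "
        "splitting into independently processed segments",
        stacklevel=2,
    )
    edges = [0, *(breaks + 1), len(series)]
    return [series.slice(a, b) for a, b in zip(edges[:-1], edges[1:])]
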