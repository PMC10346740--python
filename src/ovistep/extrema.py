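"""Windowed peak and valley detection on the combined-acceleration signal.

A sample qualifies as a peak only if the signal rises strictly through its
n left neighbors and falls strictly through its n right neighbors, and the
peak clears an amplitude threshold.  The two-sided monotonicity window
suppresses the pseudo-peaks that plain local-maximum detection picks up
from residual noise.  Valleys use the mirrored condition with no threshold.
Gait analysis downstream always compares a peak with the valley that
follows it, so the module also pairs each peak with its following valley.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal import MagnitudeSeries

__all__ = ["ExtremaSet", "detect_peaks", "detect_valleys", "pair_extrema", "detect_extrema"]


@dataclass
class ExtremaSet:
    """Indexed peaks and valleys of a magnitude signal.

    ``paired_valley_indices``/``values`` (set by :func:`pair_extrema`) are
    aligned with the peaks: entry k is the valley paired with peak k.
    """

    peak_indices: np.ndarray
    peak_values: np.ndarray
    valley_indices: np.ndarray
    valley_values: np.ndarray
    n_peak: int = 4
    n_valley: int = 2
    thr: float = 12.0
    paired_valley_indices: np.ndarray | None = None
    paired_valley_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        self.peak_values = np.asarray(self.peak_values, dtype=float)
        self.valley_indices = np.asarray(self.valley_indices, dtype=int)
        self.valley_values = np.asarray(self.valley_values, dtype=float)
        for idx in (self.peak_indices, self.valley_indices):
            if len(idx) > 1 and not np.all(np.diff(idx) > 0):
                raise ValueError("extrema indices must be strictly ascending")

    @property
    def paired(self) -> bool:
        return self.paired_valley_indices is not None

    def n_peaks(self) -> int:
        return len(self.peak_indices)

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize indices, values and parameters (debugging/CLI dump)."""
        payload = {
            "peak_indices": self.peak_indices.tolist(),
            "peak_values": self.peak_values.tolist(),
            "valley_indices": self.valley_indices.tolist(),
            "valley_values": self.valley_values.tolist(),
            "n_peak": self.n_peak,
            "n_valley": self.n_valley,
            "thr": self.thr,
        }
        if self.paired:
            payload["paired_valley_indices"] = self.paired_valley_indices.tolist()
            payload["paired_valley_values"] = self.paired_valley_values.tolist()
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _as_values(signal: MagnitudeSeries | np.ndarray) -> np.ndarray:
    if isinstance(signal, MagnitudeSeries):
        return signal.values
    return np.asarray(signal, dtype=float)


def _monotone_flags(x: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks: strictly-rising-over-n-left and strictly-falling-over-n-right.

    With d = diff(x), index i rises iff d[i-n:i] > 0 element-wise and falls
    iff d[i:i+n] < 0 element-wise; cumulative sums of the sign masks give
    both tests in O(len) without a Python loop.
    """
    m = len(x)
    d = np.diff(x)
    pos = np.concatenate(([0], np.cumsum(d > 0)))
    neg = np.concatenate(([0], np.cumsum(d < 0)))
    rising = np.zeros(m, dtype=bool)
    falling = np.zeros(m, dtype=bool)
    idx = np.arange(n, m - n)
    if len(idx) > 0:
        rising[idx] = (pos[idx] - pos[idx - n]) == n
        falling[idx] = (neg[idx + n] - neg[idx]) == n
    return rising, falling


def detect_peaks(
    signal: MagnitudeSeries | np.ndarray,
    n: int = 4,
    thr: float = 12.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Peaks under the two-sided strict-monotonicity window.

    Index i is a peak iff x[i-n] < ... < x[i-1] < x[i] > x[i+1] > ... > x[i+n]
    (all inequalities strict) and x[i] > thr.  Indices within n of either
    boundary never qualify: the condition needs n real neighbors per side.
    Plateaus (equal neighbors) produce no peak.

    Returns (indices, values), both ascending.
    """
    x = _as_values(signal)
    if n < 1:
        raise ValueError("window half-width n must be >= 1")
    if len(x) <= 2 * n:
        warnings.warn(
            f"signal of {len(x)} samples is shorter than 2n+1={2*n+1}; no peaks",
            stacklevel=2,
        )
        return np.array([], dtype=int), np.array([], dtype=float)
    rising, falling = _monotone_flags(x, n)
    mask = rising & falling & (x > thr)
    idx = np.flatnonzero(mask)
    return idx, x[idx]


def detect_valleys(
    signal: MagnitudeSeries | np.ndarray,
    n: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Valleys: the mirrored condition (strict fall then strict rise), no threshold."""
    x = _as_values(signal)
    if n < 1:
        raise ValueError("window half-width n must be >= 1")
    if len(x) <= 2 * n:
        warnings.warn(
            f"signal of {len(x)} samples is shorter than 2n+1={2*n+1}; no valleys",
            stacklevel=2,
        )
        return np.array([], dtype=int), np.array([], dtype=float)
    rising, falling = _monotone_flags(-x, n)
    mask = rising & falling
    idx = np.flatnonzero(mask)
    return idx, x[idx]


def pair_extrema(
    peak_indices: np.ndarray,
    valley_indices: np.ndarray,
    signal: MagnitudeSeries | np.ndarray | None = None,
    valley_values: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair each peak with its following valley.

    Peak k is paired with the first valley after it that precedes peak k+1.
    When no detected valley falls in that span (shallow or truncated dips),
    the fallback is the minimum sample strictly between peak k and peak k+1
    (or between the last peak and the end of the signal); the fallback needs
    ``signal``.

    Returns (paired_valley_indices, paired_valley_values) aligned with the
    peaks, so that downstream rules can compare peak[k] with valley[k].
    """
    peak_indices = np.asarray(peak_indices, dtype=int)
    valley_indices = np.asarray(valley_indices, dtype=int)
    x = None if signal is None else _as_values(signal)
    if valley_values is None:
        if x is None:
            raise ValueError("need signal or valley_values to look up valley heights")
        valley_values = x[valley_indices]
    else:
        valley_values = np.asarray(valley_values, dtype=float)

    out_idx = np.empty(len(peak_indices), dtype=int)
    out_val = np.empty(len(peak_indices), dtype=float)
    for k, p in enumerate(peak_indices):
        nxt = peak_indices[k + 1] if k + 1 < len(peak_indices) else (
            len(x) if x is not None else np.iinfo(np.int64).max
        )
        in_span = valley_indices[(valley_indices > p) & (valley_indices < nxt)]
        if len(in_span) > 0:
            v = in_span[0]
            out_idx[k] = v
            out_val[k] = valley_values[np.searchsorted(valley_indices, v)]
        else:
            if x is None:
                raise ValueError(
                    f"peak at {p} has no following valley and no signal for the fallback"
                )
            lo, hi = p + 1, min(nxt, len(x))
            if lo >= hi:  # adjacent peaks / peak at the last sample
                out_idx[k] = min(p + 1, len(x) - 1)
            else:
                out_idx[k] = lo + int(np.argmin(x[lo:hi]))
            out_val[k] = x[out_idx[k]]
    return out_idx, out_val


def detect_extrema(
    signal: MagnitudeSeries | np.ndarray,
    n_peak: int = 4,
    n_valley: int = 2,
    thr: float = 12.0,
) -> ExtremaSet:
    """Detect peaks and valleys and pair them; the pipeline entry point."""
    p_idx, p_val = detect_peaks(signal, n=n_peak, thr=thr)
    v_idx, v_val = detect_valleys(signal, n=n_valley)
    ext = ExtremaSet(
        peak_indices=p_idx, peak_values=p_val,
        valley_indices=v_idx, valley_values=v_val,
        n_peak=n_peak, n_valley=n_valley, thr=thr,
    )
    if len(p_idx) > 0:
        pv_idx, pv_val = pair_extrema(p_idx, v_idx, signal=signal, valley_values=v_val)
        ext.paired_valley_indices = pv_idx
        ext.paired_valley_values = pv_val
    else:
        ext.paired_valley_indices = np.array([], dtype=int)
        ext.paired_valley_values = np.array([], dtype=float)
    return ext
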