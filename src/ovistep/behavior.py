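"""Rule-based recognition of running and leg-shaking behavior.

Running and leg shaking both corrupt naive peak counting: running packs
several footfalls into one second so peaks are missed, while leg shaking
(a scratching motion during standing or lying) produces step-like peaks
that are not steps at all.  Both behaviors share a signature in the
combined acceleration — a train of peaks whose following valleys stay
high, i.e. a small peak-valley difference — and differ in amplitude band:
running peaks exceed 30 m/s^2, leg-shake peaks stay below 39 m/s^2.
Leg shaking is then separated from genuinely brisk walking (same
acceleration envelope) by the variance of the x-axis angular velocity,
which is large when the leg flails freely and small during a supported
gait.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .config import ThresholdConfig
from .extrema import ExtremaSet
from .signal import MagnitudeSeries

__all__ = [
    "BehaviorWindow",
    "FeatureVector",
    "ClassificationMetrics",
    "detect_running",
    "detect_leg_shake_candidates",
    "classify_candidate",
    "window_variance",
    "extract_features",
    "cluster_behaviors",
    "classification_metrics",
]

RUNNING = "running"
LEG_SHAKE = "leg_shake"
FAST_WALK = "fast_walk"


@dataclass
class BehaviorWindow:
    """A labeled half-open sample interval [start_index, end_index).

    ``peak_ids`` are positions into the originating :class:`ExtremaSet`'s
    peak arrays (not sample indices).  ``W`` is the window size in original
    sample indices, the quantity the running-step formula consumes.
    """

    start_index: int
    end_index: int
    peak_ids: list[int] = field(default_factory=list)
    label: str | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.start_index >= self.end_index:
            raise ValueError("window must satisfy start < end")

    @property
    def W(self) -> int:
        return self.end_index - self.start_index

    def overlaps(self, other: "BehaviorWindow") -> bool:
        return self.start_index < other.end_index and other.start_index < self.end_index

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "start_index": int(self.start_index),
            "end_index": int(self.end_index),
            "W": int(self.W),
            "n_peaks": len(self.peak_ids),
            "truncated": self.truncated,
        }


@dataclass(frozen=True)
class FeatureVector:
    """Moment features of a gyro-x window: mean, var, std, kurt, skew.

    Population moments; ``kurt`` is excess kurtosis (a Gaussian scores 0).
    """

    mean: float
    var: float
    std: float
    kurt: float
    skew: float

    def __post_init__(self) -> None:
        if self.var < 0:
            raise ValueError("variance cannot be negative")
        if not math.isclose(self.std**2, self.var, abs_tol=1e-9):
            raise ValueError("std**2 must equal var")

    def as_array(self) -> np.ndarray:
        return np.array([self.mean, self.var, self.std, self.kurt, self.skew])


def _pairs_in_window(ext: ExtremaSet, peak_ids: list[int], end: int) -> np.ndarray:
    """Paired valley values for the window's peaks whose valley lies before ``end``.

    The valley that terminates a window (the dip under thr3) falls at or
    after the closing sample and is not part of the behavior itself.
    """
    if not peak_ids:
        return np.array([], dtype=float)
    ids = np.asarray(peak_ids, dtype=int)
    v_idx = ext.paired_valley_indices[ids]
    v_val = ext.paired_valley_values[ids]
    return v_val[v_idx < end]


def _valley_test(valleys: np.ndarray, floor: float, quantifier: str) -> bool:
    # peak - valley < peak - floor reduces algebraically to valley > floor
    if len(valleys) == 0:
        return True
    if quantifier == "any":
        return bool(np.any(valleys > floor))
    return bool(np.all(valleys > floor))


def _first_drop(values: np.ndarray, lo: int, hi: int, level: float) -> int | None:
    """First sample index in [lo, hi) where the signal falls below ``level``."""
    seg = values[lo:hi]
    below = np.flatnonzero(seg < level)
    return None if len(below) == 0 else lo + int(below[0])


def detect_running(
    extrema: ExtremaSet,
    cfg: ThresholdConfig | None = None,
    signal: MagnitudeSeries | np.ndarray | None = None,
) -> list[BehaviorWindow]:
    """Scan the peak stream for running episodes.

    A window opens at the first peak above ``thr1`` and closes at the first
    subsequent peak below ``thr2`` (or ``thr3``), or — when the signal is
    supplied and ``close_on_sample`` is on — at the first raw sample that
    drops below ``thr3``, whichever comes first.  A closed window is labeled
    ``running`` when its interior peak-valley pairs keep their valleys above
    ``thr4``; windows failing that test are returned unlabeled so callers
    can inspect them, and a window still open at the end of the trace is
    closed at the final sample with ``truncated=True``.
    """
    cfg = cfg or ThresholdConfig()
    if not extrema.paired:
        raise ValueError("extrema must be paired (run detect_extrema/pair_extrema first)")
    values = None
    if signal is not None:
        values = signal.values if isinstance(signal, MagnitudeSeries) else np.asarray(signal, float)
    n_samples = len(values) if values is not None else (
        int(extrema.peak_indices[-1]) + 1 if extrema.n_peaks() else 0
    )

    windows: list[BehaviorWindow] = []
    p_idx, p_val = extrema.peak_indices, extrema.peak_values
    i = 0
    while i < len(p_idx):
        if p_val[i] <= cfg.thr1:
            i += 1
            continue
        start = int(p_idx[i])
        end = None
        truncated = False
        close_peak_pos = None
        prev_sample = start
        j = i + 1
        while j < len(p_idx):
            if cfg.close_on_sample and values is not None:
                drop = _first_drop(values, prev_sample + 1, int(p_idx[j]), cfg.thr3)
                if drop is not None:
                    end = drop
                    break
            if p_val[j] < cfg.thr2 or p_val[j] < cfg.thr3:
                end = int(p_idx[j])
                close_peak_pos = j
                break
            prev_sample = int(p_idx[j])
            j += 1
        if end is None:
            if cfg.close_on_sample and values is not None:
                drop = _first_drop(values, prev_sample + 1, n_samples, cfg.thr3)
                if drop is not None:
                    end = drop
            if end is None:
                end = n_samples - 1 if n_samples > start + 1 else start + 1
                truncated = True
        peak_ids = [k for k in range(i, len(p_idx)) if start <= p_idx[k] < end]
        win = BehaviorWindow(start_index=start, end_index=end,
                             peak_ids=peak_ids, truncated=truncated)
        valleys = _pairs_in_window(extrema, peak_ids, end)
        if _valley_test(valleys, cfg.thr4, cfg.pair_quantifier):
            win.label = RUNNING
        windows.append(win)
        # resume after the window (skip its closing peak if any)
        i = close_peak_pos + 1 if close_peak_pos is not None else int(
            np.searchsorted(p_idx, end)
        )
    return windows


def detect_leg_shake_candidates(
    extrema: ExtremaSet,
    signal: MagnitudeSeries | np.ndarray,
    cfg: ThresholdConfig | None = None,
    running_windows: list[BehaviorWindow] | None = None,
) -> list[BehaviorWindow]:
    """Scan for leg-shake candidate windows (label assigned later).

    A window opens at a peak above ``thr5`` and closes when the signal
    falls under ``thr3``.  It is a candidate only if every enclosed peak
    stays below the regional restriction ``thr8`` (a peak that high means
    running, not shaking), its peak-valley pairs keep valleys above
    ``thr7``, and it encloses at least ``min_candidate_pairs`` pairs —
    an isolated walking pulse encloses none.  Candidates overlapping a
    running-labeled window are discarded.
    """
    cfg = cfg or ThresholdConfig()
    if not extrema.paired:
        raise ValueError("extrema must be paired (run detect_extrema/pair_extrema first)")
    values = signal.values if isinstance(signal, MagnitudeSeries) else np.asarray(signal, float)
    n_samples = len(values)
    running_windows = [w for w in (running_windows or []) if w.label == RUNNING]

    out: list[BehaviorWindow] = []
    p_idx, p_val = extrema.peak_indices, extrema.peak_values
    i = 0
    while i < len(p_idx):
        if p_val[i] <= cfg.thr5:
            i += 1
            continue
        start = int(p_idx[i])
        truncated = False
        end = _first_drop(values, start + 1, n_samples, cfg.thr3)
        if end is None:
            end = n_samples - 1 if n_samples > start + 1 else start + 1
            truncated = True
        peak_ids = [k for k in range(i, len(p_idx)) if start <= p_idx[k] < end]
        win = BehaviorWindow(start_index=start, end_index=end,
                             peak_ids=peak_ids, truncated=truncated)
        overlapped = [rw for rw in running_windows if win.overlaps(rw)]
        if overlapped:
            # a shake bout directly after a run would be swallowed by the
            # discarded window; re-scan from the end of the running episode
            i = int(np.searchsorted(p_idx, max(rw.end_index for rw in overlapped)))
            continue
        valleys = _pairs_in_window(extrema, peak_ids, end)
        is_candidate = (
            bool(np.all(p_val[peak_ids] < cfg.thr8))
            and _valley_test(valleys, cfg.thr7, cfg.pair_quantifier)
            and len(valleys) >= cfg.min_candidate_pairs
        )
        if is_candidate:
            out.append(win)
        i = int(np.searchsorted(p_idx, end))
    return out


def window_variance(gyro_x: np.ndarray, window: BehaviorWindow,
                    population: bool = True) -> float:
    seg = np.asarray(gyro_x, dtype=float)[window.start_index:window.end_index]
    return float(np.var(seg, ddof=0 if population else 1))


def classify_candidate(
    window: BehaviorWindow,
    gyro_x: np.ndarray,
    cfg: ThresholdConfig | None = None,
) -> str:
    """Label a candidate window leg_shake or fast_walk by gyro-x variance.

    Variance strictly above ``var_cut`` means the leg is flailing (shake);
    at or below it the motion is a supported brisk gait.  Sets and returns
    the window label.
    """
    cfg = cfg or ThresholdConfig()
    if window.W < 2:
        warnings.warn("window shorter than 2 samples: variance undefined, "
                      "labeling fast_walk", stacklevel=2)
        window.label = FAST_WALK
        return FAST_WALK
    var = window_variance(gyro_x, window, population=cfg.population_variance)
    window.label = LEG_SHAKE if var > cfg.var_cut else FAST_WALK
    return window.label


def extract_features(values: np.ndarray) -> FeatureVector:
    """Moment features of a gyro-x window (population convention).

    A degenerate (constant) window has undefined standardized moments;
    skew and kurt are reported as 0 with a warning.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("feature window must contain at least 2 samples")
    mean = float(np.mean(x))
    d = x - mean
    m2 = float(np.mean(d**2))
    if m2 < 1e-24:
        warnings.warn("constant window: skew and kurt reported as 0", stacklevel=2)
        return FeatureVector(mean=mean, var=0.0, std=0.0, kurt=0.0, skew=0.0)
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return FeatureVector(
        mean=mean,
        var=m2,
        std=math.sqrt(m2),
        kurt=m4 / m2**2 - 3.0,
        skew=m3 / m2**1.5,
    )


def cluster_behaviors(
    features: list[FeatureVector] | np.ndarray,
    k: int = 3,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """K-means clustering of feature vectors (exploratory analysis).

    This is the analysis that motivates using gyro-x variance as the
    shake/fast-walk discriminator; it is not part of the runtime counting
    pipeline.  Lloyd's algorithm with 10 restarts, deterministic given
    ``seed``.  Returns (labels, centroids).
    """
    X = np.asarray([f.as_array() if isinstance(f, FeatureVector) else f
                    for f in features], dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if len(X) < k:
        raise ValueError(f"need at least k={k} feature rows, got {len(X)}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy, precision and recall from a binary confusion matrix.

    An undefined ratio (zero denominator) is NaN with the matching
    ``*_defined`` flag cleared.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float

    @property
    def precision_defined(self) -> bool:
        return not math.isnan(self.precision)

    @property
    def recall_defined(self) -> bool:
        return not math.isnan(self.recall)


def classification_metrics(predicted, actual, positive=None) -> ClassificationMetrics:
    """accuracy = (TP+TN)/(TP+FP+FN+TN), precision = TP/(TP+FP), recall = TP/(TP+FN).

    ``predicted`` and ``actual`` are equal-length binary label sequences;
    ``positive`` defaults to True/1 or, for string labels, must be given.
    """
    pred = list(predicted)
    act = list(actual)
    if len(pred) != len(act):
        raise ValueError("predicted and actual must have equal length")
    if len(pred) == 0:
        raise ValueError("empty label sequences")
    labels = set(pred) | set(act)
    if len(labels) > 2:
        raise ValueError(f"binary labels expected, got {sorted(map(str, labels))}")
    if positive is None:
        if labels <= {0, 1} or labels <= {False, True}:
            positive = 1
        else:
            raise ValueError("positive label must be specified for non-boolean labels")
    tp = sum(1 for p, a in zip(pred, act) if p == positive and a == positive)
    tn = sum(1 for p, a in zip(pred, act) if p != positive and a != positive)
    fp = sum(1 for p, a in zip(pred, act) if p == positive and a != positive)
    fn = sum(1 for p, a in zip(pred, act) if p != positive and a == positive)
    total = tp + tn + fp + fn
    return ClassificationMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=(tp + tn) / total,
        precision=tp / (tp + fp) if (tp + fp) > 0 else math.nan,
        recall=tp / (tp + fn) if (tp + fn) > 0 else math.nan,
    )
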