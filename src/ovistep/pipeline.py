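"""End-to-end step counting: combine → filter → extrema → behaviors → aggregate."""

from __future__ import annotations

from dataclasses import dataclass, field

from .behavior import (
    RUNNING,
    BehaviorWindow,
    classify_candidate,
    detect_leg_shake_candidates,
    detect_running,
)
from .config import RunConfig
from .extrema import ExtremaSet, detect_extrema
from .signal import ImuSeries, MagnitudeSeries, combine_acceleration, low_pass, split_on_gaps
from .stepcount import StepReport, aggregate

__all__ = ["PipelineResult", "count_steps"]


@dataclass
class PipelineResult:
    """Step report plus the intermediate artifacts that produced it."""

    report: StepReport
    magnitude: MagnitudeSeries
    extrema: ExtremaSet
    windows: list[BehaviorWindow] = field(default_factory=list)


def _count_segment(series: ImuSeries, config: RunConfig) -> PipelineResult:
    thr = config.thresholds
    mag = combine_acceleration(series)
    if config.filter.enabled:
        mag = low_pass(mag, cutoff_hz=config.filter.cutoff_hz,
                       order=config.filter.order)
    ext = detect_extrema(mag, n_peak=thr.n_peak, n_valley=thr.n_valley, thr=thr.thr)
    run_wins = detect_running(ext, thr, signal=mag)
    running = [w for w in run_wins if w.label == RUNNING]
    candidates = detect_leg_shake_candidates(ext, mag, thr, running_windows=running)
    for cand in candidates:
        classify_candidate(cand, series.gyro_x, thr)
    windows = running + candidates
    report = aggregate(ext, windows, thr)
    return PipelineResult(report=report, magnitude=mag, extrema=ext, windows=windows)


def count_steps(
    series: ImuSeries,
    config: RunConfig | None = None,
) -> tuple[StepReport, list[PipelineResult]]:
    """Run the full counting pipeline on a six-axis trace.

    Traces with timestamp gaps longer than 2/fs are split and each
    contiguous segment is processed independently; counts are summed.
    Returns the (total) report and the per-segment results.
    """
    config = config or RunConfig()
    segments = split_on_gaps(series)
    results = [_count_segment(seg, config) for seg in segments]
    if len(results) == 1:
        return results[0].report, results
    total = {}
    for res in results:
        for k, v in res.report.to_dict().items():
            total[k] = total.get(k, 0) + v
    return StepReport(**total), results
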