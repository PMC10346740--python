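"""Threshold and pipeline configuration.

All tunable constants of the step-counting pipeline live here, so that no
threshold is ever hard-coded at a call site.  The defaults are the operating
point for leg-mounted sensors on sheep sampled at 32 Hz: a walking step shows
one combined-acceleration peak above 12 m/s^2 roughly every 29 samples,
running drives peaks above 30 m/s^2 with elevated valleys, and leg shaking
produces walking-amplitude peaks (below 39 m/s^2) with high x-axis gyro
variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import yaml

__all__ = ["ThresholdConfig", "FilterConfig", "IoConfig", "RunConfig", "load_config"]


@dataclass
class ThresholdConfig:
    """Thresholds and constants of the detection and counting rules.

    Parameters
    ----------
    thr
        Minimum combined-acceleration peak height (m/s^2) for a step peak.
    thr1
        Peak height opening a running window (m/s^2).
    thr2
        Peak height below which a running window closes (m/s^2).
    thr3
        Signal level below which any behavior window closes (m/s^2);
        dropping under it means the animal is strolling or motionless.
    thr4
        Valley floor for the running peak-valley test (m/s^2): a window is
        running only if its interior valleys stay above ``thr4``.
    thr5
        Peak height opening a leg-shake candidate window (m/s^2).
    thr7
        Valley floor for the leg-shake peak-valley test (m/s^2).
    thr8
        Regional peak restriction (m/s^2): every peak inside a leg-shake
        candidate must stay below it, separating leg shaking from running.
    var_cut
        x-axis gyro variance separating leg shaking (above) from fast
        walking (below), in squared gyro units (default rad^2/s^2).
    n_peak, n_valley
        Half-widths of the two-sided monotonicity window for peak and
        valley detection (samples).
    K
        Scale factor converting a running-window length to steps.
    L
        Mean samples per normal walking step at ``fs`` (samples).
    fs
        Sampling frequency (Hz).
    pair_quantifier
        Whether ``all`` interior peak-valley pairs must satisfy the
        valley-floor test for a window to qualify, or ``any``.
    close_on_sample
        Close behavior windows as soon as the raw signal drops below
        ``thr3``, in addition to the closing-peak tests.  Without it a
        window would stay open across a standstill, because peaks below
        the step threshold never enter the extrema stream.
    min_candidate_pairs
        Minimum number of interior peak-valley pairs for a leg-shake
        candidate.  Sustained shaking keeps the signal above ``thr3`` for
        several oscillations; an isolated walking pulse encloses no pair.
    population_variance
        Use the population (divisor N) variance for the ``var_cut`` test;
        set False for the sample (N-1) convention.
    rounding
        How running steps R = W*K/L become an integer: nearest integer
        with halves away from zero, or floor.
    """

    thr: float = 12.0
    thr1: float = 30.0
    thr2: float = 20.0
    thr3: float = 12.0
    thr4: float = 20.0
    thr5: float = 12.0
    thr7: float = 12.0
    thr8: float = 39.0
    var_cut: float = 10.0
    n_peak: int = 4
    n_valley: int = 2
    K: float = 2.1
    L: int = 29
    fs: float = 32.0
    pair_quantifier: Literal["all", "any"] = "all"
    close_on_sample: bool = True
    min_candidate_pairs: int = 1
    population_variance: bool = True
    rounding: Literal["half_away", "floor"] = "half_away"

    def __post_init__(self) -> None:
        for name in ("thr", "thr1", "thr2", "thr3", "thr4", "thr5", "thr7",
                     "thr8", "var_cut", "K", "L", "fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.thr1 > self.thr2 > self.thr3):
            raise ValueError("thresholds must satisfy thr1 > thr2 > thr3")
        if self.n_peak < 1 or self.n_valley < 1:
            raise ValueError("window half-widths must be >= 1")
        if self.pair_quantifier not in ("all", "any"):
            raise ValueError("pair_quantifier must be 'all' or 'any'")
        if self.rounding not in ("half_away", "floor"):
            raise ValueError("rounding must be 'half_away' or 'floor'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FilterConfig:
    """Low-pass filter applied to the combined acceleration.

    A zero-phase second-order Butterworth at 5 Hz: walking cadence is about
    1 Hz and running harmonics stay below ~5 Hz at 32 Hz sampling, so the
    pass band keeps every gait component while removing sensor noise.
    Zero-phase (forward-backward) filtering keeps peak sample indices
    unlagged, so sample-index arithmetic on windows stays meaningful.
    """

    cutoff_hz: float = 5.0
    order: int = 2
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass
class IoConfig:
    """CSV dialect for six-axis input files."""

    time_col: str = "time"
    acc_cols: tuple[str, str, str] = ("acc_x", "acc_y", "acc_z")
    gyro_cols: tuple[str, str, str] = ("gyro_x", "gyro_y", "gyro_z")
    delimiter: str = ","


@dataclass
class RunConfig:
    """Full pipeline configuration: thresholds, filtering and I/O."""

    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    io: IoConfig = field(default_factory=IoConfig)

    def to_dict(self) -> dict:
        return {
            "thresholds": asdict(self.thresholds),
            "filter": asdict(self.filter),
            "io": asdict(self.io),
        }


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file.

    Unknown keys raise; threshold invariants are validated at load.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {"thresholds", "filter", "io"}
    extra = set(raw) - known
    if extra:
        raise ValueError(f"unknown config sections: {sorted(extra)}")
    kwargs = {}
    if "thresholds" in raw:
        kwargs["thresholds"] = ThresholdConfig(**raw["thresholds"])
    if "filter" in raw:
        kwargs["filter"] = FilterConfig(**raw["filter"])
    if "io" in raw:
        io = dict(raw["io"])
        for k in ("acc_cols", "gyro_cols"):
            if k in io:
                io[k] = tuple(io[k])
        kwargs["io"] = IoConfig(**io)
    return RunConfig(**kwargs)
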