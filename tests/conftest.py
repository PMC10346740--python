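"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive every rule with plain Python loops and
no numpy vectorization, so they share no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ovistep.simulate import SegmentSpec


def brute_force_peaks(x, n: int, thr: float) -> list[int]:
    """Direct evaluation of the two-sided monotonicity peak condition."""
    out = []
    for i in range(len(x)):
        if i < n or i >= len(x) - n:
            continue
        if not x[i] > thr:
            continue
        left = all(x[i - k] - x[i - k - 1] > 0 for k in range(n))
        right = all(x[i + k] - x[i + k + 1] > 0 for k in range(n))
        if left and right:
            out.append(i)
    return out


def brute_force_valleys(x, n: int) -> list[int]:
    out = []
    for i in range(len(x)):
        if i < n or i >= len(x) - n:
            continue
        left = all(x[i - k] - x[i - k - 1] < 0 for k in range(n))
        right = all(x[i + k] - x[i + k + 1] < 0 for k in range(n))
        if left and right:
            out.append(i)
    return out


def brute_force_moments(values) -> dict[str, float]:
    """Direct-summation population moments (mean, var, std, kurt, skew)."""
    vals = [float(v) for v in values]
    n = len(vals)
    mean = sum(vals) / n
    m2 = sum((v - mean) ** 2 for v in vals) / n
    if m2 == 0:
        return {"mean": mean, "var": 0.0, "std": 0.0, "kurt": 0.0, "skew": 0.0}
    m3 = sum((v - mean) ** 3 for v in vals) / n
    m4 = sum((v - mean) ** 4 for v in vals) / n
    return {
        "mean": mean,
        "var": m2,
        "std": math.sqrt(m2),
        "kurt": m4 / m2**2 - 3.0,
        "skew": m3 / m2**1.5,
    }


def mixed_trace_specs(n_walk=(15, 10, 5)) -> list[SegmentSpec]:
    """A day-in-the-life trace: walking interleaved with running, shaking,

    fast walking and standing still, at the generator's default amplitudes.
    """
    return [
        SegmentSpec("stationary", 3.0),
        SegmentSpec("walk", n_walk[0] * 29 / 32),
        SegmentSpec("run", 8.0),
        SegmentSpec("walk", n_walk[1] * 29 / 32),
        SegmentSpec("leg_shake", 5.0),
        SegmentSpec("stationary", 2.0),
        SegmentSpec("fast_walk", 5.0),
        SegmentSpec("walk", n_walk[2] * 29 / 32),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def single_peak_signal():
    """The canonical one-peak ramp: peak of 14 at index 7 under n=4, thr=12."""
    return np.array([9, 9, 9, 10, 11, 12, 13, 14, 13, 12, 11, 10, 9, 9, 9], dtype=float)
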