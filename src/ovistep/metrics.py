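"""Evaluation arithmetic for step-count predictions.

Per-trial accuracy is the relative error |pred - true| / true * 100, i.e.
(Pre - True)/(True/100) in magnitude.  K-factor calibration is scored with
MSE, RMSE and MAE over signed per-window step errors; the summaries here
use an n-1 divisor for MSE and MAE (the convention the bundled field-trial
tables were computed with — see the docs), switchable to the standard n
divisor.  Display rounding follows the tables: 2 decimals per row, 3 for
means, with halves away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "round_half_away",
    "relative_error",
    "ErrorTable",
    "error_table",
    "mean_relative_error",
    "mse_rmse_mae",
    "detection_error_rate",
]


def round_half_away(x, decimals: int = 0):
    """Decimal rounding with ties going away from zero (unlike numpy's

    banker's rounding); a small epsilon guards against 0.49999... floats
    produced by decimal-exact halves.
    """
    x = np.asarray(x, dtype=float)
    scaled = x * 10.0**decimals
    out = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5 + 1e-9) / 10.0**decimals
    return float(out) if out.ndim == 0 else out


def relative_error(true, pred):
    """|pred - true| / true * 100, in percent.

    Scale-free and non-negative.  A zero true count makes the ratio
    undefined and returns NaN.  Accepts scalars or arrays.
    """
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(t > 0, np.abs(p - t) / t * 100.0, np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass
class ErrorTable:
    """True vs. predicted counts with per-row relative errors and their mean.

    ``relative_errors`` holds full-precision percentages; ``rounded`` the
    2-decimal display values.  ``summary`` is the arithmetic mean of the
    rounded rows (the tables' convention: means are taken over the printed
    2-decimal entries), and ``summary_exact`` the mean of the unrounded
    rows.
    """

    true_values: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        self.true_values = np.asarray(self.true_values, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.true_values.shape != self.predicted.shape:
            raise ValueError("true and predicted must have equal length")
        if len(self.true_values) == 0:
            raise ValueError("error table cannot be empty")

    @property
    def relative_errors(self) -> np.ndarray:
        return relative_error(self.true_values, self.predicted)

    @property
    def rounded(self) -> np.ndarray:
        return round_half_away(self.relative_errors, 2)

    @property
    def summary(self) -> float:
        return float(np.mean(self.rounded))

    @property
    def summary_exact(self) -> float:
        return float(np.mean(self.relative_errors))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "true": self.true_values,
            "predicted": self.predicted,
            "relative_error_pct": self.rounded,
        })


def error_table(true, pred) -> ErrorTable:
    return ErrorTable(true_values=np.asarray(true), predicted=np.asarray(pred))


def mean_relative_error(true, pred, rounded_rows: bool = True) -> float:
    """Unweighted mean of per-row relative errors, in percent.

    With ``rounded_rows`` (default) each row is first rounded to 2
    decimals, matching how published summary means are formed from
    printed per-row values.
    """
    tab = error_table(true, pred)
    return tab.summary if rounded_rows else tab.summary_exact


def mse_rmse_mae(errors, bessel: bool = True) -> tuple[float, float, float]:
    """(MSE, RMSE, MAE) of signed step errors.

    With ``bessel`` (default) MSE = sum(e^2)/(n-1) and MAE = sum(|e|)/(n-1);
    pass False for the standard 1/n divisor.  RMSE is always sqrt(MSE).
    Needs at least two errors.
    """
    e = np.asarray(errors, dtype=float)
    if len(e) < 2:
        raise ValueError("need at least 2 errors")
    denom = len(e) - 1 if bessel else len(e)
    mse = float(np.sum(e**2) / denom)
    mae = float(np.sum(np.abs(e)) / denom)
    return mse, math.sqrt(mse), mae


def detection_error_rate(errors: int, detections: int) -> float:
    """SER = detection errors / detections for leg-shake detection.

    NaN when no detections were made (undefined rate).
    """
    if errors < 0 or detections < 0:
        raise ValueError("counts must be non-negative")
    if detections == 0:
        return math.nan
    if errors > detections:
        raise ValueError("errors cannot exceed detections")
    return errors / detections
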