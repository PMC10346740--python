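"""Bundled field-trial evaluation records.

Small tables from the grazing-sheep field trial that this algorithm was
calibrated and evaluated against: manual step counts from synchronized
video against the counts of a plain peak-detection counter and of the
behavior-classification counter, the running/leg-shake evaluation, and
the K-factor calibration sweep.  They are inputs to the evaluation
arithmetic in :mod:`ovistep.metrics` and :mod:`ovistep.stepcount`; the
raw sensor recordings themselves are not public.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["step_predictions", "running_and_shake", "k_sweep_errors", "K_SWEEP_TRUE_STEPS"]


def step_predictions() -> pd.DataFrame:
    """Total-step evaluation: two one-hour sessions per animal over four days.

    Columns: observation date and animal, the manual (video) count
    ``true``, the plain peak-detection prediction ``pred_peak`` and the
    behavior-classification prediction ``pred_behavior``.
    """
    rows = [
        ("Sep 3", "Ram1", 147, 154, 155),
        ("Sep 3", "Ram1", 125, 131, 132),
        ("Sep 5", "Ewe1", 100, 93, 93),
        ("Sep 5", "Ewe1", 82, 158, 101),
        ("Sep 6", "Ram2", 78, 88, 80),
        ("Sep 6", "Ram2", 219, 229, 217),
        ("Sep 7", "Ewe2", 243, 238, 238),
        ("Sep 7", "Ewe2", 187, 165, 193),
    ]
    return pd.DataFrame(rows, columns=["date", "sheep", "true",
                                       "pred_peak", "pred_behavior"])


def running_and_shake() -> pd.DataFrame:
    """Running-step and leg-shake-detection evaluation, one day per row.

    ``run_true``: manual running-step count; ``run_pred_peak`` /
    ``run_pred_behavior``: the two algorithms' running-step estimates;
    ``shake_detections``: leg-shake windows detected; ``shake_errors``:
    how many of those were wrong.
    """
    rows = [
        ("Sep 3", 56, 43, 60, 5, 1),
        ("Sep 5", 9, 8, 9, 25, 2),
        ("Sep 6", 81, 65, 78, 12, 1),
        ("Sep 7", 83, 63, 98, 1, 1),
    ]
    return pd.DataFrame(rows, columns=["date", "run_true", "run_pred_peak",
                                       "run_pred_behavior", "shake_detections",
                                       "shake_errors"])


#: Manual running-step counts of the eight calibration windows.
K_SWEEP_TRUE_STEPS = np.array([15, 38, 54, 19, 25, 16, 29, 24])


def k_sweep_errors() -> pd.DataFrame:
    """Signed per-window step errors of the K calibration sweep.

    One row per candidate scale factor K (1.5-2.5 in steps of 0.1); the
    eight error columns are round(W*K/L) - true for the eight calibration
    running windows whose manual counts are :data:`K_SWEEP_TRUE_STEPS`.
    """
    rows = {
        1.5: [-2, -9, -11, -3, -6, -3, -3, -3],
        1.6: [-1, -8, -9, -3, -5, -2, -2, -3],
        1.7: [0, -6, -7, -2, -4, -2, -1, -2],
        1.8: [0, -5, -5, -1, -3, -1, 0, -2],
        1.9: [1, -4, -4, 0, -2, -1, 0, -1],
        2.0: [2, -2, -2, 0, -1, 0, 1, 0],
        2.1: [2, -1, 0, 1, 1, 1, 2, 0],
        2.2: [3, 1, 2, 2, 2, 1, 3, 1],
        2.3: [4, 2, 4, 3, 3, 2, 4, 1],
        2.4: [5, 4, 6, 4, 4, 2, 4, 2],
        2.5: [5, 5, 8, 4, 5, 3, 5, 2],
    }
    df = pd.DataFrame(
        [(k, *errs) for k, errs in rows.items()],
        columns=["K", *(f"e{i}" for i in range(1, 9))],
    )
    return df
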