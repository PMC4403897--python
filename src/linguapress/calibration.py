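"""Sensor calibration verification.

The pressure sensor is checked against a reference source (classically a
mercury sphygmomanometer) over 0-300 mmHg. A straight line is fitted to
the readback-vs-reference pairs by ordinary least squares; the sensor
passes when every residual over the accuracy range (0-225 mmHg, where the
sensing module is specified to ~1 mmHg) stays within tolerance. Fitting
both slope and intercept, rather than assuming the identity line, lets the
check detect gain drift and offset drift separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ACCURACY_RANGE_MMHG",
    "CALIBRATION_RANGE_MMHG",
    "CalibrationRecord",
    "CalibrationFit",
    "fit_calibration",
    "compare_sessions",
]

#: Range over which the reference check is performed, mmHg.
CALIBRATION_RANGE_MMHG = (0.0, 300.0)
#: Range over which the sensor's ~1 mmHg accuracy is specified, mmHg.
ACCURACY_RANGE_MMHG = (0.0, 225.0)


@dataclass(frozen=True)
class CalibrationRecord:
    """Reference/readback pressure pairs from one calibration session."""

    reference: np.ndarray
    readback: np.ndarray
    session_date: str = ""

    def __post_init__(self):
        ref = np.asarray(self.reference, dtype=float)
        rb = np.asarray(self.readback, dtype=float)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "readback", rb)
        if ref.shape != rb.shape or ref.ndim != 1:
            raise ValueError("reference and readback must be 1-D of equal length")
        if len(ref) < 3:
            raise ValueError("calibration needs at least 3 points")
        if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(rb))):
            raise ValueError("calibration pressures must be finite")
        lo, hi = CALIBRATION_RANGE_MMHG
        if ref.min() < lo or ref.max() > hi:
            raise ValueError(f"reference pressures must lie in [{lo}, {hi}] mmHg")


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line through the calibration pairs plus the pass decision."""

    slope: float
    intercept: float
    residuals: np.ndarray
    max_abs_residual: float
    pass_flag: bool
    tolerance: float

    def predict(self, pressure) -> np.ndarray:
        return self.slope * np.asarray(pressure, dtype=float) + self.intercept


def fit_calibration(
    record: CalibrationRecord, tolerance: float = 1.0
) -> CalibrationFit:
    """Fit ``readback = slope * reference + intercept`` and gate on residuals.

    The pass decision uses the maximum absolute residual restricted to
    reference points inside the accuracy range (<= 225 mmHg), compared to
    ``tolerance`` (default: the sensor's stated 1 mmHg accuracy).
    """
    ref, rb = record.reference, record.readback
    if np.ptp(ref) == 0:
        raise ValueError("degenerate calibration: all reference pressures equal")
    res = stats.linregress(ref, rb)
    slope, intercept = float(res.slope), float(res.intercept)
    residuals = rb - (slope * ref + intercept)
    in_range = ref <= ACCURACY_RANGE_MMHG[1]
    max_abs = float(np.max(np.abs(residuals[in_range]))) if in_range.any() else 0.0
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        residuals=residuals,
        max_abs_residual=max_abs,
        pass_flag=bool(max_abs <= tolerance),
        tolerance=float(tolerance),
    )


def compare_sessions(
    fit_a: CalibrationFit,
    fit_b: CalibrationFit,
    pressure_grid=None,
    tolerance: float = 1.0,
) -> dict:
    """Maximum predicted-readback disagreement between two sessions.

    Evaluates both fitted lines over ``pressure_grid`` (default: 1 mmHg
    steps across the calibration range) and reports the largest absolute
    difference and whether it exceeds ``tolerance`` (drift flag).
    """
    if pressure_grid is None:
        pressure_grid = np.arange(CALIBRATION_RANGE_MMHG[0], CALIBRATION_RANGE_MMHG[1] + 1.0, 1.0)
    grid = np.asarray(pressure_grid, dtype=float)
    diff = np.abs(fit_a.predict(grid) - fit_b.predict(grid))
    i = int(np.argmax(diff))
    return {
        "max_drift_mmHg": float(diff[i]),
        "at_pressure_mmHg": float(grid[i]),
        "tolerance_mmHg": float(tolerance),
        "drift_flag": bool(diff[i] > tolerance),
    }
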