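"""Goniometer calibration and gait-cycle segmentation.

Calibration is a two-posture procedure: the sensors are zeroed while the
subject stands upright, then a known reference posture is recorded — sitting
(90° hip and knee flexion) and resting the feet on an inclined platform
(43° ankle dorsiflexion, since the ankle cannot physically reach 90°).  A
raw reading y is then linearly mapped to

    y_map = (y − zero) / x · x0

where x is the measured calibration maximum (the "joint factor") and x0 the
reference angle of the calibration posture.  The map is exact at both
endpoints: the zero posture maps to 0° and the maximum posture to x0.

Gait cycles are delimited by successive peaks of one joint trace, by default
right-hip flexion: one cycle spans peak-to-peak, so n peaks yield n−1 cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "CalibrationError", "CalibrationParams", "GaitCycle",
    "JOINT_CLASS_REFERENCE", "calibrate", "map_angle", "segment_gait",
]


class CalibrationError(ValueError):
    """Degenerate or invalid calibration."""


#: Reference maxima x0 of the calibration postures, degrees.
JOINT_CLASS_REFERENCE: dict[str, float] = {"hip": 90.0, "knee": 90.0,
                                           "ankle": 43.0}


@dataclass(frozen=True)
class CalibrationParams:
    """Linear calibration of one goniometer channel.

    zero_offset: raw reading in the standing (zero) posture, degrees.
    measured_max: x, raw excursion from zero to the calibration posture.
    reference_max: x0, 90° for hip/knee, 43° for ankle.
    """

    zero_offset: float
    measured_max: float
    reference_max: float

    def __post_init__(self) -> None:
        if self.measured_max <= 0:
            raise CalibrationError(
                f"measured calibration range must be positive, "
                f"got {self.measured_max}")
        if self.reference_max not in JOINT_CLASS_REFERENCE.values():
            raise CalibrationError(
                f"reference maximum must be one of "
                f"{sorted(set(JOINT_CLASS_REFERENCE.values()))}, "
                f"got {self.reference_max}")

    @property
    def slope(self) -> float:
        """Degrees of mapped angle per degree of raw reading (= x0/x)."""
        return self.reference_max / self.measured_max


def calibrate(zero_posture_reading: float, max_posture_reading: float,
              joint_class: str) -> CalibrationParams:
    """Build calibration parameters from the two posture readings.

    ``joint_class`` is 'hip', 'knee' or 'ankle' and selects the reference
    maximum x0.  Raises :class:`CalibrationError` when the two readings
    coincide (zero range).
    """
    try:
        x0 = JOINT_CLASS_REFERENCE[joint_class.lower()]
    except KeyError:
        raise CalibrationError(
            f"unknown joint class {joint_class!r}; expected one of "
            f"{sorted(JOINT_CLASS_REFERENCE)}") from None
    x = float(max_posture_reading) - float(zero_posture_reading)
    if x == 0:
        raise CalibrationError(
            "degenerate calibration: maximum-posture reading equals "
            "zero-posture reading")
    if x < 0:
        raise CalibrationError(
            "calibration range is negative: maximum-posture reading lies "
            "below the zero-posture reading")
    return CalibrationParams(float(zero_posture_reading), x, x0)


def map_angle(y_raw, params: CalibrationParams, warn_extrapolation: bool = True):
    """Map raw reading(s) to calibrated degrees: (y − zero)/x · x0.

    The map is affine in the raw reading and is applied unchanged outside
    the calibrated range [zero, zero + x] (extension beyond the standing
    zero maps to negative angles); extrapolation is flagged with a warning.
    """
    y = np.asarray(y_raw, dtype=float)
    mapped = (y - params.zero_offset) / params.measured_max * params.reference_max
    if warn_extrapolation:
        excursion = y - params.zero_offset
        if np.any(excursion > params.measured_max) or np.any(excursion < -params.measured_max):
            warnings.warn("raw reading outside the calibrated range; the "
                          "linear map was extrapolated", stacklevel=2)
    if np.isscalar(y_raw):
        return float(mapped)
    return mapped


@dataclass(frozen=True)
class GaitCycle:
    """One stride: half-open sample span [start_index, end_index)."""

    start_index: int
    end_index: int
    duration: float         # seconds

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("gait cycle must end after it starts")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index


def segment_gait(joint_trace, sampling_rate: float,
                 expected_cadence_bounds: tuple[float, float] = (0.4, 1.5),
                 prominence_fraction: float = 0.10,
                 smooth_window: float = 0.15) -> list[GaitCycle]:
    """Segment a joint-angle trace into gait cycles at flexion maxima.

    The trace is first smoothed with a centered moving average of
    ``smooth_window`` seconds (suppresses sample-level sensor noise without
    moving stride-scale peaks).  Peaks are then local maxima separated by
    at least 0.6 / cadence_upper seconds with prominence of at least
    ``prominence_fraction`` of the trace's inter-quartile range, which
    makes the segmentation deterministic, robust to additive noise, and
    invariant to amplitude scaling.  Cycles span successive peaks, so n
    peaks give n − 1 cycles.  Fewer than two peaks (e.g. a constant trace)
    yields an empty list with a warning.
    """
    trace = np.asarray(joint_trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("joint_trace must be one-dimensional")
    lo, hi = expected_cadence_bounds
    if not (0 < lo < hi):
        raise ValueError("cadence bounds must satisfy 0 < lower < upper")
    win = int(round(smooth_window * sampling_rate))
    if win > 1 and trace.size >= win:
        kernel = np.ones(win) / win
        trace = np.convolve(trace, kernel, mode="same")
    q1, q3 = np.percentile(trace, [25, 75]) if trace.size else (0.0, 0.0)
    iqr = q3 - q1
    if iqr <= 0:
        warnings.warn("flat joint trace: no gait cycles found", stacklevel=2)
        return []
    min_distance = max(1, int(round(0.6 * sampling_rate / hi)))
    peaks, _ = find_peaks(trace, distance=min_distance,
                          prominence=prominence_fraction * iqr)
    if peaks.size < 2:
        warnings.warn(f"found {peaks.size} peak(s); at least 2 are needed "
                      f"to delimit a gait cycle", stacklevel=2)
        return []
    return [GaitCycle(int(a), int(b), (b - a) / sampling_rate)
            for a, b in zip(peaks[:-1], peaks[1:])]
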