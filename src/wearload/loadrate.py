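"""The estimated mean load-rate magnitude.

Load rate is the time derivative of the weight-bearing force on the lower
limb, in N/s.  From a triaxial accelerometer it is estimated through
Newton's second law as body mass times the jerk magnitude, averaged over
the first differences of the sampled signal:

    mean_j  m * sqrt( sum_i ((a_i[j+1] - a_i[j]) / dt)^2 ),   i = x, y, z

with n samples at interval dt (so n-1 difference terms).  From a calibrated
force plate the analogous statistic is the mean absolute first difference
of the vertical force divided by dt.  No filtering is applied anywhere:
averaging over the many steps in a 60-s window stands in for smoothing.

Differencing cancels any constant offset, so gravity (and any constant
sensor bias) drops out of the accelerometer estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, UsageError
from .signal_io import AccelSeries, ForceSeries, is_uniform

__all__ = [
    "LoadRateSummary",
    "mean_load_rate_from_accel",
    "mean_load_rate_from_force",
    "sensor_error_ratio",
]


@dataclass(frozen=True)
class LoadRateSummary:
    """One device's estimated mean load-rate magnitude for one trial."""

    value: float  # N/s, >= 0
    n_samples: int  # samples entering the estimate (>= 2)
    device_id: str
    source: str  # "accel" | "force"


def _grid_step(timestamps: np.ndarray) -> float:
    if timestamps.size < 2:
        raise InsufficientDataError("need at least 2 samples to difference")
    if not is_uniform(timestamps):
        raise UsageError("series is not on a uniform grid; resample_uniform it first")
    return float(np.median(np.diff(timestamps)))


def mean_load_rate_from_accel(series: AccelSeries, mass: float) -> LoadRateSummary:
    """Estimated mean load-rate magnitude (N/s) from a triaxial accelerometer.

    ``mass`` is the participant's body mass in kg.  The series must be on a
    uniform time grid with at least two samples.
    """
    if mass <= 0:
        raise UsageError(f"mass must be > 0 kg, got {mass}")
    dt = _grid_step(series.timestamps)
    jerk_mag = np.sqrt(
        np.diff(series.ax) ** 2 + np.diff(series.ay) ** 2 + np.diff(series.az) ** 2
    ) / dt
    value = mass * float(jerk_mag.mean())
    return LoadRateSummary(
        value=value, n_samples=len(series), device_id=series.device_id, source="accel"
    )


def mean_load_rate_from_force(series: ForceSeries) -> LoadRateSummary:
    """Estimated mean load-rate magnitude (N/s) from a calibrated force plate."""
    if not series.calibrated:
        raise UsageError("force series must be calibrated before estimating load rate")
    dt = _grid_step(series.timestamps)
    value = float(np.mean(np.abs(np.diff(series.values)))) / dt
    return LoadRateSummary(
        value=value, n_samples=len(series), device_id=series.device_id, source="force"
    )


def sensor_error_ratio(device_derived, reference_derived) -> float:
    """Time-domain root-mean-squared error ratio between two aligned series, in percent.

    Defined as 100 * RMS(device - reference) / RMS(reference); used for the
    bench (shaker-rig) comparison of a wearable against a reference
    accelerometer, both expressed as load-rate time series.
    """
    d = np.asarray(device_derived, dtype=float)
    r = np.asarray(reference_derived, dtype=float)
    if d.shape != r.shape:
        raise UsageError(f"series shapes differ: {d.shape} vs {r.shape}")
    ref_rms = float(np.sqrt(np.mean(r**2)))
    if ref_rms == 0.0:
        raise UsageError("reference series is identically zero; ratio undefined")
    return 100.0 * float(np.sqrt(np.mean((d - r) ** 2))) / ref_rms
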