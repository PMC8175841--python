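"""Sensor CSV I/O, force-plate calibration and trial windowing.

Trials are 90-s recordings: a triaxial wearable accelerometer stream at a
nominal 50 Hz and a force-plate channel at a nominal 128 Hz.  The first
20 s of each trial are a habituation period and are discarded, the next
60 s form the analysis window, and the final 10 s are dropped to avoid
end-of-trial behaviour changes.  On a uniform grid this leaves exactly
``rate * 60`` samples per trial (7680 at 128 Hz, 3000 at 50 Hz).

The force plate is read either as already-calibrated newtons
(``t_s,force_N``) or as raw load-cell voltages (``t_s,v1,v2,v3,v4``); the
four load-cell channels are summed into one vertical signal and mapped to
newtons through a linear calibration fitted to known weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as _st

from .errors import (
    CalibrationError,
    FormatError,
    SeriesValidationError,
    UsageError,
    WindowError,
)

__all__ = [
    "AccelSeries",
    "ForceSeries",
    "CalibrationModel",
    "read_accel_csv",
    "write_accel_csv",
    "read_force_csv",
    "write_force_csv",
    "read_calibration_csv",
    "fit_calibration",
    "apply_calibration",
    "invert_calibration",
    "extract_window",
    "resample_uniform",
]

STANDARD_GRAVITY = 9.81  # m/s^2

ACCEL_COLUMNS = ["t_s", "ax_ms2", "ay_ms2", "az_ms2"]
FORCE_COLUMNS = ["t_s", "force_N"]
VOLTAGE_COLUMNS = ["t_s", "v1", "v2", "v3", "v4"]
CALIBRATION_COLUMNS = ["weight_kg", "voltage_V"]


def _check_timestamps(t: np.ndarray) -> None:
    if t.size == 0:
        raise SeriesValidationError("series has no samples")
    d = np.diff(t)
    bad = np.nonzero(d <= 0)[0]
    if bad.size:
        raise SeriesValidationError(
            f"timestamps not strictly increasing: first offence at index {bad[0] + 1} "
            f"(t[{bad[0]}]={t[bad[0]]!r}, t[{bad[0] + 1}]={t[bad[0] + 1]!r})"
        )


@dataclass
class AccelSeries:
    """A timestamped triaxial acceleration recording from one device in one trial.

    Channels are in m/s^2; timestamps in seconds, strictly increasing.
    """

    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    device_id: str = "wearable"
    nominal_rate: float = 50.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = self.timestamps.size
        if not (self.ax.size == self.ay.size == self.az.size == n):
            raise SeriesValidationError("acceleration channels have unequal lengths")
        if self.nominal_rate <= 0:
            raise SeriesValidationError("nominal_rate must be > 0")
        _check_timestamps(self.timestamps)

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def duration(self) -> float:
        """Span covered by the samples, counting one sample period for the last one."""
        return float(self.timestamps[-1] - self.timestamps[0]) + 1.0 / self.nominal_rate


@dataclass
class ForceSeries:
    """A timestamped force-plate channel: calibrated newtons or raw summed volts."""

    timestamps: np.ndarray
    values: np.ndarray
    calibrated: bool = True
    nominal_rate: float = 128.0
    device_id: str = "forceplate"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.size != self.values.size:
            raise SeriesValidationError("timestamps and values have unequal lengths")
        if self.nominal_rate <= 0:
            raise SeriesValidationError("nominal_rate must be > 0")
        _check_timestamps(self.timestamps)

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0]) + 1.0 / self.nominal_rate


@dataclass(frozen=True)
class CalibrationModel:
    """Linear voltage-to-force map fitted to known weights placed on the plate."""

    slope: float  # N per V
    intercept: float  # N
    r2: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise SeriesValidationError(f"r2 out of [0, 1]: {self.r2}")


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    if len(df) == 0:
        raise FormatError(f"{path}: header only, no data rows")
    return df


def read_accel_csv(path, device_id: str = "wearable", nominal_rate: float = 50.0) -> AccelSeries:
    """Read a wearable CSV (``t_s,ax_ms2,ay_ms2,az_ms2``) into a validated series."""
    df = _read_csv(path, ACCEL_COLUMNS)
    return AccelSeries(
        timestamps=df["t_s"].to_numpy(),
        ax=df["ax_ms2"].to_numpy(),
        ay=df["ay_ms2"].to_numpy(),
        az=df["az_ms2"].to_numpy(),
        device_id=device_id,
        nominal_rate=nominal_rate,
    )


def write_accel_csv(series: AccelSeries, path) -> None:
    pd.DataFrame(
        {
            "t_s": series.timestamps,
            "ax_ms2": series.ax,
            "ay_ms2": series.ay,
            "az_ms2": series.az,
        }
    ).to_csv(path, index=False)


def read_force_csv(path, nominal_rate: float = 128.0) -> ForceSeries:
    """Read a force-plate CSV.

    ``t_s,force_N`` yields a calibrated series; ``t_s,v1,v2,v3,v4`` sums the
    four load-cell channels into one raw (uncalibrated) voltage signal.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if len(df) == 0:
        raise FormatError(f"{path}: header only, no data rows")
    if "force_N" in df.columns:
        if "t_s" not in df.columns:
            raise FormatError(f"{path}: missing column(s) ['t_s']")
        values = df["force_N"].to_numpy()
        calibrated = True
    else:
        missing = [c for c in VOLTAGE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(
                f"{path}: expected force_N or v1..v4 columns; missing {missing}"
            )
        values = df[["v1", "v2", "v3", "v4"]].to_numpy().sum(axis=1)
        calibrated = False
    return ForceSeries(
        timestamps=df["t_s"].to_numpy(),
        values=values,
        calibrated=calibrated,
        nominal_rate=nominal_rate,
    )


def write_force_csv(series: ForceSeries, path) -> None:
    if not series.calibrated:
        raise UsageError("write_force_csv writes calibrated series; use voltage writer")
    pd.DataFrame({"t_s": series.timestamps, "force_N": series.values}).to_csv(path, index=False)


def read_calibration_csv(path) -> pd.DataFrame:
    """Read a calibration table ``weight_kg,voltage_V``."""
    return _read_csv(path, CALIBRATION_COLUMNS)


def fit_calibration(weights_kg, voltages_V, g: float = STANDARD_GRAVITY) -> CalibrationModel:
    """Fit the ordinary-least-squares line mapping voltage (V) to force (N).

    Forces are the calibration weights times ``g``.  Requires at least two
    distinct voltage values.
    """
    w = np.asarray(weights_kg, dtype=float)
    v = np.asarray(voltages_V, dtype=float)
    if w.size != v.size:
        raise CalibrationError("weights and voltages have unequal lengths")
    if w.size < 2:
        raise CalibrationError("need at least 2 calibration points")
    if np.ptp(v) == 0.0:
        raise CalibrationError("degenerate fit: all calibration voltages identical")
    force = w * g
    res = _st.linregress(v, force)
    r2 = float(res.rvalue**2) if np.ptp(force) > 0 else 1.0
    return CalibrationModel(slope=float(res.slope), intercept=float(res.intercept), r2=min(r2, 1.0))


def apply_calibration(model: CalibrationModel, raw: ForceSeries) -> ForceSeries:
    """Map a raw voltage series to newtons; timestamps are unchanged."""
    if raw.calibrated:
        raise UsageError("series is already calibrated")
    return ForceSeries(
        timestamps=raw.timestamps.copy(),
        values=model.slope * raw.values + model.intercept,
        calibrated=True,
        nominal_rate=raw.nominal_rate,
        device_id=raw.device_id,
    )


def invert_calibration(model: CalibrationModel, calibrated: ForceSeries) -> ForceSeries:
    """Map a calibrated series back to raw volts (synthetic data generation)."""
    if not calibrated.calibrated:
        raise UsageError("series is already raw")
    if model.slope == 0:
        raise CalibrationError("cannot invert a zero-slope calibration")
    return ForceSeries(
        timestamps=calibrated.timestamps.copy(),
        values=(calibrated.values - model.intercept) / model.slope,
        calibrated=False,
        nominal_rate=calibrated.nominal_rate,
        device_id=calibrated.device_id,
    )


def extract_window(series, head_s: float = 20.0, keep_s: float = 60.0, tail_s: float = 10.0):
    """Extract the analysis window ``[head_s, head_s + keep_s)`` from a trial.

    Timestamps (relative to the first sample) are re-zeroed to the window
    start.  The tail is dropped implicitly.  Raises :class:`WindowError`
    when the trial is shorter than ``head_s + keep_s``.
    """
    t0 = series.timestamps[0]
    needed = head_s + keep_s
    if series.duration < needed - 1e-9:
        raise WindowError(
            f"trial too short for window: need {needed:g} s, have {series.duration:g} s"
        )
    rel = series.timestamps - t0
    mask = (rel >= head_s - 1e-12) & (rel < head_s + keep_s - 1e-12)
    new_t = rel[mask] - head_s
    if isinstance(series, AccelSeries):
        return AccelSeries(
            timestamps=new_t,
            ax=series.ax[mask],
            ay=series.ay[mask],
            az=series.az[mask],
            device_id=series.device_id,
            nominal_rate=series.nominal_rate,
        )
    return ForceSeries(
        timestamps=new_t,
        values=series.values[mask],
        calibrated=series.calibrated,
        nominal_rate=series.nominal_rate,
        device_id=series.device_id,
    )


def is_uniform(timestamps: np.ndarray, rel_tol: float = 1e-6) -> bool:
    """True when sample spacing is constant to within ``rel_tol`` of the median step."""
    d = np.diff(timestamps)
    if d.size == 0:
        return True
    med = np.median(d)
    return bool(np.all(np.abs(d - med) <= rel_tol * med))


def resample_uniform(series, rate: float | None = None):
    """Linearly interpolate a series onto a uniform grid at ``rate`` (default: nominal).

    Used for wearables whose loggers emit slightly irregular timestamps; the
    load-rate estimator requires a uniform grid.
    """
    rate = float(rate or series.nominal_rate)
    t = series.timestamps
    n = int(np.floor((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n) / rate
    if isinstance(series, AccelSeries):
        return AccelSeries(
            timestamps=grid,
            ax=np.interp(grid, t, series.ax),
            ay=np.interp(grid, t, series.ay),
            az=np.interp(grid, t, series.az),
            device_id=series.device_id,
            nominal_rate=rate,
        )
    return ForceSeries(
        timestamps=grid,
        values=np.interp(grid, t, series.values),
        calibrated=series.calibrated,
        nominal_rate=rate,
        device_id=series.device_id,
    )
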