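"""Shared domain types for the gait-analysis pipeline.

All quantities use a single internal unit convention: seconds, meters,
m/s^2, rad/s.  Time is measured from trial start (0-based) and all event
windows are half-open ``[start, end)``.  Left and right shank sensors are
always processed independently and never averaged.

World frame: x anterior-posterior (movement direction), y lateral,
z vertical (up).  Sensor frame (lateral shank mount): x along the shank
(proximal/up when standing), y anterior-posterior, z perpendicular to the
sagittal plane, so the sagittal-plane angular velocity lives on gyro z and
the anterior-posterior acceleration on acc y.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

Side = Literal["left", "right"]

#: Index of the anterior-posterior channel in the sensor accelerometer.
AP_AXIS = 1
#: Index of the sagittal-plane channel in the sensor gyroscope.
SAGITTAL_AXIS = 2

_UNIFORMITY_TOL = 1e-6  # s, allowed deviation from uniform sampling


def _check_uniform_time(t: np.ndarray, what: str) -> None:
    if t.ndim != 1 or t.size < 2:
        raise ValueError(f"{what}: need at least 2 time samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{what}: non-monotonic time")
    if np.ptp(dt) > _UNIFORMITY_TOL:
        raise ValueError(f"{what}: time not uniform within {_UNIFORMITY_TOL} s")


@dataclass
class ImuTrace:
    """Timestamped 3-axis specific force and angular velocity for one shank.

    Attributes
    ----------
    t : (n,) array, seconds, uniformly sampled, strictly increasing
    acc : (n, 3) array, specific force in m/s^2, sensor frame
    gyro : (n, 3) array, angular velocity in rad/s, sensor frame
    fs : sampling rate in Hz (nominal 200)
    side : "left" or "right"
    axis_map : maps semantic channel names to column indices; by default the
        anterior-posterior acceleration is acc[:, 1] and the sagittal-plane
        angular velocity is gyro[:, 2].
    """

    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    fs: float
    side: Side = "left"
    axis_map: dict = field(default_factory=lambda: {"ap": AP_AXIS, "sagittal": SAGITTAL_AXIS})

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        _check_uniform_time(self.t, "ImuTrace")
        n = self.t.size
        if self.acc.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("acc and gyro must be (n, 3) arrays matching t")

    @property
    def acc_ap(self) -> np.ndarray:
        """Anterior-posterior specific force channel, m/s^2."""
        return self.acc[:, self.axis_map["ap"]]

    @property
    def gyro_sagittal(self) -> np.ndarray:
        """Sagittal-plane angular velocity channel, rad/s (raw sign)."""
        return self.gyro[:, self.axis_map["sagittal"]]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return self.t.size


@dataclass
class GaitEvents:
    """Ordered gait-event times for one side.

    Within one complete cycle the order is
    ``MSW(k) < IC(k) < MST(k) < FC(k) < MSW(k+1)``.
    ``t_cycle`` is the trial-average gait-cycle duration derived from the
    dominant frequency of the sagittal shank angular velocity.
    """

    side: Side
    msw: np.ndarray
    ic: np.ndarray
    mst: np.ndarray
    fc: np.ndarray
    t_cycle: float
    ic_flagged: np.ndarray | None = None  # True where no interior ay maximum existed

    def __post_init__(self) -> None:
        for name in ("msw", "ic", "mst", "fc"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError(f"GaitEvents.{name} must be strictly increasing")


@dataclass
class StrideRecord:
    """One gait cycle (IC to next ipsilateral IC) with its parameters.

    Percentages are of the stride duration; ``swing_pct + stance_pct == 100``
    exactly.  Spatial fields are NaN until the trajectory stage fills them.
    """

    side: Side
    t_ic: float
    stride_duration: float
    step_duration: float = np.nan
    swing_pct: float = np.nan
    stance_pct: float = np.nan
    double_support_pct: float = np.nan
    stride_length: float = np.nan
    stride_width: float = np.nan
    stride_height: float = np.nan
    valid: bool = True

    FIELDS = (
        "side", "t_ic", "stride_duration", "step_duration", "swing_pct",
        "stance_pct", "double_support_pct", "stride_length", "stride_width",
        "stride_height", "valid",
    )


@dataclass
class ForcePlateTrace:
    """Vertical ground-reaction force of one treadmill belt."""

    t: np.ndarray
    vgrf: np.ndarray
    fs: float
    side: Side = "left"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.vgrf = np.asarray(self.vgrf, dtype=float)
        _check_uniform_time(self.t, "ForcePlateTrace")
        if self.vgrf.shape != self.t.shape:
            raise ValueError("vgrf must match t")
        if not np.all(np.isfinite(self.vgrf)):
            raise ValueError("vgrf must be finite")


@dataclass
class MarkerTrace:
    """3-D lab-frame trajectory of the reflective marker on one sensor.

    Lab frame: x anterior-posterior along the treadmill, y lateral,
    z vertical.  ``belt_speed`` is the treadmill belt speed in m/s.
    """

    t: np.ndarray
    pos: np.ndarray
    fs: float
    belt_speed: float = 0.0
    side: Side = "left"
    gap_flags: np.ndarray | None = None  # True where a gap was interpolated

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        _check_uniform_time(self.t, "MarkerTrace")
        if self.pos.shape != (self.t.size, 3):
            raise ValueError("pos must be (n, 3)")
        if self.belt_speed < 0:
            raise ValueError("belt_speed must be >= 0")


@dataclass
class TrialConfig:
    """Trial-level configuration and unit declarations for input files.

    ``sensor_to_ankle_distance`` is the lever arm between the sensor and the
    ankle joint used for the quasi-static boundary-velocity estimate
    (default 0.10 m).  ``long_stride_threshold`` is the stride duration
    above which the extra high-pass drift filter is applied (default 2.5 s).
    """

    subject_id: str = "anonymous"
    speed_condition: float | str = "preferred"
    sensor_to_ankle_distance: float = 0.10
    gravity: float = 9.81
    long_stride_threshold: float = 2.5
    gyro_units: Literal["rad/s", "deg/s"] = "rad/s"
    acc_units: Literal["m/s^2", "g"] = "m/s^2"
    orientation_gain: float = 0.01
    time_column: str = "t"
    acc_columns: tuple = ("ax", "ay", "az")
    gyro_columns: tuple = ("gx", "gy", "gz")

    def __post_init__(self) -> None:
        if self.sensor_to_ankle_distance <= 0:
            raise ValueError("sensor_to_ankle_distance must be > 0")
        if self.long_stride_threshold <= 0:
            raise ValueError("long_stride_threshold must be > 0")


__all__ = [
    "AP_AXIS",
    "SAGITTAL_AXIS",
    "ForcePlateTrace",
    "GaitEvents",
    "ImuTrace",
    "MarkerTrace",
    "Side",
    "StrideRecord",
    "TrialConfig",
    "replace",
]
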