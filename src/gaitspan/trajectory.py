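"""Per-stride sensor trajectories from strapdown integration.

The chain is: estimate the sensor orientation without a magnetometer
(complementary filter: gyroscope strapdown continuously corrected toward
the accelerometer-implied inclination), rotate the specific force into the
world frame and remove gravity, then integrate each mid-stance-to-mid-stance
segment twice with trapezoidal integration.  Integration drift is removed
with a linear velocity correction anchored on quasi-static boundary
velocities (|v| = |omega| * r with r the sensor-to-ankle lever arm, directed
along the shank's instantaneous forward tangent).  Abnormally long strides
(> 2.5 s) additionally get a first-order 0.0002 Hz high-pass on the segment
acceleration.  Yaw is unobservable without a magnetometer, so each stride is
finally rotated about the vertical axis so the mean horizontal swing-phase
velocity points along +x (heading alignment).

On a treadmill the boundary condition deliberately ignores the belt motion
(the stance foot moves with the belt, yet |v| = omega * r is its speed
relative to the belt), so the integrated trajectory lives in the belt frame
and the forward displacement directly measures the stride length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import cos, sin, sqrt

import numpy as np
from scipy import integrate as spi
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d
from scipy.spatial.transform import Rotation

from .types import ImuTrace

log = logging.getLogger(__name__)

_Z = np.array([0.0, 0.0, 1.0])


@dataclass
class OrientationSeries:
    """Unit quaternions (scalar-last, sensor -> world) per sample."""

    t: np.ndarray
    q: np.ndarray  # (n, 4), [x, y, z, w]
    filter_gain: float

    def rotations(self) -> Rotation:
        return Rotation.from_quat(self.q)


@dataclass
class StrideTrajectory:
    """Velocity and displacement of one MST-to-MST segment.

    ``v`` and ``p`` are in the heading-aligned world frame after
    :func:`heading_align` (x = movement direction, y lateral, z vertical);
    ``p[0] == 0`` exactly.
    """

    t: np.ndarray
    v: np.ndarray
    p: np.ndarray
    long_stride_filtered: bool = False
    heading_flagged: bool = False


def estimate_gyro_bias(imu: ImuTrace, *, window: float = 0.5,
                       still_threshold: float = 0.03,
                       max_rate: float = 0.1) -> np.ndarray:
    """Gyroscope bias from quasi-static spans (e.g. standing before the walk).

    A span counts as still when, over a sliding window, the per-axis
    standard deviation of the angular velocity stays below
    ``still_threshold`` rad/s on every axis *and* the mean rotation rate is
    below ``max_rate`` rad/s.  The rate criterion matters: the quiet
    mid-stance plateau of slow gait has low variance but a genuine 0.2-0.3
    rad/s rotation, and a typical MEMS bias is well under 0.1 rad/s.
    Returns zeros when no still span exists.
    """
    g = imu.gyro
    n = max(3, int(round(window * imu.fs)))
    if len(g) < n:
        return np.zeros(3)
    c1 = np.cumsum(np.vstack([np.zeros(3), g]), axis=0)
    c2 = np.cumsum(np.vstack([np.zeros(3), g ** 2]), axis=0)
    mean = (c1[n:] - c1[:-n]) / n
    var = np.maximum((c2[n:] - c2[:-n]) / n - mean ** 2, 0.0)
    still = (np.all(np.sqrt(var) < still_threshold, axis=1)
             & (np.linalg.norm(mean, axis=1) < max_rate))
    if not still.any():
        log.info("side %s: no still span found, gyro bias not removed", imu.side)
        return np.zeros(3)
    return mean[still].mean(axis=0)


def _tilt_from_accel(a: np.ndarray) -> np.ndarray:
    """Scalar-last quaternion of the minimal rotation taking ``a`` to +z."""
    a = a / np.linalg.norm(a)
    axis = np.cross(a, _Z)
    s = np.linalg.norm(axis)
    c = float(np.dot(a, _Z))
    if s < 1e-12:
        if c > 0:
            return np.array([0.0, 0.0, 0.0, 1.0])
        return np.array([1.0, 0.0, 0.0, 0.0])  # 180 deg about x
    angle = np.arctan2(s, c)
    axis = axis / s
    return np.concatenate([axis * np.sin(angle / 2), [np.cos(angle / 2)]])


def estimate_orientation(imu: ImuTrace, gain: float = 0.01, *,
                         gravity: float = 9.81, acc_tolerance: float = 0.2,
                         init_window: float = 0.5) -> OrientationSeries:
    """Magnetometer-free orientation from a complementary filter.

    The gyroscope is integrated sample by sample and the tilt is pulled
    toward the accelerometer-implied inclination by the per-sample fraction
    ``gain``, down-weighted linearly as the specific-force magnitude departs
    from gravity by up to ``acc_tolerance`` m/s^2 (movement acceleration
    makes the accelerometer a poor vertical reference).  The departure is
    taken as a running maximum over +/-50 ms: an instantaneous
    ``|a| == g`` crossing during swing has a badly wrong direction, so only
    sustained quasi-static spans (mid-stance) may correct the tilt.  Yaw is
    unobservable and left unconstrained; it is fixed later per stride by
    heading alignment.  The initial tilt comes from the mean accelerometer
    vector over the first ``init_window`` seconds, assuming a quasi-static
    start.
    """
    if not 0 <= gain <= 1:
        raise ValueError("gain must be in [0, 1]")
    acc, gyro = imu.acc, imu.gyro
    dt = 1.0 / imu.fs
    dev = np.abs(np.linalg.norm(acc, axis=1) - gravity)
    half = max(1, int(round(0.05 * imu.fs)))
    dev = maximum_filter1d(dev, size=2 * half + 1, mode="nearest")
    weights = np.clip(1.0 - dev / acc_tolerance, 0.0, 1.0)
    n_init = max(1, int(round(init_window * imu.fs)))
    a0 = acc[:n_init].mean(axis=0)
    if abs(np.linalg.norm(a0) - gravity) > 2.0:
        warnings.warn("accelerometer far from gravity during initialization; "
                      "falling back to identity initial tilt", stacklevel=2)
        qx = qy = qz = 0.0
        qw = 1.0
    else:
        qx, qy, qz, qw = _tilt_from_accel(a0)

    n = len(imu)
    out = np.empty((n, 4))
    half_dt = 0.5 * dt
    for i in range(n):
        gx, gy, gz = gyro[i]
        # body-frame gyro increment: q <- q * exp([gx,gy,gz]*dt/2);
        # sample 0 carries the initial orientation, no increment yet
        ang = sqrt(gx * gx + gy * gy + gz * gz) * half_dt if i else 0.0
        if ang > 1e-12:
            f = sin(ang) / ang * half_dt
            dw, dx, dy, dz = cos(ang), gx * f, gy * f, gz * f
            qw, qx, qy, qz = (qw * dw - qx * dx - qy * dy - qz * dz,
                              qw * dx + qx * dw + qy * dz - qz * dy,
                              qw * dy - qx * dz + qy * dw + qz * dx,
                              qw * dz + qx * dy - qy * dx + qz * dw)
        weight = weights[i]
        if weight > 0.0 and gain > 0.0:
            ax, ay, az = acc[i]
            # accelerometer direction in world frame
            wx = ax * (1 - 2 * (qy * qy + qz * qz)) + ay * 2 * (qx * qy - qw * qz) + az * 2 * (qx * qz + qw * qy)
            wy = ax * 2 * (qx * qy + qw * qz) + ay * (1 - 2 * (qx * qx + qz * qz)) + az * 2 * (qy * qz - qw * qx)
            wz = ax * 2 * (qx * qz - qw * qy) + ay * 2 * (qy * qz + qw * qx) + az * (1 - 2 * (qx * qx + qy * qy))
            # rotation from a_world toward +z: axis = a_world x z = (wy, -wx, 0)
            s = sqrt(wx * wx + wy * wy)
            if s > 1e-12:
                angle = np.arctan2(s, wz) * gain * weight * 0.5
                ca, sa = cos(angle), sin(angle) / s
                cx, cy = wy * sa, -wx * sa
                # world-frame correction: q <- dq * q
                qw, qx, qy, qz = (ca * qw - cx * qx - cy * qy,
                                  ca * qx + cx * qw + cy * qz,
                                  ca * qy - cx * qz + cy * qw,
                                  ca * qz + cx * qy - cy * qx)
        norm = sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
        qw, qx, qy, qz = qw / norm, qx / norm, qy / norm, qz / norm
        out[i] = (qx, qy, qz, qw)
    return OrientationSeries(t=imu.t, q=out, filter_gain=gain)


def world_acceleration(imu: ImuTrace, orientation: OrientationSeries,
                       gravity: float = 9.81) -> np.ndarray:
    """Movement acceleration in the world frame: ``R(q) a_sensor - g z``."""
    if len(orientation.t) != len(imu):
        raise ValueError("orientation must cover the IMU time span")
    a_world = orientation.rotations().apply(imu.acc)
    a_world[:, 2] -= gravity
    return a_world


def boundary_velocity(gyro_at_mst: float | np.ndarray, r: float) -> float:
    """Quasi-static speed at mid-stance: ``|v| = |omega| * r``.

    ``r`` is the sensor-to-ankle lever arm (about 0.10 m).  With the foot
    planted, the sensor pivots about the ankle, so its residual speed is the
    angular rate times the lever arm.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    return float(np.linalg.norm(np.atleast_1d(gyro_at_mst)) * r)


def boundary_velocity_vector(gyro_sensor: np.ndarray, q_xyzw: np.ndarray,
                             r: float) -> np.ndarray:
    """World-frame mid-stance velocity vector ``R (omega x r_lever)``.

    The lever arm runs from the ankle up to the sensor along the shank
    (the sensor x-axis, up or down depending on which way the sensor is
    worn; the upward sense is recovered from the orientation estimate), so
    the sensor velocity about the planted ankle is ``omega x lever``.  Its
    magnitude equals :func:`boundary_velocity` for a pure sagittal rotation
    and its direction is the shank's forward tangent; all signs come from
    the vector algebra, so mirrored left/right mounts need no special-casing.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    rot = Rotation.from_quat(q_xyzw)
    up_sensor = rot.inv().apply(_Z)  # world up expressed in the sensor frame
    lever = np.array([r if up_sensor[0] >= 0 else -r, 0.0, 0.0])
    v_sensor = np.cross(np.asarray(gyro_sensor, dtype=float), lever)
    return rot.apply(v_sensor)


def integrate_stride(a_world_seg: np.ndarray, v_start: np.ndarray,
                     v_end: np.ndarray, fs: float, *,
                     long_stride_threshold: float = 2.5,
                     hp_cutoff: float = 0.0002,
                     t_start: float = 0.0) -> StrideTrajectory:
    """Doubly integrate one MST-to-MST acceleration segment.

    Trapezoidal integration gives the raw velocity; a linearly interpolated
    correction is subtracted so the velocity equals ``v_start`` at the first
    sample and ``v_end`` at the last (first-order drift removal).  Segments
    longer than ``long_stride_threshold`` seconds are first high-pass
    filtered (first-order Butterworth, ``hp_cutoff`` Hz, zero-phase) to curb
    the larger drift of slow strides.  A second trapezoidal pass yields the
    displacement with ``p[0] = 0``.
    """
    a = np.asarray(a_world_seg, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    n, dims = a.shape
    if n < 3:
        raise ValueError("segment shorter than 3 samples")
    dur = (n - 1) / fs
    if dur <= 0.2:
        raise ValueError("segment duration must exceed 0.2 s")
    v_start = np.broadcast_to(np.atleast_1d(np.asarray(v_start, float)), (dims,))
    v_end = np.broadcast_to(np.atleast_1d(np.asarray(v_end, float)), (dims,))
    if not (np.all(np.isfinite(v_start)) and np.all(np.isfinite(v_end))):
        raise ValueError("boundary velocities must be finite")

    long_stride = dur > long_stride_threshold
    if long_stride:
        b, a_coef = sps.butter(1, hp_cutoff / (fs / 2), btype="highpass")
        # Gustafsson edges: the default reflect-padding of filtfilt would
        # act like per-segment mean removal for so low a cutoff
        a = sps.filtfilt(b, a_coef, a, axis=0, method="gust")

    t = t_start + np.arange(n) / fs
    v_raw = v_start + spi.cumulative_trapezoid(a, dx=1.0 / fs, axis=0, initial=0.0)
    ramp = ((t - t[0]) / (t[-1] - t[0]))[:, None]
    v = v_raw - ramp * (v_raw[-1] - v_end)
    p = spi.cumulative_trapezoid(v, dx=1.0 / fs, axis=0, initial=0.0)
    return StrideTrajectory(t=t, v=v, p=p, long_stride_filtered=bool(long_stride))


def heading_align(trajectory: StrideTrajectory,
                  swing_interval: tuple[float, float]) -> StrideTrajectory:
    """Rotate a stride about the vertical axis so the mean horizontal
    swing-phase velocity points along +x.

    Without a magnetometer the heading is arbitrary; the main movement
    direction is recovered from the horizontal velocity during swing.  If
    that mean velocity is below 1 mm/s the stride is flagged and left
    unrotated.
    """
    t = trajectory.t
    lo, hi = swing_interval
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError("swing interval outside stride span")
    mask = (t >= lo) & (t < hi)
    if not mask.any():
        mask = slice(None)
    vxy = trajectory.v[mask, :2].mean(axis=0)
    speed = np.linalg.norm(vxy)
    if speed < 1e-3:
        return StrideTrajectory(t=t, v=trajectory.v, p=trajectory.p,
                                long_stride_filtered=trajectory.long_stride_filtered,
                                heading_flagged=True)
    c, s = vxy / speed
    rot = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
    return StrideTrajectory(t=t, v=trajectory.v @ rot.T, p=trajectory.p @ rot.T,
                            long_stride_filtered=trajectory.long_stride_filtered)


def spatial_params(trajectory: StrideTrajectory) -> tuple[float, float, float]:
    """(stride_length, stride_width, stride_height) of an aligned stride.

    Length is the maximum forward displacement from the segment start;
    width and height are the lateral and vertical displacement ranges.
    """
    p = trajectory.p
    length = float(np.max(p[:, 0]) - p[0, 0])
    width = float(np.ptp(p[:, 1]))
    height = float(np.ptp(p[:, 2]))
    return length, width, height
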