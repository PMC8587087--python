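"""Synthetic treadmill-gait generator with exact ground truth.

The simulator emulates steady-state dual-belt treadmill walking with a
shank-mounted IMU above each ankle, an instrumented force plate under each
belt and a reflective marker on each sensor.  All streams derive from one
analytic kinematic model with closed-form first and second derivatives, so
the accelerometer, gyroscope, force and marker signals are mutually
consistent and every gait event and spatial parameter is known exactly.

Model per gait cycle (one side):

* The ankle is planted on the belt from initial contact (IC) until shortly
  before final contact (FC); in the lab frame it then drifts backward at
  belt speed.  From pre-swing through swing it advances by
  ``belt_speed x stride_duration`` (belt frame) along a minimum-jerk
  profile whose acceleration peaks exactly at FC (push-off), with a
  ``sin^3`` vertical arc of the stride height and lateral half-wave of the
  stride width.
* The shank sagittal angle follows smooth rotation-rate bumps: a landing
  bump centred on IC, two flanking stance bumps whose overlap puts the
  slowest rotation exactly at mid-stance (MST), a push-off bump centred on
  FC, and a large opposite swing bump centred on mid-swing (MSW).  With the
  swing-positive sign convention this reproduces the canonical shank
  angular-velocity profile: a dominant MSW peak, troughs at IC and FC, and
  a quiet mid-stance.
* A damped ~45 Hz oscillation in the ankle path, centred exactly on each
  IC (and a smaller one on each FC), produces the impact transient that
  detectors key on, while contributing only micrometres of displacement.
* The vertical GRF is a double-hump profile scaled to body weight with
  steep symmetric edges, non-zero exactly over each true stance.

Cycle-to-cycle variability is lognormal jitter on the stride duration;
both sides share one jittered cycle clock in anti-phase, so double-support
and step timings stay physiological.  Trials are deterministic given
``rng_seed``, using NumPy's default PCG64 generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.spatial.transform import Rotation

from .types import ForcePlateTrace, ImuTrace, MarkerTrace

_G = 9.81


# ---------------------------------------------------------------------------
# smooth analytic primitives (value, first and second derivative)

def _hann_add(t, c, w, amp, out, out_d=None, out_dd=None, out_int=None):
    """Add a Hann bump of amplitude ``amp`` and width ``w`` centred at ``c``
    (and its derivatives / running integral) to the output arrays."""
    lo, hi = np.searchsorted(t, [c - w / 2, c + w / 2])
    u = 2.0 * np.pi * (t[lo:hi] - c) / w
    out[lo:hi] += amp * 0.5 * (1.0 + np.cos(u))
    if out_d is not None:
        out_d[lo:hi] += -amp * np.pi / w * np.sin(u)
    if out_dd is not None:
        out_dd[lo:hi] += -amp * 2.0 * (np.pi / w) ** 2 * np.cos(u)
    if out_int is not None:
        out_int[lo:hi] += amp * w / (4.0 * np.pi) * (u + np.pi + np.sin(u))
        out_int[hi:] += amp * w / 2.0


def _minjerk(u):
    v = 10 * u ** 3 - 15 * u ** 4 + 6 * u ** 5
    d = 30 * u ** 2 - 60 * u ** 3 + 30 * u ** 4
    dd = 60 * u - 180 * u ** 2 + 120 * u ** 3
    return v, d, dd


def _sin3(u):
    s, c = np.sin(np.pi * u), np.cos(np.pi * u)
    v = s ** 3
    d = 3 * np.pi * s ** 2 * c
    dd = 3 * np.pi ** 2 * (2 * s * c ** 2 - s ** 3)
    return v, d, dd


def _wavelet_add(t, c, sigma, freq, acc_amp, direction, pos, vel, acc):
    """Add a Gaussian-windowed cosine displacement transient centred at
    ``c`` whose peak *acceleration* at the centre is ``acc_amp`` along
    ``direction``; updates position, velocity and acceleration arrays."""
    w = 2.0 * np.pi * freq
    scale = -acc_amp / (1.0 / sigma ** 2 + w ** 2)
    lo, hi = np.searchsorted(t, [c - 5 * sigma, c + 5 * sigma])
    u = t[lo:hi] - c
    g = np.exp(-u ** 2 / (2 * sigma ** 2))
    cwu, swu = np.cos(w * u), np.sin(w * u)
    d = scale * g * cwu
    d1 = scale * g * (-u / sigma ** 2 * cwu - w * swu)
    dd = scale * g * ((u ** 2 / sigma ** 4 - 1.0 / sigma ** 2 - w ** 2) * cwu
                      + 2.0 * u * w / sigma ** 2 * swu)
    pos[lo:hi] += np.outer(d, direction)
    vel[lo:hi] += np.outer(d1, direction)
    acc[lo:hi] += np.outer(dd, direction)


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return 3 * x ** 2 - 2 * x ** 3


# ---------------------------------------------------------------------------
# parameters

@dataclass
class GaitModelParams:
    """Stated world of one synthetic treadmill trial.

    Defaults correspond to the 0.5 m/s spinal-cord-injury walking regime
    (stride duration 1.69 s, swing 33%, stride height 10.1 cm, width
    2.1 cm); use :func:`preset` for the other speed conditions.  Noise
    defaults are typical consumer-MEMS magnitudes.
    """

    belt_speed: float = 0.5            # m/s
    stride_duration: float = 1.69      # s, mean cycle duration
    stance_fraction: float = 0.67      # 1 - swing fraction
    stride_height: float = 0.101       # m, vertical arc of the swing
    stride_width: float = 0.021        # m, lateral deviation range
    asym_duration: float = 1.0         # left-side stride-duration factor
    asym_length: float = 1.0           # left-side stride-length factor (treadmill: folded into duration)
    jitter_cv_duration: float = 0.047  # lognormal CV of cycle duration
    acc_noise_sd: float = 0.05         # m/s^2, white
    gyro_noise_sd: float = 0.005       # rad/s, white
    gyro_bias: float = 0.01            # rad/s, constant, random direction
    fp_noise_sd: float = 0.0           # N
    marker_noise_sd: float = 0.0       # m
    body_weight: float = 700.0         # N
    trial_duration: float = 180.0      # s, includes the standing lead-in
    lead_in: float = 2.0               # s of quasi-static standing
    fs_imu: float = 200.0
    fs_fp: float = 1000.0
    fs_marker: float = 100.0
    rng_seed: int = 0
    sensor_to_ankle: float = 0.10      # m, lever arm to the sensor
    impact_acc: float = 12.0           # m/s^2, landing transient peak
    pushoff_acc: float = 8.0           # m/s^2, lift-off transient peak
    roll_wobble: float = 0.03          # rad, frontal-plane lean amplitude
    yaw_wobble: float = 0.025          # rad, transverse wobble amplitude
    # shank rotation budget per cycle, rad (landing, 2x stance flank,
    # push-off); the opposing swing rotation balances them exactly
    rot_landing: float = 0.15
    rot_flank: float = 0.20
    rot_pushoff: float = 0.35

    def validate(self) -> None:
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must be in (0, 1)")
        if (1 - self.stance_fraction) * self.stride_duration <= 0:
            raise ValueError("infeasible parameters: swing time <= 0")
        for name in ("jitter_cv_duration", "acc_noise_sd", "gyro_noise_sd",
                     "gyro_bias", "fp_noise_sd", "marker_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.trial_duration < 30.0:
            raise ValueError("trial_duration must be >= 30 s (spectral stage)")

    @property
    def mean_stride_length(self) -> float:
        """Implied mean stride length on the treadmill, m."""
        return self.belt_speed * self.stride_duration


_PRESETS = {
    # condition: belt m/s, stride s, swing %, height m, width m, intra-subject SD of duration s
    "sci_0.3": (0.3, 2.14, 28.7, 0.090, 0.021, 0.12),
    "sci_0.5": (0.5, 1.69, 33.0, 0.101, 0.021, 0.08),
    "sci_preferred": (0.76, 1.38, 35.5, 0.111, 0.019, 0.04),
    "hc_0.5": (0.5, 1.60, 34.2, 0.100, 0.019, 0.05),
}


def preset(condition: str, **overrides) -> GaitModelParams:
    """Parameter set for one validated walking regime.

    ``sci_*`` are the spinal-cord-injury cohort conditions (0.3 m/s,
    0.5 m/s, preferred speed 0.76 m/s); ``hc_0.5`` the healthy controls at
    0.5 m/s.  Means and cycle-to-cycle variability follow the measured
    spatio-temporal profiles of those regimes.
    """
    if condition not in _PRESETS:
        raise KeyError(f"unknown condition {condition!r}; options: {sorted(_PRESETS)}")
    v, dur, swing_pct, height, width, dur_sd = _PRESETS[condition]
    p = GaitModelParams(belt_speed=v, stride_duration=dur,
                        stance_fraction=1.0 - swing_pct / 100.0,
                        stride_height=height, stride_width=width,
                        jitter_cv_duration=dur_sd / dur)
    return replace(p, **overrides) if overrides else p


def pathology_overlay(params: GaitModelParams,
                      kind: Literal["drop_foot", "asymmetry", "ataxia"],
                      severity: float = 1.0) -> GaitModelParams:
    """Qualitative gait-deficit overlays.

    ``drop_foot`` flattens the lift-off (weaker push-off transient and
    rotation, blurring FC); ``asymmetry`` lengthens left-side strides (on a
    fixed-speed treadmill a stride-length asymmetry is the same scaling);
    ``ataxia`` inflates the cycle-to-cycle variability.
    """
    if kind == "drop_foot":
        f = 1.0 - 0.7 * min(severity, 1.0)
        return replace(params, pushoff_acc=params.pushoff_acc * f,
                       rot_pushoff=params.rot_pushoff * (1.0 - 0.5 * min(severity, 1.0)))
    if kind == "asymmetry":
        return replace(params, asym_duration=1.0 + 0.2 * severity)
    if kind == "ataxia":
        return replace(params, jitter_cv_duration=params.jitter_cv_duration * (1.0 + 1.5 * severity))
    raise KeyError(f"unknown pathology overlay {kind!r}")


# ---------------------------------------------------------------------------
# trial containers

@dataclass
class SideTruth:
    """Exact per-side ground truth on the IMU time grid."""

    ic: np.ndarray          # contact instants, s
    fc: np.ndarray          # lift-off instants, s
    msw: np.ndarray         # peak swing angular velocity, s
    mst: np.ndarray         # quasi-static mid-stance, s
    seg_length: np.ndarray  # per MST->MST segment: max forward belt-frame displacement, m
    seg_width: np.ndarray   # per segment: lateral range, m
    seg_height: np.ndarray  # per segment: vertical range, m
    t: np.ndarray           # IMU-rate time grid
    p_lab: np.ndarray       # true sensor position, lab frame, m
    v_lab: np.ndarray       # true sensor velocity, lab frame, m/s
    a_lab: np.ndarray       # true sensor acceleration (kinematic), m/s^2
    q_xyzw: np.ndarray      # true sensor->world quaternions


@dataclass
class SyntheticTrial:
    params: GaitModelParams
    imu_left: ImuTrace
    imu_right: ImuTrace
    fp_left: ForcePlateTrace
    fp_right: ForcePlateTrace
    markers_left: MarkerTrace
    markers_right: MarkerTrace
    truth: dict = field(default_factory=dict)  # side -> SideTruth


# ---------------------------------------------------------------------------
# generation

_START_DELAY = 0.3  # s between end of lead-in and the first contact


def _cycle_schedule(p: GaitModelParams, rng) -> dict:
    """Draw the jittered cycle clock and both sides' contact times."""
    n = int(np.ceil((p.trial_duration + 3 * p.stride_duration) / p.stride_duration)) + 2
    cv = p.jitter_cv_duration
    if cv > 0:
        sigma = np.sqrt(np.log(1 + cv ** 2))
        base = p.stride_duration * np.exp(rng.normal(0.0, sigma, n) - sigma ** 2 / 2)
    else:
        base = np.full(n, p.stride_duration)
    t0 = p.lead_in + _START_DELAY
    left_d = base * p.asym_duration * p.asym_length
    ic_left = t0 + np.concatenate(([0.0], np.cumsum(left_d)))
    ic_right = t0 + 0.5 * base[0] + np.concatenate(([0.0], np.cumsum(base)))
    return {"left": ic_left, "right": ic_right}


def _side_kinematics(p: GaitModelParams, ic: np.ndarray, t: np.ndarray,
                     side: str, need_imu: bool):
    """Evaluate the analytic kinematics of one side on the grid ``t``.

    Returns position/velocity/acceleration (lab frame), Euler angles and
    rates, and the per-cycle event schedule.
    """
    n = t.size
    durations = np.diff(ic)
    n_cyc = durations.size
    st = p.stance_fraction * durations          # stance duration per cycle
    sw = durations - st                          # swing duration
    pre = 0.2113 / (1.0 - 0.2113) * sw           # pre-swing: min-jerk accel peak lands on FC
    wdur = sw + pre                              # ankle advance window
    fc = ic[:-1] + st
    msw = fc + 0.5 * sw

    v = p.belt_speed
    y0 = 0.10 if side == "left" else -0.10
    lat_sign = 1.0 if side == "left" else -1.0

    pos = np.zeros((n, 3))
    vel = np.zeros((n, 3))
    acc = np.zeros((n, 3))
    pos[:, 1] = y0

    # cycle index per sample; -1 = standing lead-in
    idx = np.searchsorted(ic, t, side="right") - 1
    idx = np.clip(idx, -1, n_cyc - 1)
    walking = idx >= 0
    k = np.clip(idx, 0, n_cyc - 1)
    tau = t - ic[k]

    # --- ankle anterior-posterior motion (belt frame advance, lab output)
    D_s, st_s, pre_s, w_s, sw_s = (a[k] for a in (durations, st, pre, wdur, sw))
    in_ramp = walking & (tau >= st_s - pre_s)
    u = np.zeros(n)
    u[in_ramp] = (tau[in_ramp] - (st_s - pre_s)[in_ramp]) / w_s[in_ramp]
    mj, mj_d, mj_dd = _minjerk(np.clip(u, 0.0, 1.0))
    adv = np.where(in_ramp, v * D_s * mj, 0.0)
    adv_d = np.where(in_ramp, v * D_s / w_s * mj_d, 0.0)
    adv_dd = np.where(in_ramp, v * D_s / w_s ** 2 * mj_dd, 0.0)
    pos[walking, 0] = -v * tau[walking] + adv[walking]
    vel[walking, 0] = -v + adv_d[walking]
    acc[walking, 0] = adv_dd[walking]

    # --- vertical arc and lateral half-wave during swing
    in_swing = walking & (tau >= st_s)
    us = np.zeros(n)
    us[in_swing] = (tau[in_swing] - st_s[in_swing]) / sw_s[in_swing]
    s3, s3_d, s3_dd = _sin3(np.clip(us, 0.0, 1.0))
    for axis, amp_arr in ((2, np.full(n_cyc, p.stride_height)),
                          (1, np.full(n_cyc, lat_sign * p.stride_width))):
        amp = amp_arr[k]
        pos[in_swing, axis] += (amp * s3)[in_swing]
        vel[in_swing, axis] += (amp * s3_d / sw_s)[in_swing]
        acc[in_swing, axis] += (amp * s3_dd / sw_s ** 2)[in_swing]

    # --- impact and push-off transients in the ankle path
    dir_land = np.array([0.8, 0.0, 0.6])
    dir_push = np.array([1.0, 0.0, 0.0])
    for tc in ic[1:n_cyc + 1]:
        _wavelet_add(t, tc, 0.008, 45.0, p.impact_acc, dir_land, pos, vel, acc)
    for tc in fc:
        _wavelet_add(t, tc, 0.008, 45.0, p.pushoff_acc, dir_push, pos, vel, acc)

    # --- shank pitch: rotation-rate bumps with closed-form integral
    theta_d = np.zeros(n)
    theta_dd = np.zeros(n)
    theta_int = np.zeros(n)
    for j in range(n_cyc):
        t_ic, t_fc, s_j, swj = ic[j], fc[j], st[j], sw[j]
        budget = p.rot_landing + 2 * p.rot_flank + p.rot_pushoff
        bumps = (
            (t_ic, 0.24 * s_j, p.rot_landing),
            (t_ic + 0.30 * s_j, 0.70 * s_j, p.rot_flank),
            (t_ic + 0.70 * s_j, 0.70 * s_j, p.rot_flank),
            (t_fc, 0.30 * s_j, p.rot_pushoff),
            (t_fc + 0.5 * swj, swj, -budget),
        )
        for c, w, area in bumps:
            _hann_add(t, c, w, 2.0 * area / w, theta_d, None if not need_imu else theta_dd,
                      None, theta_int)
    beta0 = -0.35
    beta = beta0 + theta_int
    beta_d = theta_d

    # true mid-stance: minimum foot (= sensor) speed while the ankle is
    # planted, i.e. the smallest |rotation rate| of the stance
    mst = ic[:n_cyc] + 0.5 * st
    for j in range(n_cyc):
        a, b = np.searchsorted(t, [ic[j], ic[j] + st[j] - pre[j]])
        if b - a > 2:
            mst[j] = t[a + int(np.argmin(np.abs(theta_d[a:b])))]

    # --- small frontal / transverse wobbles, extremum pinned on mid-stance
    alpha = np.zeros(n)
    alpha_d = np.zeros(n)
    gamma = np.zeros(n)
    gamma_d = np.zeros(n)
    ph = 2.0 * np.pi * (tau - 0.5 * st_s) / D_s
    a0 = p.roll_wobble * lat_sign
    g0 = p.yaw_wobble * lat_sign
    alpha[walking] = a0 * np.cos(ph[walking])
    alpha_d[walking] = (-a0 * 2.0 * np.pi / D_s * np.sin(ph))[walking]
    gamma[walking] = g0 * np.cos(ph[walking])
    gamma_d[walking] = (-g0 * 2.0 * np.pi / D_s * np.sin(ph))[walking]
    stand = ~walking
    if stand.any():  # freeze at the value taken at the first contact
        alpha[stand] = a0 * np.cos(-np.pi * p.stance_fraction)
        gamma[stand] = g0 * np.cos(-np.pi * p.stance_fraction)

    # --- sensor = ankle + lever arm along the (sagittal) shank direction
    r = p.sensor_to_ankle
    sb, cb = np.sin(beta), np.cos(beta)
    pos = pos + r * np.column_stack([sb, np.zeros(n), cb])
    vel = vel + r * np.column_stack([beta_d * cb, np.zeros(n), -beta_d * sb])
    acc = acc + r * np.column_stack([theta_dd * cb - beta_d ** 2 * sb,
                                     np.zeros(n),
                                     -theta_dd * sb - beta_d ** 2 * cb])

    events = {"ic": ic[1:n_cyc], "fc": fc, "msw": msw, "mst": mst,
              "ic_all": ic[:n_cyc + 1], "durations": durations}
    angles = {"alpha": alpha, "beta": beta, "gamma": gamma,
              "alpha_d": alpha_d, "beta_d": beta_d, "gamma_d": gamma_d}
    return pos, vel, acc, angles, events


_R_BS = {
    # sensor axes expressed in the body frame (x anterior, y left, z up);
    # columns are x_s, y_s, z_s.  Both sensors face outward on their lateral
    # mounts, so the right one is worn inverted: left has x up the shank and
    # z pointing left, right has x down the shank and z pointing right.
    "left": np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]]),
    "right": np.array([[0.0, 1.0, 0.0], [0.0, 0.0, -1.0], [-1.0, 0.0, 0.0]]),
}


def _body_rates(angles) -> np.ndarray:
    """Body-frame angular velocity from intrinsic z-y-x Euler angles."""
    a, b = angles["alpha"], angles["beta"]
    ad, bd, gd = angles["alpha_d"], angles["beta_d"], angles["gamma_d"]
    sa, ca, sb, cb = np.sin(a), np.cos(a), np.sin(b), np.cos(b)
    return np.column_stack([
        ad - gd * sb,
        bd * ca + gd * cb * sa,
        gd * cb * ca - bd * sa,
    ])


def _vgrf(p: GaitModelParams, events, t: np.ndarray, rng) -> np.ndarray:
    # double-hump loading over each true stance; a small pedestal under the
    # steep 8 ms edges makes the force cross typical event thresholds
    # (tens of N) within ~1-2 samples of the true contact and lift-off
    f = np.zeros(t.size)
    edge, pedestal = 0.008, 0.10
    ic_all = events["ic_all"]
    for j, t_fc in enumerate(events["fc"]):
        t_ic = ic_all[j]
        s_j = t_fc - t_ic
        lo, hi = np.searchsorted(t, [t_ic, t_fc])
        tau = t[lo:hi] - t_ic
        u = tau / s_j
        base = 1.05 * np.sin(np.pi * u) + 0.25 * np.sin(3 * np.pi * u)
        shape = pedestal + (1.0 - pedestal) * base
        f[lo:hi] = (p.body_weight * shape
                    * _smoothstep(tau / edge) * _smoothstep((s_j - tau) / edge))
    if p.fp_noise_sd > 0:
        f = np.maximum(f + rng.normal(0.0, p.fp_noise_sd, f.size), 0.0)
    return f


def _segment_spatial(t, p_lab, v_belt_x, mst):
    """True spatial parameters per MST->MST segment, belt frame."""
    x_belt = p_lab[:, 0] + v_belt_x * t
    lengths, widths, heights = [], [], []
    for a, b in zip(mst[:-1], mst[1:]):
        lo, hi = np.searchsorted(t, [a, b])
        seg = slice(lo, hi + 1)
        lengths.append(np.max(x_belt[seg]) - x_belt[lo])
        widths.append(np.ptp(p_lab[seg, 1]))
        heights.append(np.ptp(p_lab[seg, 2]))
    return np.asarray(lengths), np.asarray(widths), np.asarray(heights)


def simulate_trial(params: GaitModelParams) -> SyntheticTrial:
    """Generate one synthetic treadmill trial (deterministic per seed)."""
    p = params
    p.validate()
    rng = np.random.default_rng(p.rng_seed)
    schedule = _cycle_schedule(p, rng)
    bias_dir = rng.normal(size=3)
    bias = p.gyro_bias * bias_dir / np.linalg.norm(bias_dir)

    t_imu = np.arange(int(round(p.trial_duration * p.fs_imu))) / p.fs_imu
    t_fp = np.arange(int(round(p.trial_duration * p.fs_fp))) / p.fs_fp
    t_mk = np.arange(int(round(p.trial_duration * p.fs_marker))) / p.fs_marker

    imu, fp, mk, truth = {}, {}, {}, {}
    for side in ("left", "right"):
        ic = schedule[side]
        pos, vel, acc, angles, events = _side_kinematics(p, ic, t_imu, side, True)
        rot_wb = Rotation.from_euler(
            "ZYX", np.column_stack([angles["gamma"], angles["beta"], angles["alpha"]]))
        rot_ws = rot_wb * Rotation.from_matrix(_R_BS[side])
        omega_b = _body_rates(angles)
        gyro = omega_b @ _R_BS[side]  # R_bs^T applied row-wise
        spec_force = acc.copy()
        spec_force[:, 2] += _G
        acc_sensor = rot_ws.inv().apply(spec_force)
        gyro_noisy = gyro + bias + rng.normal(0.0, p.gyro_noise_sd, gyro.shape)
        acc_noisy = acc_sensor + rng.normal(0.0, p.acc_noise_sd, acc_sensor.shape)
        imu[side] = ImuTrace(t=t_imu, acc=acc_noisy, gyro=gyro_noisy,
                             fs=p.fs_imu, side=side)

        # restrict truth to events fully inside the sampled span
        margin = t_imu[-1]
        keep = events["mst"] <= margin
        mst = events["mst"][keep]
        seg_l, seg_w, seg_h = _segment_spatial(t_imu, pos, p.belt_speed, mst)
        truth[side] = SideTruth(
            ic=events["ic_all"][events["ic_all"] <= margin],
            fc=events["fc"][events["fc"] <= margin],
            msw=events["msw"][events["msw"] <= margin],
            mst=mst,
            seg_length=seg_l, seg_width=seg_w, seg_height=seg_h,
            t=t_imu, p_lab=pos, v_lab=vel, a_lab=acc,
            q_xyzw=rot_ws.as_quat())

        fp[side] = ForcePlateTrace(t=t_fp, vgrf=_vgrf(p, events, t_fp, rng),
                                   fs=p.fs_fp, side=side)
        mpos, _, _, _, _ = _side_kinematics(p, ic, t_mk, side, False)
        if p.marker_noise_sd > 0:
            mpos = mpos + rng.normal(0.0, p.marker_noise_sd, mpos.shape)
        mk[side] = MarkerTrace(t=t_mk, pos=mpos, fs=p.fs_marker,
                               belt_speed=p.belt_speed, side=side)

    return SyntheticTrial(params=p, imu_left=imu["left"], imu_right=imu["right"],
                          fp_left=fp["left"], fp_right=fp["right"],
                          markers_left=mk["left"], markers_right=mk["right"],
                          truth=truth)


def duration_for_strides(params: GaitModelParams, n_strides: int) -> float:
    """Trial duration that yields at least ``n_strides`` complete strides."""
    span = (n_strides + 2) * params.stride_duration * max(params.asym_duration, 1.0)
    return params.lead_in + _START_DELAY + span
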