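"""Orientation estimation, gravity removal, per-stride integration and
spatial parameters."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import gaitspan as gs
from gaitspan import trajectory as tj
from gaitspan.types import ImuTrace

FS = 200.0
G = 9.81


def _imu(acc, gyro, fs=FS, side="left"):
    n = len(acc)
    return ImuTrace(t=np.arange(n) / fs, acc=np.asarray(acc, float),
                    gyro=np.asarray(gyro, float), fs=fs, side=side)


class TestOrientation:
    def test_stationary_sensor_identity_tilt(self):
        n = int(4 * FS)
        imu = _imu(np.tile([0.0, 0.0, G], (n, 1)), np.zeros((n, 3)))
        o = tj.estimate_orientation(imu)
        z_world = Rotation.from_quat(o.q).apply([0, 0, 1.0])
        assert np.allclose(z_world, [0, 0, 1.0], atol=1e-9)

    def test_pure_gyro_strapdown_with_zero_gain(self):
        """1 rad/s about z for 2 s integrates to a 2.0 rad rotation."""
        n = int(2 * FS) + 1
        imu = _imu(np.tile([0.0, 0.0, G], (n, 1)),
                   np.tile([0.0, 0.0, 1.0], (n, 1)))
        o = tj.estimate_orientation(imu, gain=0.0)
        angle = Rotation.from_quat(o.q[-1]).magnitude()
        assert angle == pytest.approx(2.0, abs=1e-6)

    def test_quaternions_unit_norm_and_continuous(self, analysis_05, trial_05):
        o = tj.estimate_orientation(trial_05.imu_left)
        norms = np.linalg.norm(o.q, axis=1)
        assert np.max(np.abs(norms - 1.0)) < 1e-9
        dots = np.abs(np.sum(o.q[1:] * o.q[:-1], axis=1))
        assert dots.min() > 0.99  # no sign flips between samples

    def test_rocking_with_noise_tilt_rms_under_2deg(self, rng):
        """A sensor rocking +/-17 deg about a horizontal axis with MEMS-level
        noise; the simulated orientation is the oracle."""
        n = int(30 * FS)
        t = np.arange(n) / FS
        beta = 0.3 * np.sin(2 * np.pi * 0.8 * t)
        beta_d = 0.3 * 2 * np.pi * 0.8 * np.cos(2 * np.pi * 0.8 * t)
        rot = Rotation.from_euler("y", beta.reshape(-1, 1))
        acc = rot.inv().apply(np.tile([0.0, 0.0, G], (n, 1)))
        gyro = np.column_stack([np.zeros(n), beta_d, np.zeros(n)])
        imu = _imu(acc + rng.normal(0, 0.05, (n, 3)),
                   gyro + rng.normal(0, 0.005, (n, 3)))
        o = tj.estimate_orientation(imu)
        z_est = Rotation.from_quat(o.q).inv().apply([0, 0, 1.0])
        z_true = rot.inv().apply([0, 0, 1.0])
        ang = np.degrees(np.arccos(np.clip(np.sum(z_est * z_true, axis=1), -1, 1)))
        assert np.sqrt(np.mean(ang[int(FS):] ** 2)) < 2.0

    def test_non_gravity_init_warns_and_falls_back(self):
        n = int(2 * FS)
        imu = _imu(np.tile([0.0, 0.0, 30.0], (n, 1)), np.zeros((n, 3)))
        with pytest.warns(UserWarning, match="identity"):
            tj.estimate_orientation(imu)

    def test_gyro_bias_recovered_from_standing(self, trial_05):
        params = trial_05.params
        bias = tj.estimate_gyro_bias(trial_05.imu_right)
        assert np.linalg.norm(bias) == pytest.approx(params.gyro_bias, abs=2e-3)


class TestWorldAcceleration:
    def test_stationary_residual_small(self):
        n = int(3 * FS)
        imu = _imu(np.tile([0.0, 0.0, G], (n, 1)), np.zeros((n, 3)))
        o = tj.estimate_orientation(imu)
        a = tj.world_acceleration(imu, o)
        assert np.linalg.norm(a, axis=1).max() < 0.05

    def test_rotated_sensor_gravity_removed(self):
        """Sensor rotated 90 deg about x reads gravity on +y; the world
        acceleration is still ~zero."""
        n = int(3 * FS)
        imu = _imu(np.tile([0.0, G, 0.0], (n, 1)), np.zeros((n, 3)))
        o = tj.estimate_orientation(imu)
        a = tj.world_acceleration(imu, o)
        assert np.linalg.norm(a, axis=1).max() < 0.05

    def test_simulator_truth_orientation_gives_true_acceleration(self, trial_05_clean):
        tr = trial_05_clean.truth["right"]
        o = tj.OrientationSeries(t=trial_05_clean.imu_right.t, q=tr.q_xyzw,
                                 filter_gain=0.0)
        a = tj.world_acceleration(trial_05_clean.imu_right, o)
        rms = np.sqrt(np.mean((a - tr.a_lab) ** 2))
        assert rms < 0.01


class TestBoundaryVelocity:
    def test_magnitude_rule(self):
        assert tj.boundary_velocity(0.4, 0.10) == pytest.approx(0.04)
        assert tj.boundary_velocity(0.0, 0.10) == 0.0
        assert tj.boundary_velocity(1.0, 0.10) == pytest.approx(0.10)

    def test_invalid_lever(self):
        with pytest.raises(ValueError):
            tj.boundary_velocity(0.4, 0.0)

    def test_vector_form_matches_magnitude_for_sagittal_rotation(self):
        q = Rotation.identity().as_quat()
        v = tj.boundary_velocity_vector(np.array([0.0, 0.0, 0.4]), q, 0.10)
        assert np.linalg.norm(v) == pytest.approx(0.04)
        assert v[1] == pytest.approx(0.04)  # forward tangent: z cross x = y


class TestIntegrateStride:
    def test_zero_acceleration_zero_boundaries(self):
        n = int(1.0 * FS) + 1
        traj = tj.integrate_stride(np.zeros((n, 3)), np.zeros(3), np.zeros(3), FS)
        assert np.allclose(traj.p, 0.0)
        assert traj.p[0, 0] == 0.0

    def test_constant_acceleration_closed_form(self):
        """1 m/s^2 for 1 s with exact boundary velocities: x = 0.5 m."""
        n = int(1.0 * FS) + 1
        a = np.zeros((n, 3))
        a[:, 0] = 1.0
        traj = tj.integrate_stride(a, np.zeros(3), np.array([1.0, 0, 0]), FS)
        assert traj.p[-1, 0] == pytest.approx(0.5, abs=1e-3)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            tj.integrate_stride(np.zeros((2, 3)), np.zeros(3), np.zeros(3), FS)
        with pytest.raises(ValueError):
            tj.integrate_stride(np.zeros((10, 3)), np.zeros(3), np.zeros(3), FS)

    def test_nonfinite_boundaries_rejected(self):
        n = int(1.0 * FS) + 1
        with pytest.raises(ValueError):
            tj.integrate_stride(np.zeros((n, 3)), np.array([np.nan, 0, 0]),
                                np.zeros(3), FS)

    def test_simulator_stride_endpoint_under_1mm(self, trial_05_clean):
        """True acceleration + true boundary velocities reproduce the true
        trajectory endpoint within 1 mm (integrator validated before the
        boundary-velocity approximation enters)."""
        tr = trial_05_clean.truth["right"]
        for j in range(3, 23):
            i0 = int(round(tr.mst[j] * FS))
            i1 = int(round(tr.mst[j + 1] * FS))
            traj = tj.integrate_stride(tr.a_lab[i0:i1 + 1], tr.v_lab[i0],
                                       tr.v_lab[i1], FS)
            p_true = tr.p_lab[i0:i1 + 1] - tr.p_lab[i0]
            assert np.linalg.norm(traj.p[-1] - p_true[-1]) < 1e-3

    def test_trapezoidal_order_of_convergence(self):
        """Endpoint error shrinks as O(fs^-2): halving the step divides the
        error by ~4 (analytic sinusoidal acceleration as oracle)."""
        w = 2 * np.pi * 2.0
        errs = []
        for fs in (100.0, 200.0, 400.0):
            n = int(1.0 * fs) + 1
            t = np.arange(n) / fs
            a = np.column_stack([3.0 * np.sin(w * t), np.zeros(n), np.zeros(n)])
            v1 = np.array([3 * (1 - np.cos(w * 1.0)) / w, 0, 0])
            traj = tj.integrate_stride(a, np.zeros(3), v1, fs)
            p_true = 3 * (1.0 - np.sin(w * 1.0) / w) / w
            errs.append(abs(traj.p[-1, 0] - p_true))
        r1, r2 = errs[0] / errs[1], errs[1] / errs[2]
        assert 3.3 < r1 < 4.7 and 3.3 < r2 < 4.7

    def test_long_stride_highpass_near_identity(self):
        """The 0.0002 Hz first-order high-pass barely alters a 3 s segment
        (its time constant is ~800 s); the flag is set regardless."""
        n = int(3.0 * FS) + 1
        t = np.arange(n) / FS
        a = np.column_stack([1.0 + np.sin(2 * np.pi * t), np.zeros(n), np.zeros(n)])
        long = tj.integrate_stride(a, np.zeros(3), np.array([3.0, 0, 0]), FS)
        short = tj.integrate_stride(a, np.zeros(3), np.array([3.0, 0, 0]), FS,
                                    long_stride_threshold=10.0)
        assert long.long_stride_filtered and not short.long_stride_filtered
        assert np.max(np.abs(long.p - short.p)) < 1e-4


class TestHeadingAlignment:
    def _traj(self, v):
        n = len(v)
        t = np.arange(n) / FS
        from scipy.integrate import cumulative_trapezoid
        p = cumulative_trapezoid(v, dx=1 / FS, axis=0, initial=0.0)
        return tj.StrideTrajectory(t=t, v=np.asarray(v, float), p=p)

    def test_diagonal_velocity_rotated_to_x(self):
        n = int(1.0 * FS)
        v = np.tile([1.0, 1.0, 0.0], (n, 1))
        out = tj.heading_align(self._traj(v), (0.2, 0.6))
        assert np.allclose(out.v[:, 0], np.sqrt(2.0), atol=1e-9)
        assert np.allclose(out.v[:, 1], 0.0, atol=1e-9)

    def test_already_aligned_is_identity(self):
        n = int(1.0 * FS)
        v = np.tile([1.2, 0.0, 0.3], (n, 1))
        base = self._traj(v)
        out = tj.heading_align(base, (0.2, 0.6))
        assert np.allclose(out.v, base.v) and np.allclose(out.p, base.p)

    def test_near_zero_swing_velocity_flagged(self):
        n = int(1.0 * FS)
        out = tj.heading_align(self._traj(np.zeros((n, 3))), (0.2, 0.6))
        assert out.heading_flagged

    def test_interval_outside_span_rejected(self):
        n = int(1.0 * FS)
        with pytest.raises(ValueError):
            tj.heading_align(self._traj(np.ones((n, 3))), (0.2, 5.0))

    def test_vertical_rotation_invariance_of_spatial_params(self):
        """Pre-rotating a stride about the vertical axis changes nothing
        after heading re-alignment."""
        n = int(1.0 * FS)
        t = np.arange(n) / FS
        v = np.column_stack([1.0 + 0.2 * np.sin(6 * t), 0.1 * np.cos(9 * t),
                             0.3 * np.sin(3 * t)])
        base = tj.heading_align(self._traj(v), (0.2, 0.8))
        ref = tj.spatial_params(base)
        for ang in (0.4, 1.7, 3.0):
            c, s = np.cos(ang), np.sin(ang)
            rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
            turned = self._traj(v @ rot.T)
            out = tj.heading_align(turned, (0.2, 0.8))
            assert np.allclose(tj.spatial_params(out), ref, atol=1e-9)


class TestSpatialParams:
    def _traj_from_p(self, p):
        n = len(p)
        return tj.StrideTrajectory(t=np.arange(n) / FS, v=np.zeros_like(p),
                                   p=np.asarray(p, float))

    def test_straight_line(self):
        t = np.linspace(0, 1, 201)
        p = np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])
        assert tj.spatial_params(self._traj_from_p(p)) == pytest.approx((1.0, 0.0, 0.0))

    def test_vertical_arc_height(self):
        t = np.linspace(0, 1, 201)
        p = np.column_stack([t, np.zeros_like(t), 0.05 * np.sin(np.pi * t)])
        L, W, H = tj.spatial_params(self._traj_from_p(p))
        assert H == pytest.approx(0.05, abs=1e-6)

    def test_time_reversal_preserves_width_and_height(self):
        t = np.linspace(0, 1, 201)
        p = np.column_stack([t - 0.3 * np.sin(2 * t), 0.02 * np.sin(np.pi * t),
                             0.05 * np.sin(np.pi * t)])
        fwd = tj.spatial_params(self._traj_from_p(p))
        rev = tj.spatial_params(self._traj_from_p(p[::-1] - p[-1]))
        assert rev[1] == pytest.approx(fwd[1]) and rev[2] == pytest.approx(fwd[2])
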