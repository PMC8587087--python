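"""Adaptive gait-event detection: closed-form cases, generator-oracle cases,
invariances, and an exhaustive-scan oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitspan as gs
from _oracles import naive_detector
from gaitspan.events import (NoGaitError, PeakParams, _window_slice,
                             detect_final_contact, detect_initial_contact,
                             detect_midstance, detect_midswing,
                             dominant_cycle_duration, normalize_sign)
from gaitspan.types import GaitEvents
from gaitspan.validation import match_event_times

FS = 200.0


class TestCycleDuration:
    def test_pure_tone(self):
        """A 0.5 Hz sinusoid has a 2.00 s cycle."""
        t = np.arange(int(60 * FS)) / FS
        assert dominant_cycle_duration(np.sin(2 * np.pi * 0.5 * t), FS) == pytest.approx(2.0, abs=0.02)

    def test_zero_signal_raises(self):
        with pytest.raises(NoGaitError):
            dominant_cycle_duration(np.zeros(int(12 * FS)), FS)

    def test_synthetic_gait_preferred_speed(self):
        """Generator cycle period recovered within 0.05 s at 1.38 s strides."""
        trial = gs.simulate_trial(gs.preset("sci_preferred", rng_seed=11,
                                            trial_duration=180.0))
        wz, _ = normalize_sign(trial.imu_right.gyro_sagittal)
        t_cycle = dominant_cycle_duration(wz, FS)
        assert t_cycle == pytest.approx(1.38, abs=0.05)


class TestMidswing:
    def test_sinusoid_peaks_closed_form(self):
        """3 sin(2 pi 0.5 t) over 30 s: 15 peaks at 0.5, 2.5, ..., 28.5 s."""
        t = np.arange(int(30 * FS)) / FS
        x = 3.0 * np.sin(2 * np.pi * 0.5 * t)
        msw = detect_midswing(x, FS, 2.0)
        assert len(msw) == 15
        assert np.allclose(msw, np.arange(15) * 2.0 + 0.5, atol=1.0 / FS)

    def test_low_peaks_rejected_by_adaptive_threshold(self):
        """Peaks below 20% of the 99th percentile are not gait cycles;
        expectation recomputed by brute force."""
        t = np.arange(int(30 * FS)) / FS
        x = 3.0 * np.sin(2 * np.pi * 0.5 * t)
        for k in range(15):  # scale every 3rd cycle down to 0.1 rad/s
            if k % 3 == 2:
                sl = slice(int(k * 2.0 * FS), int((k + 1) * 2.0 * FS))
                x[sl] *= 0.1 / 3.0
        threshold = 0.2 * np.percentile(x, 99)
        expected = [k * 2.0 + 0.5 for k in range(15)
                    if (3.0 if k % 3 != 2 else 0.1) >= threshold]
        msw = detect_midswing(x, FS, 2.0)
        assert np.allclose(msw, expected, atol=1.0 / FS)

    def test_no_peaks_raises(self):
        with pytest.raises(NoGaitError):
            detect_midswing(np.full(4000, 0.0), FS, 1.5)

    def test_synthetic_cycle_count_exact(self, trial_05):
        """Every generator cycle detected, none invented (0.5 m/s, noisy)."""
        for imu, side in ((trial_05.imu_left, "left"), (trial_05.imu_right, "right")):
            wz, _ = normalize_sign(imu.gyro_sagittal)
            msw = detect_midswing(wz, FS, dominant_cycle_duration(wz, FS))
            truth = trial_05.truth[side].msw
            assert len(msw) == len(truth)
            assert match_event_times(msw, truth, 0.5).size == len(truth)


class TestInitialContact:
    def test_window_arithmetic(self):
        """MSW at 10 s with Tcycle 1.5 s searches [10.075, 10.675)."""
        i0, i1, ok = _window_slice(0.0, FS, 100000, 10.0 + 0.05 * 1.5, 10.0 + 0.45 * 1.5)
        assert ok
        assert i0 / FS == pytest.approx(10.075, abs=1 / FS)
        assert i1 / FS == pytest.approx(10.675, abs=1 / FS)

    def test_single_impact_peak_hit_exactly(self):
        """An impact 20% of the cycle after MSW is returned as the IC."""
        t = np.arange(int(20 * FS)) / FS
        t_cycle, msw = 1.5, 10.0
        impact = msw + 0.2 * t_cycle
        ay = np.exp(-((t - impact) ** 2) / (2 * 0.01 ** 2))
        ic, kept, flags = detect_initial_contact(ay, np.array([msw]), t_cycle, FS)
        assert kept.all() and not flags[0]
        assert ic[0] == pytest.approx(impact, abs=1.0 / FS)

    def test_no_interior_maximum_flags_window_max(self):
        t = np.arange(int(20 * FS)) / FS
        ay = t.copy()  # monotone: no interior local max anywhere
        ic, kept, flags = detect_initial_contact(ay, np.array([10.0]), 1.5, FS)
        assert kept.all() and flags[0]
        assert ic[0] == pytest.approx(10.675 - 1 / FS, abs=1.1 / FS)

    def test_incomplete_cycle_dropped(self):
        ay = np.zeros(int(10 * FS))
        ic, kept, _ = detect_initial_contact(ay, np.array([9.9]), 1.5, FS)
        assert ic.size == 0 and not kept[0]

    def test_noiseless_gait_mean_error_under_15ms(self, trial_05_clean):
        """Against the generator's exact contact instants."""
        for imu, side in ((trial_05_clean.imu_left, "left"),
                          (trial_05_clean.imu_right, "right")):
            ev = gs.detect_events(imu)
            err = match_event_times(ev.ic, trial_05_clean.truth[side].ic, 0.4)
            assert err.size > 25
            assert np.abs(err).mean() < 0.015


class TestFinalContact:
    def test_midpoint_rule(self):
        """omega-z minimum at 9.40 s and ay maximum at 9.50 s give FC = 9.45 s."""
        t = np.arange(int(12 * FS)) / FS
        wz = -np.exp(-((t - 9.40) ** 2) / (2 * 0.02 ** 2))
        ay = np.exp(-((t - 9.50) ** 2) / (2 * 0.02 ** 2))
        fc, kept = detect_final_contact(wz, ay, np.array([10.0]), 2.0, FS)
        assert kept.all()
        assert fc[0] == pytest.approx(9.45, abs=1.0 / FS)

    def test_window_arithmetic(self):
        """MSW at 10 s with Tcycle 2 s searches [9.30, 9.90)."""
        i0, i1, ok = _window_slice(0.0, FS, 100000, 10.0 - 0.35 * 2.0, 10.0 - 0.05 * 2.0)
        assert ok and i0 / FS == pytest.approx(9.30) and i1 / FS == pytest.approx(9.90)

    def test_window_before_signal_dropped(self):
        fc, kept = detect_final_contact(np.zeros(1000), np.zeros(1000),
                                        np.array([0.2]), 2.0, FS)
        assert fc.size == 0 and not kept[0]

    def test_noiseless_gait_mean_error_under_40ms(self, trial_05_clean):
        """Against the generator's exact lift-off instants."""
        for imu, side in ((trial_05_clean.imu_left, "left"),
                          (trial_05_clean.imu_right, "right")):
            ev = gs.detect_events(imu)
            err = match_event_times(ev.fc, trial_05_clean.truth[side].fc, 0.4)
            assert err.size > 25
            assert np.abs(err).mean() < 0.040


class TestMidstance:
    def test_parabola_vertex(self):
        t = np.arange(int(4 * FS)) / FS
        wz = -((t - 1.5) ** 2)
        mst = detect_midstance(wz, np.array([1.0]), np.array([2.0]), FS)
        assert mst[0] == pytest.approx(1.5, abs=1.0 / FS)

    def test_monotone_signal_puts_mst_on_last_stance_sample(self):
        t = np.arange(int(4 * FS)) / FS
        mst = detect_midstance(t, np.array([1.0]), np.array([2.0]), FS)
        assert mst[0] == pytest.approx(2.0 - 1.0 / FS, abs=0.6 / FS)

    def test_unmatched_ic_dropped(self):
        mst = detect_midstance(np.zeros(1000), np.array([1.0]), np.array([0.5]), FS)
        assert mst.size == 0

    def test_event_ordering_on_synthetic_gait(self, analysis_05):
        """MSW < IC < MST < FC < next MSW for every complete cycle."""
        for side in (analysis_05.left, analysis_05.right):
            ev = side.events
            for k, t_ic in enumerate(ev.ic):
                msw_before = ev.msw[ev.msw < t_ic]
                assert msw_before.size
                nxt = ev.msw[ev.msw > t_ic]
                mst = ev.mst[(ev.mst > t_ic)]
                fc = ev.fc[(ev.fc > t_ic)]
                if not (nxt.size and mst.size and fc.size):
                    continue
                assert t_ic < mst[0] < fc[0] < nxt[0]


class TestTemporalParams:
    def _events(self, side, ic, fc):
        return GaitEvents(side=side, msw=np.array([]), ic=np.asarray(ic, float),
                          mst=np.array([]), fc=np.asarray(fc, float), t_cycle=1.6)

    def test_worked_example(self):
        """Stride 1.6 s, swing 31.25%, step 0.8 s, double support 18.75%."""
        left = self._events("left", [0.0, 1.6], [1.1])
        right = self._events("right", [0.8], [0.3])
        recs = [r for r in gs.compute_temporal_params(left, right) if r.side == "left"]
        assert len(recs) == 1
        r = recs[0]
        assert r.stride_duration == pytest.approx(1.6)
        assert r.swing_pct == pytest.approx(31.25)
        assert r.stance_pct == pytest.approx(68.75)
        assert r.step_duration == pytest.approx(0.8)
        assert r.double_support_pct == pytest.approx(18.75)

    def test_symmetric_gait_steps_sum_to_stride(self):
        left = self._events("left", [0.0, 1.6, 3.2], [1.1, 2.7])
        right = self._events("right", [0.8, 2.4], [0.3, 1.9])
        recs = gs.compute_temporal_params(left, right)
        l0 = [r for r in recs if r.side == "left"][0]
        r0 = [r for r in recs if r.side == "right"][0]
        assert l0.step_duration + r0.step_duration == pytest.approx(l0.stride_duration)

    def test_swing_plus_stance_exactly_100(self, analysis_05):
        for r in analysis_05.strides:
            if np.isfinite(r.swing_pct):
                assert r.swing_pct + r.stance_pct == pytest.approx(100.0, abs=1e-9)

    def test_fewer_than_two_ics_yields_no_strides(self):
        left = self._events("left", [0.0], [])
        right = self._events("right", [0.8], [0.3])
        assert gs.compute_temporal_params(left, right) == []

    def test_mean_stride_duration_at_05(self, trial_05):
        """Cohort-mean stride duration within 10 ms of the generator's 1.69 s."""
        ev = gs.detect_events(trial_05.imu_right)
        assert np.diff(ev.ic).mean() == pytest.approx(1.69, abs=0.010)


class TestInvariances:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(min_value=0.05, max_value=50.0))
    def test_positive_scaling_leaves_events_unchanged(self, scale):
        """Thresholds are percentile-relative, so amplitude calibration
        cannot move any event."""
        trial = _SCALE_TRIAL["trial"]
        imu = trial.imu_right
        base = _SCALE_TRIAL["events"]
        scaled = gs.ImuTrace(t=imu.t, acc=imu.acc * scale, gyro=imu.gyro * scale,
                             fs=imu.fs, side=imu.side)
        ev = gs.detect_events(scaled)
        for name in ("msw", "ic", "mst", "fc"):
            assert np.array_equal(getattr(ev, name), getattr(base, name))

    def test_time_shift_shifts_events_exactly(self):
        trial = _SCALE_TRIAL["trial"]
        imu = trial.imu_right
        shift = 7.25
        shifted = gs.ImuTrace(t=imu.t + shift, acc=imu.acc, gyro=imu.gyro,
                              fs=imu.fs, side=imu.side)
        base, ev = _SCALE_TRIAL["events"], gs.detect_events(shifted)
        for name in ("msw", "ic", "mst", "fc"):
            assert np.allclose(getattr(ev, name), getattr(base, name) + shift,
                               atol=1e-9)



class TestExhaustiveOracle:
    def test_detector_matches_naive_scan(self):
        """On a short trace, an exhaustive per-sample scan must reproduce the
        vectorized detector's events exactly."""
        trial = gs.simulate_trial(gs.preset("sci_0.5", rng_seed=9,
                                            trial_duration=40.0))
        full = trial.imu_right
        n = int(29.0 * full.fs)  # analyze a sub-30 s trace
        imu = gs.ImuTrace(t=full.t[:n], acc=full.acc[:n], gyro=full.gyro[:n],
                          fs=full.fs, side=full.side)
        params = PeakParams()
        wz, _ = normalize_sign(imu.gyro_sagittal)
        ay = imu.acc_ap
        n_msw, n_ic, n_fc, n_mst = naive_detector(wz, ay, imu.fs, params)
        ev = gs.detect_events(imu, params)
        assert np.allclose(ev.msw, n_msw, atol=1e-12)
        assert np.allclose(ev.ic, n_ic, atol=1e-12)
        assert np.allclose(ev.fc, n_fc, atol=1e-12)
        assert np.allclose(ev.mst, n_mst, atol=1e-12)


_SCALE_TRIAL = {}


def setup_module(module):
    trial = gs.simulate_trial(gs.preset("sci_0.5", rng_seed=17, trial_duration=40.0))
    _SCALE_TRIAL["trial"] = trial
    _SCALE_TRIAL["events"] = gs.detect_events(trial.imu_right)
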