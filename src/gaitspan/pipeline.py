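"""End-to-end drivers: sensors -> events -> trajectories -> stride table.

``analyze_trial`` runs the full sensor chain for both shanks and returns
stride records with temporal and spatial parameters.  ``truth_records``
builds the equivalent records from a synthetic trial's exact ground truth
so the two can be compared cycle by cycle with the validation module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import events as ev
from . import trajectory as tj
from .synthetic import SyntheticTrial
from .types import GaitEvents, ImuTrace, StrideRecord, TrialConfig

log = logging.getLogger(__name__)


def assign_segments_to_strides(mst: np.ndarray, ic: np.ndarray) -> dict[int, int]:
    """Map MST->MST segment index to the stride whose IC lies inside it.

    Segment ``j`` spans ``[MST(j), MST(j+1))``; the stride starting at the
    IC inside that span receives the segment's spatial parameters.
    """
    out: dict[int, int] = {}
    for j in range(len(mst) - 1):
        hits = np.flatnonzero((ic >= mst[j]) & (ic < mst[j + 1]))
        if hits.size:
            out[j] = int(hits[-1])
    return out


@dataclass
class SideAnalysis:
    events: GaitEvents
    trajectories: list = field(default_factory=list)  # (segment index, StrideTrajectory)
    spatial: dict = field(default_factory=dict)       # stride index -> (L, W, H)


def _analyze_side(imu: ImuTrace, config: TrialConfig,
                  params: ev.PeakParams | None = None) -> SideAnalysis:
    gait = ev.detect_events(imu, params)
    bias = tj.estimate_gyro_bias(imu)
    imu_c = ImuTrace(t=imu.t, acc=imu.acc, gyro=imu.gyro - bias, fs=imu.fs,
                     side=imu.side, axis_map=imu.axis_map)
    orient = tj.estimate_orientation(imu_c, gain=config.orientation_gain,
                                     gravity=config.gravity)
    a_world = tj.world_acceleration(imu_c, orient, gravity=config.gravity)

    r = config.sensor_to_ankle_distance
    mst, ic, fc = gait.mst, gait.ic, gait.fc
    fs, t0 = imu.fs, float(imu.t[0])
    analysis = SideAnalysis(events=gait)
    seg_map = assign_segments_to_strides(mst, ic)
    for j in range(len(mst) - 1):
        i0 = int(round((mst[j] - t0) * fs))
        i1 = int(round((mst[j + 1] - t0) * fs))
        if i1 - i0 < 3 or (i1 - i0) / fs <= 0.2:
            continue
        v0 = tj.boundary_velocity_vector(imu_c.gyro[i0], orient.q[i0], r)
        v1 = tj.boundary_velocity_vector(imu_c.gyro[i1], orient.q[i1], r)
        traj = tj.integrate_stride(
            a_world[i0:i1 + 1], v0, v1, fs,
            long_stride_threshold=config.long_stride_threshold,
            t_start=mst[j])
        swing_fc = fc[(fc >= mst[j]) & (fc < mst[j + 1])]
        swing_ic = ic[(ic > mst[j]) & (ic <= mst[j + 1])]
        if swing_fc.size and swing_ic.size and swing_ic[-1] > swing_fc[-1]:
            swing = (float(swing_fc[-1]), float(swing_ic[-1]))
        else:
            swing = (float(traj.t[0]), float(traj.t[-1]))
        traj = tj.heading_align(traj, swing)
        analysis.trajectories.append((j, traj))
        if j in seg_map:
            analysis.spatial[seg_map[j]] = tj.spatial_params(traj)
    return analysis


def _attach_spatial(records: list[StrideRecord], spatial: dict[str, dict]) -> None:
    counters = {"left": 0, "right": 0}
    for rec in records:
        i = counters[rec.side]
        if i in spatial[rec.side]:
            rec.stride_length, rec.stride_width, rec.stride_height = spatial[rec.side][i]
        counters[rec.side] += 1


@dataclass
class TrialAnalysis:
    left: SideAnalysis
    right: SideAnalysis
    strides: list[StrideRecord]


def analyze_trial(imu_left: ImuTrace, imu_right: ImuTrace,
                  config: TrialConfig | None = None,
                  peak_params: ev.PeakParams | None = None) -> TrialAnalysis:
    """Full sensor-only gait analysis of one trial (both sides)."""
    config = config or TrialConfig()
    left = _analyze_side(imu_left, config, peak_params)
    right = _analyze_side(imu_right, config, peak_params)
    records = ev.compute_temporal_params(left.events, right.events)
    _attach_spatial(records, {"left": left.spatial, "right": right.spatial})
    log.info("analyzed trial: %d strides (%d left, %d right)", len(records),
             sum(r.side == "left" for r in records),
             sum(r.side == "right" for r in records))
    return TrialAnalysis(left=left, right=right, strides=records)


def truth_records(trial: SyntheticTrial) -> list[StrideRecord]:
    """Exact stride records from a synthetic trial's ground truth,
    built with the same definitions as the sensor pipeline."""
    gt_events = {}
    for side, truth in trial.truth.items():
        gt_events[side] = GaitEvents(side=side, msw=truth.msw, ic=truth.ic,
                                     mst=truth.mst, fc=truth.fc,
                                     t_cycle=trial.params.stride_duration)
    records = ev.compute_temporal_params(gt_events["left"], gt_events["right"])
    spatial = {}
    for side, truth in trial.truth.items():
        seg_map = assign_segments_to_strides(truth.mst, truth.ic)
        spatial[side] = {stride: (truth.seg_length[seg], truth.seg_width[seg],
                                  truth.seg_height[seg])
                         for seg, stride in seg_map.items()}
    _attach_spatial(records, spatial)
    return records
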