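"""Gold-standard gait parameters from force plates and motion capture.

Events come from the vertical ground-reaction force of the instrumented
dual-belt treadmill: the force is low-pass FIR filtered (30 Hz, zero-phase
so the thresholds act on undelayed force), gated at 30 N, and de-glitched
with a 0.2 s duration gate applied both to short loaded runs (spurious
contacts) and short unloaded runs (spurious unloading).  Every remaining
loaded run is a stance phase whose first and last samples are the IC and
FC.  Spatial parameters come from the marker on the sensor plus the belt
motion.  Strides whose expected swing shows no unloaded span on the
stride's own plate (the walker stepped across the belt gap) are excluded,
and a trial with fewer than ten valid strides in total is excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .events import compute_temporal_params
from .types import ForcePlateTrace, GaitEvents, MarkerTrace, StrideRecord

log = logging.getLogger(__name__)

MIN_VALID_STRIDES = 10


def _lowpass_fir(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """Zero-phase FIR low-pass with >= 60 dB stopband attenuation."""
    width = min(0.8 * cutoff, 0.5 * (fs / 2 - cutoff)) / (fs / 2)
    numtaps, beta = sps.kaiserord(60.0, width)
    numtaps |= 1  # odd length, symmetric
    taps = sps.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs)
    return sps.filtfilt(taps, [1.0], x, padlen=min(3 * numtaps, x.size - 1))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    padded = np.concatenate(([False], mask, [False])).view(np.int8)
    edges = np.flatnonzero(np.diff(padded))
    return list(zip(edges[::2], edges[1::2]))


def gate_vgrf(fp: ForcePlateTrace, *, lp_cutoff: float = 30.0,
              force_threshold: float = 30.0, min_duration: float = 0.2) -> np.ndarray:
    """Filtered and gated vGRF: loaded where walking weight is truly on the
    plate, exactly zero elsewhere."""
    f = _lowpass_fir(fp.vgrf, fp.fs, lp_cutoff)
    f = np.where(f >= force_threshold, f, 0.0)
    n_min = int(round(min_duration * fp.fs))
    loaded = f > 0
    n_spur = n_gap = 0
    for a, b in _runs(loaded):  # spurious short contacts
        if b - a < n_min:
            f[a:b] = 0.0
            n_spur += 1
    loaded = f > 0
    for a, b in _runs(~loaded):  # spurious short unloading inside stance
        if b - a < n_min and a > 0 and b < f.size:
            f[a:b] = 0.5 * (f[a - 1] + f[b])
            n_gap += 1
    if n_spur or n_gap:
        log.info("vGRF gating (%s): removed %d short contact(s), bridged %d short gap(s)",
                 fp.side, n_spur, n_gap)
    return f


def grf_stance_phases(fp: ForcePlateTrace, *, lp_cutoff: float = 30.0,
                      force_threshold: float = 30.0,
                      min_duration: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """IC and FC times from the vertical GRF of one belt.

    Each gated loaded run is one stance; its first sample is the IC and its
    last the FC.  Because even a zero-phase low-pass smears a loading edge
    symmetrically (the filtered force crosses the threshold before the raw
    force does), each run edge is refined to the raw force's threshold
    crossing within the filter's smear width, so thresholds act on
    undelayed force.  Returns ``(ic_times, fc_times)`` (may be empty).
    """
    f = gate_vgrf(fp, lp_cutoff=lp_cutoff, force_threshold=force_threshold,
                  min_duration=min_duration)
    margin = int(round(fp.fs / lp_cutoff))  # ~ smear width of the FIR edge
    ic, fc = [], []
    for a, b in _runs(f > 0):
        lo = max(a - margin, 0)
        hot = np.flatnonzero(fp.vgrf[lo:min(a + margin, b)] >= force_threshold)
        if hot.size:
            a = lo + hot[0]
        hi = min(b + margin, fp.vgrf.size)
        hot = np.flatnonzero(fp.vgrf[max(b - margin, a):hi] >= force_threshold)
        if hot.size:
            b = max(b - margin, a) + hot[-1] + 1
        ic.append(fp.t[a])
        fc.append(fp.t[b - 1])
    return np.asarray(ic), np.asarray(fc)


def grf_events(fp: ForcePlateTrace, **kwargs) -> GaitEvents:
    """Force-plate events packaged for the shared temporal-parameter code.

    MSW/MST are not observable from the plates and stay empty; the average
    cycle duration is the mean IC-to-IC interval.
    """
    ic, fc = grf_stance_phases(fp, **kwargs)
    t_cycle = float(np.mean(np.diff(ic))) if ic.size > 1 else np.nan
    return GaitEvents(side=fp.side, msw=np.array([]), ic=ic, mst=np.array([]),
                      fc=fc, t_cycle=t_cycle)


def flag_contaminated_strides(fp_own: ForcePlateTrace, events: GaitEvents,
                              **gate_kwargs) -> np.ndarray:
    """Validity per stride of ``events.side``: a stride is contaminated when
    its expected swing interval contains no unloaded span on its own plate
    (stepping in the middle of the dual-belt treadmill merges stances)."""
    f = gate_vgrf(fp_own, **gate_kwargs)
    ic = events.ic
    valid = np.ones(max(ic.size - 1, 0), dtype=bool)
    for k in range(ic.size - 1):
        fcs = events.fc[(events.fc > ic[k]) & (events.fc < ic[k + 1])]
        lo = fcs[-1] if fcs.size else ic[k]
        a, b = np.searchsorted(fp_own.t, [lo, ic[k + 1]])
        valid[k] = bool(np.any(f[a:b] == 0.0))
    return valid


def marker_stride_length(marker: MarkerTrace, ic_pair: tuple[float, float],
                         belt_speed: float | None = None) -> float:
    """Stride length: anterior-posterior marker displacement between the two
    ICs plus the distance the belt moved in between."""
    t0, t1 = ic_pair
    if t0 < marker.t[0] or t1 > marker.t[-1]:
        raise ValueError("IC outside marker trace span")
    v = marker.belt_speed if belt_speed is None else belt_speed
    x0, x1 = np.interp([t0, t1], marker.t, marker.pos[:, 0])
    return float((x1 - x0) + v * (t1 - t0))


def _marker_mst(marker: MarkerTrace, t0: float, t1: float) -> float:
    """Marker-side mid-stance proxy: minimum vertical marker speed in stance."""
    a, b = np.searchsorted(marker.t, [t0, t1])
    if b - a < 3:
        return 0.5 * (t0 + t1)
    vz = np.gradient(marker.pos[a:b, 2], 1.0 / marker.fs)
    return float(marker.t[a + int(np.argmin(np.abs(vz)))])


def marker_stride_height_width(marker: MarkerTrace, ic: float, fc: float,
                               ic_next: float) -> tuple[float, float]:
    """Spatial parameters of one stride from the marker path.

    Height is the maximum vertical displacement during swing relative to
    the mid-stance height (mid-stance proxy: minimum vertical marker speed
    within stance).  Width is the maximum perpendicular deviation of the
    horizontal path from that stride's least-squares straight line.
    """
    a, b = np.searchsorted(marker.t, [fc, ic_next])
    if b - a < 2:
        raise ValueError("empty swing interval")
    t_mst = _marker_mst(marker, ic, fc)
    z_mst = float(np.interp(t_mst, marker.t, marker.pos[:, 2]))
    height = float(np.max(marker.pos[a:b, 2]) - z_mst)

    a0, b0 = np.searchsorted(marker.t, [ic, ic_next])
    xy = marker.pos[a0:b0, :2]
    # least-squares straight line (lateral on AP) of the horizontal path;
    # for a degenerate (no AP extent) path the line is the mean lateral level
    if np.ptp(xy[:, 0]) > 1e-9:
        slope, intercept = np.polyfit(xy[:, 0], xy[:, 1], 1)
    else:
        slope, intercept = 0.0, float(np.mean(xy[:, 1]))
    resid = xy[:, 1] - (slope * xy[:, 0] + intercept)
    width = float(np.max(np.abs(resid)) / np.sqrt(1.0 + slope ** 2))
    return height, width


@dataclass
class GroundTruthTrial:
    """Force-plate/marker-derived events and parameters with validity."""

    events: dict                      # side -> GaitEvents
    strides: list[StrideRecord] = field(default_factory=list)
    n_valid: int = 0
    n_excluded: int = 0
    trial_valid: bool = False


def extract_ground_truth(fp_left: ForcePlateTrace, fp_right: ForcePlateTrace,
                         markers_left: MarkerTrace | None = None,
                         markers_right: MarkerTrace | None = None,
                         **gate_kwargs) -> GroundTruthTrial:
    """Full gold-standard extraction for one trial.

    Temporal parameters reuse the same definitions as the sensor pipeline,
    applied to the force-plate events; spatial parameters come from the
    markers when provided.  Trials with fewer than ten valid strides are
    flagged invalid.
    """
    ev = {fp.side: grf_events(fp, **gate_kwargs) for fp in (fp_left, fp_right)}
    records = compute_temporal_params(ev["left"], ev["right"])
    fp_by_side = {"left": fp_left, "right": fp_right}
    mk_by_side = {"left": markers_left, "right": markers_right}
    flags = {s: flag_contaminated_strides(fp_by_side[s], ev[s], **gate_kwargs)
             for s in ("left", "right")}
    counters = {"left": 0, "right": 0}
    for rec in records:
        i = counters[rec.side]
        if i < flags[rec.side].size and not flags[rec.side][i]:
            rec.valid = False
        counters[rec.side] += 1
        marker = mk_by_side[rec.side]
        if marker is None or not rec.valid:
            continue
        side_ev = ev[rec.side]
        t0, t1 = rec.t_ic, rec.t_ic + rec.stride_duration
        fcs = side_ev.fc[(side_ev.fc > t0) & (side_ev.fc < t1)]
        if not fcs.size:
            continue
        try:
            rec.stride_length = marker_stride_length(marker, (t0, t1))
            h, w = marker_stride_height_width(marker, t0, float(fcs[-1]), t1)
            rec.stride_height, rec.stride_width = h, w
        except ValueError:
            rec.valid = False
    n_valid = sum(r.valid for r in records)
    trial = GroundTruthTrial(events=ev, strides=records, n_valid=n_valid,
                             n_excluded=len(records) - n_valid,
                             trial_valid=n_valid >= MIN_VALID_STRIDES)
    log.info("ground truth: %d valid / %d excluded strides (trial %s)",
             trial.n_valid, trial.n_excluded,
             "valid" if trial.trial_valid else "EXCLUDED")
    return trial
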