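"""Adaptive gait-event detection from shank angular velocity and AP acceleration.

The detector personalizes itself to each recording instead of using fixed
thresholds: the average gait-cycle duration ``Tcycle`` is taken from the
dominant spectral component of the sagittal shank angular velocity, the
mid-swing (MSW) peaks are found with a minimum height of 20% of the signal's
99th percentile and a minimum spacing of 50% of ``Tcycle``, and the initial
(IC) / final (FC) contact searches use windows expressed as fractions of
``Tcycle`` anchored on each MSW:

* IC: largest local maximum of the AP acceleration in
  ``[MSW + 5% Tcycle, MSW + 45% Tcycle)``,
* FC: midpoint between the minimum of the angular velocity and the maximum
  of the AP acceleration in ``[MSW - 35% Tcycle, MSW - 5% Tcycle)``,
* MST: maximum of the angular velocity between an IC and the following FC.

Event times are reported at sample resolution (no sub-sample interpolation):
the errors of interest are already close to the 5 ms resolution of a 200 Hz
recording.  Window arithmetic always uses the trial-level ``Tcycle``, not
per-cycle durations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import GaitEvents, ImuTrace, StrideRecord

log = logging.getLogger(__name__)


class NoGaitError(ValueError):
    """No periodicity or no gait cycles could be detected."""


@dataclass
class PeakParams:
    """Personalized peak-detection settings (fractions of signal statistics
    and of the trial-average cycle duration)."""

    min_height_fraction: float = 0.20
    height_percentile: float = 99.0
    min_distance_fraction: float = 0.50
    ic_window: tuple[float, float] = (0.05, 0.45)
    fc_window: tuple[float, float] = (-0.35, -0.05)

    def __post_init__(self) -> None:
        if not 0 < self.min_height_fraction < 1:
            raise ValueError("min_height_fraction must be in (0, 1)")
        if self.ic_window[0] >= self.ic_window[1] or self.fc_window[0] >= self.fc_window[1]:
            raise ValueError("window bounds must be ordered")


def normalize_sign(gyro_z: np.ndarray, params: PeakParams | None = None) -> tuple[np.ndarray, int]:
    """Flip the sagittal angular velocity so mid-swing is a positive peak.

    Laterally mounted left/right sensors have mirrored z-axes; the side with
    the larger 99th-percentile magnitude is taken as the swing direction.
    Returns the (possibly flipped) signal and the applied sign (+1 or -1).
    """
    p = (params or PeakParams()).height_percentile
    x = np.asarray(gyro_z, dtype=float)
    sign = -1 if np.percentile(-x, p) > np.percentile(x, p) else 1
    return sign * x, sign


def dominant_cycle_duration(gyro_z: np.ndarray, fs: float, *,
                            band: tuple[float, float] = (0.2, 2.0),
                            freq_resolution: float = 0.01,
                            main_fraction: float = 0.5) -> float:
    """Average gait-cycle duration from the first main spectral component.

    ``Tcycle = 1 / fmax`` where ``fmax`` is the frequency of the first
    (lowest-frequency) main component of the magnitude spectrum of the
    mean-removed signal within the physiological band (default 0.2-2.0 Hz,
    i.e. stride durations of 0.5-5 s, DC excluded).  "Main" means a local
    spectral peak reaching at least ``main_fraction`` of the largest
    in-band magnitude: one-sided gait signals carry strong harmonics of
    the cycle frequency that can rival the fundamental, and locking onto a
    harmonic would halve every adaptive search window.  The FFT is
    zero-padded so the frequency resolution is at most ``freq_resolution``.
    """
    x = np.asarray(gyro_z, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be > 0")
    x = x - np.mean(x)
    n = x.size
    n_fft = int(2 ** np.ceil(np.log2(max(n, fs / freq_resolution))))
    spec = np.abs(np.fft.rfft(x, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise NoGaitError("search band contains no frequency bins")
    mags = spec[in_band]
    floor = 1e-9 * np.sqrt(np.sum(x ** 2) + 1e-300) * n
    if np.max(mags) <= floor or not np.any(x):
        raise NoGaitError("no dominant periodicity")
    peaks, _ = sps.find_peaks(mags, height=main_fraction * np.max(mags))
    i_max = peaks[0] if peaks.size else int(np.argmax(mags))
    fmax = freqs[in_band][i_max]
    return float(1.0 / fmax)


def detect_midswing(gyro_z: np.ndarray, fs: float, t_cycle: float,
                    params: PeakParams | None = None,
                    t0: float = 0.0) -> np.ndarray:
    """Mid-swing times: prominent positive peaks of the angular velocity.

    Peaks must reach ``min_height_fraction`` of the ``height_percentile``-th
    percentile of the signal and be spaced at least
    ``min_distance_fraction * Tcycle`` apart (greedy suppression, higher
    peak wins; ties break toward the earlier sample).
    """
    params = params or PeakParams()
    x = np.asarray(gyro_z, dtype=float)
    height = params.min_height_fraction * np.percentile(x, params.height_percentile)
    distance = max(1, int(round(params.min_distance_fraction * t_cycle * fs)))
    idx, _ = sps.find_peaks(x, height=height, distance=distance)
    if idx.size == 0:
        raise NoGaitError("no gait detected")
    return t0 + idx / fs


def _window_slice(t0: float, fs: float, n: int, start: float, end: float):
    """Sample range for the half-open time window [start, end)."""
    i0 = int(np.ceil((start - t0) * fs - 1e-9))
    i1 = int(np.ceil((end - t0) * fs - 1e-9))
    return max(i0, 0), min(i1, n), i0 >= 0 and i1 <= n


def detect_initial_contact(acc_ap: np.ndarray, msw: np.ndarray, t_cycle: float,
                           fs: float, params: PeakParams | None = None,
                           t0: float = 0.0):
    """IC per MSW: largest local maximum of the AP acceleration in the
    window ``[MSW + 5% Tcycle, MSW + 45% Tcycle)``.

    If the window holds no interior local maximum, its global maximum is
    used and the cycle flagged.  Cycles whose window extends past the end
    of the signal are dropped (incomplete), as are their MSWs.

    Returns ``(ic_times, kept_msw_mask, flags)``.
    """
    params = params or PeakParams()
    a = np.asarray(acc_ap, dtype=float)
    lo, hi = params.ic_window
    ic, kept, flags = [], np.zeros(len(msw), bool), []
    for k, m in enumerate(np.asarray(msw, dtype=float)):
        i0, i1, inside = _window_slice(t0, fs, a.size, m + lo * t_cycle, m + hi * t_cycle)
        if not inside or i1 - i0 < 3:
            continue
        seg = a[i0:i1]
        pk, _ = sps.find_peaks(seg)
        if pk.size:
            j = pk[np.argmax(seg[pk])]
            flag = False
        else:
            j = int(np.argmax(seg))
            flag = True
        ic.append(t0 + (i0 + j) / fs)
        flags.append(flag)
        kept[k] = True
    return np.asarray(ic), kept, np.asarray(flags, dtype=bool)


def detect_final_contact(gyro_z: np.ndarray, acc_ap: np.ndarray,
                         msw: np.ndarray, t_cycle: float, fs: float,
                         params: PeakParams | None = None, t0: float = 0.0):
    """FC per MSW: midpoint between the angular-velocity minimum and the
    AP-acceleration maximum in ``[MSW - 35% Tcycle, MSW - 5% Tcycle)``.

    Global window extrema are used.  The FC is assigned to the cycle
    ending at that MSW; cycles whose window starts before the signal are
    dropped.  Returns ``(fc_times, kept_msw_mask)``.
    """
    params = params or PeakParams()
    w = np.asarray(gyro_z, dtype=float)
    a = np.asarray(acc_ap, dtype=float)
    lo, hi = params.fc_window
    fc, kept = [], np.zeros(len(msw), bool)
    for k, m in enumerate(np.asarray(msw, dtype=float)):
        i0, i1, inside = _window_slice(t0, fs, w.size, m + lo * t_cycle, m + hi * t_cycle)
        if not inside or i1 - i0 < 3:
            continue
        t_min = t0 + (i0 + int(np.argmin(w[i0:i1]))) / fs
        t_max = t0 + (i0 + int(np.argmax(a[i0:i1]))) / fs
        fc.append(0.5 * (t_min + t_max))
        kept[k] = True
    return np.asarray(fc), kept


def detect_midstance(gyro_z: np.ndarray, ic: np.ndarray, fc: np.ndarray,
                     fs: float, t0: float = 0.0) -> np.ndarray:
    """MST per stance: maximum of the angular velocity in ``[IC, next FC)``.

    With the mid-swing-positive sign convention the stance-phase angular
    velocity is small, and its maximum marks the quasi-static instant the
    per-stride integration is anchored on.  Unmatched ICs (no following FC)
    are dropped.  A monotone signal puts MST on the last sample before FC.
    """
    w = np.asarray(gyro_z, dtype=float)
    fc = np.asarray(fc, dtype=float)
    mst = []
    for t_ic in np.asarray(ic, dtype=float):
        nxt = fc[fc > t_ic]
        if nxt.size == 0:
            continue
        i0, i1, inside = _window_slice(t0, fs, w.size, t_ic, nxt[0])
        if i1 - i0 < 1:
            continue
        mst.append(t0 + (i0 + int(np.argmax(w[i0:i1]))) / fs)
    return np.asarray(mst)


def detect_events(imu: ImuTrace, params: PeakParams | None = None) -> GaitEvents:
    """Run the full event-detection chain on one shank sensor."""
    params = params or PeakParams()
    wz, sign = normalize_sign(imu.gyro_sagittal, params)
    if sign < 0:
        log.info("side %s: sagittal angular velocity sign-flipped", imu.side)
    ay = imu.acc_ap
    t0, fs = float(imu.t[0]), imu.fs
    t_cycle = dominant_cycle_duration(wz, fs)
    msw = detect_midswing(wz, fs, t_cycle, params, t0)
    ic, kept_ic, ic_flags = detect_initial_contact(ay, msw, t_cycle, fs, params, t0)
    fc, kept_fc = detect_final_contact(wz, ay, msw, t_cycle, fs, params, t0)
    mst = detect_midstance(wz, ic, fc, fs, t0)
    n_drop = int((~kept_ic).sum() + (~kept_fc).sum())
    log.info("side %s: %d cycles, %d incomplete boundary cycle(s) dropped",
             imu.side, len(msw), n_drop)
    return GaitEvents(side=imu.side, msw=msw, ic=ic, mst=mst, fc=fc,
                      t_cycle=t_cycle, ic_flagged=ic_flags)


def _first_after(times: np.ndarray, t: float) -> float:
    nxt = times[times > t]
    return float(nxt[0]) if nxt.size else np.nan


def compute_temporal_params(events_left: GaitEvents,
                            events_right: GaitEvents) -> list[StrideRecord]:
    """Temporal stride parameters for both sides from detected events.

    Per stride ``k`` (IC(k) to IC(k+1) of the same side):

    * ``stride_duration = IC(k+1) - IC(k)``
    * ``swing_pct``: from the last FC inside the stride to IC(k+1), as % of
      the stride; ``stance_pct = 100 - swing_pct`` exactly
    * ``step_duration``: first contralateral IC after IC(k), minus IC(k)
    * ``double_support_pct``: first contralateral FC after IC(k), minus
      IC(k), as % of the stride

    Strides lacking a matching ipsilateral FC or contralateral event are
    flagged invalid (their missing fields stay NaN).
    """
    records: list[StrideRecord] = []
    pair = {"left": events_right, "right": events_left}
    for ev in (events_left, events_right):
        other = pair[ev.side]
        ic = np.asarray(ev.ic, dtype=float)
        if ic.size < 2:
            continue
        for k in range(ic.size - 1):
            t_ic, t_next = ic[k], ic[k + 1]
            dur = t_next - t_ic
            rec = StrideRecord(side=ev.side, t_ic=float(t_ic), stride_duration=float(dur))
            fcs = ev.fc[(ev.fc > t_ic) & (ev.fc < t_next)]
            if fcs.size:
                swing = (t_next - fcs[-1]) / dur * 100.0
                rec.swing_pct = float(swing)
                rec.stance_pct = 100.0 - float(swing)
            else:
                rec.valid = False
            t_step = _first_after(other.ic, t_ic)
            if np.isfinite(t_step) and t_step < t_next:
                rec.step_duration = float(t_step - t_ic)
            else:
                rec.valid = False
            t_ds = _first_after(other.fc, t_ic)
            if np.isfinite(t_ds) and t_ds < t_next:
                rec.double_support_pct = float((t_ds - t_ic) / dur * 100.0)
            else:
                rec.valid = False
            records.append(rec)
    records.sort(key=lambda r: r.t_ic)
    return records
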