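"""Independent exhaustive-scan oracle used by unit and acceptance tests."""

import numpy as np

from gaitspan.events import PeakParams, dominant_cycle_duration


def naive_detector(wz, ay, fs, params: PeakParams):
    """Exhaustive-scan re-derivation of the event chain (independent oracle):
    local maxima by direct neighbour comparison, greedy distance suppression
    by height, window extrema by linear scan."""
    t_cycle = dominant_cycle_duration(wz, fs)  # shared periodicity stage
    height = params.min_height_fraction * np.percentile(wz, params.height_percentile)
    dist = max(1, int(round(params.min_distance_fraction * t_cycle * fs)))
    cand = [i for i in range(1, len(wz) - 1)
            if wz[i] > wz[i - 1] and wz[i] >= wz[i + 1] and wz[i] >= height]
    keep = []
    for i in sorted(cand, key=lambda i: -wz[i]):
        if all(abs(i - j) >= dist for j in keep):
            keep.append(i)
    msw = np.array(sorted(keep)) / fs

    def wslice(lo, hi):
        i0 = int(np.ceil(lo * fs - 1e-9))
        i1 = int(np.ceil(hi * fs - 1e-9))
        return i0, i1

    ics, fcs = [], []
    for m in msw:
        i0, i1 = wslice(m + 0.05 * t_cycle, m + 0.45 * t_cycle)
        if i0 >= 0 and i1 <= len(ay):
            local = [i for i in range(max(i0, 1), min(i1, len(ay) - 1))
                     if ay[i] > ay[i - 1] and ay[i] >= ay[i + 1]]
            if local:
                best = max(local, key=lambda i: ay[i])
            else:
                best = i0 + int(np.argmax(ay[i0:i1]))
            ics.append(best / fs)
        i0, i1 = wslice(m - 0.35 * t_cycle, m - 0.05 * t_cycle)
        if i0 >= 0 and i1 <= len(wz) and i1 - i0 >= 3:
            tmin = (i0 + int(np.argmin(wz[i0:i1]))) / fs
            tmax = (i0 + int(np.argmax(ay[i0:i1]))) / fs
            fcs.append(0.5 * (tmin + tmax))
    msts = []
    for t_ic in ics:
        later = [f for f in fcs if f > t_ic]
        if later:
            i0, i1 = wslice(t_ic, later[0])
            msts.append((i0 + int(np.argmax(wz[i0:i1]))) / fs)
    return msw, np.array(ics), np.array(fcs), np.array(msts)

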