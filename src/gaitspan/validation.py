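"""Method-agreement statistics between sensor-derived and reference strides.

Strides are paired by nearest initial contact, errors are ``sensor -
reference`` per gait cycle, and cohort summaries follow the convention of
averaging per subject and side first (left and right are never pooled into
one limb, so an asymmetric deficit is not averaged out).  Agreement is
summarized by the Bland-Altman mean difference (bias) and 95% limits of
agreement ``bias +/- 1.96 * SD``; the sample standard deviation (n-1) is
used throughout.  No relative error is defined for event timings (they are
not parameters) nor reported for stride width and height (the reference
values are close to zero, which inflates ratios).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import StrideRecord

#: parameters compared per stride, with unit of the error
PARAMETERS = {
    "stride_duration": "s",
    "step_duration": "s",
    "swing_pct": "%",
    "stance_pct": "%",
    "double_support_pct": "%",
    "stride_length": "m",
    "stride_width": "m",
    "stride_height": "m",
}

#: parameters for which a mean relative error is reported
RELATIVE_PARAMETERS = ("stride_duration", "step_duration", "swing_pct",
                       "stance_pct", "double_support_pct", "stride_length")


@dataclass
class MatchResult:
    pairs: list[tuple[StrideRecord, StrideRecord]]
    n_missed: int  # reference-only strides
    n_extra: int   # sensor-only strides


def match_strides(sensor_strides, reference_strides,
                  max_offset: float = 0.5) -> MatchResult:
    """Greedy nearest-IC pairing of sensor and reference strides.

    ``max_offset`` is the largest |IC difference| (s) accepted for a pair;
    use half the average cycle duration.  On well-separated gait the greedy
    result coincides with the optimal assignment.  Only same-side strides
    are paired.
    """
    pairs: list[tuple[StrideRecord, StrideRecord]] = []
    n_missed = n_extra = 0
    for side in ("left", "right"):
        sens = [r for r in sensor_strides if r.side == side]
        refs = [r for r in reference_strides if r.side == side]
        candidates = sorted(
            ((abs(s.t_ic - r.t_ic), i, j) for i, s in enumerate(sens)
             for j, r in enumerate(refs) if abs(s.t_ic - r.t_ic) <= max_offset),
        )
        used_s, used_r = set(), set()
        for _, i, j in candidates:
            if i not in used_s and j not in used_r:
                pairs.append((sens[i], refs[j]))
                used_s.add(i)
                used_r.add(j)
        n_extra += len(sens) - len(used_s)
        n_missed += len(refs) - len(used_r)
    pairs.sort(key=lambda p: p[0].t_ic)
    return MatchResult(pairs=pairs, n_missed=n_missed, n_extra=n_extra)


def match_event_times(detected: np.ndarray, reference: np.ndarray,
                      max_offset: float) -> np.ndarray:
    """Signed timing errors (detected - reference) for greedily paired events."""
    detected = np.asarray(detected, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cand = sorted((abs(d - r), i, j) for i, d in enumerate(detected)
                  for j, r in enumerate(reference) if abs(d - r) <= max_offset)
    used_d, used_r, errs = set(), set(), []
    for _, i, j in cand:
        if i not in used_d and j not in used_r:
            errs.append(detected[i] - reference[j])
            used_d.add(i)
            used_r.add(j)
    return np.asarray(errs)


def pair_errors(pairs) -> pd.DataFrame:
    """Per-pair errors (sensor - reference) and reference values."""
    rows = []
    for sens, ref in pairs:
        row = {"side": sens.side, "t_ic": sens.t_ic}
        for par in PARAMETERS:
            s, r = getattr(sens, par), getattr(ref, par)
            row[par] = s - r
            row[f"{par}_ref"] = r
        rows.append(row)
    return pd.DataFrame(rows)


def error_summary(pairs, subject: str = "s0") -> pd.DataFrame:
    """Mean error, SD and mean relative error per parameter.

    Errors are averaged per subject and side first, then across
    subject-sides; the relative error is the mean error divided by the mean
    reference value of that subject-side, in percent.  ``pairs`` may also
    be a list of ``(subject, MatchResult-pairs)`` tuples for a cohort.
    """
    if pairs and isinstance(pairs[0], tuple) and isinstance(pairs[0][0], str):
        frames = []
        for subj, p in pairs:
            df = pair_errors(p)
            df["subject"] = subj
            frames.append(df)
        errors = pd.concat(frames, ignore_index=True)
    else:
        errors = pair_errors(pairs)
        errors["subject"] = subject
    if errors.empty:
        raise ValueError("no stride pairs to summarize")
    group = errors.groupby(["subject", "side"])
    rows = []
    for par in PARAMETERS:
        per_ss = group[par].mean()
        per_ref = group[f"{par}_ref"].mean()
        rel = (100.0 * per_ss / per_ref).mean() if par in RELATIVE_PARAMETERS else np.nan
        rows.append({
            "parameter": par,
            "mean_error": per_ss.mean(),
            "sd_error": per_ss.std(ddof=1) if len(per_ss) > 1 else 0.0,
            "mean_relative_error_pct": rel,
            "n_pairs": int(errors[par].notna().sum()),
        })
    return pd.DataFrame(rows).set_index("parameter")


def bland_altman(differences) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement of paired differences.

    ``bias = mean(d)``, ``LoA = bias +/- 1.96 * SD(d)`` with the sample
    standard deviation (ddof=1).  Requires at least two differences.
    """
    d = np.asarray(differences, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 2:
        raise ValueError("need at least 2 differences")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def intra_subject_variability(per_subject_sds) -> float:
    """Average of the within-subject standard deviations."""
    sds = np.asarray(per_subject_sds, dtype=float)
    if sds.size == 0:
        raise ValueError("need at least one subject")
    return float(np.mean(sds))


@dataclass
class AgreementReport:
    """Per-parameter agreement between the sensor pipeline and a reference."""

    summary: pd.DataFrame                 # error_summary output
    bland_altman: dict = field(default_factory=dict)  # par -> (bias, lo, hi)
    n_missed: int = 0
    n_extra: int = 0

    def to_dict(self) -> dict:
        out = {"n_missed": self.n_missed, "n_extra": self.n_extra, "parameters": {}}
        for par, row in self.summary.iterrows():
            entry = {k: (None if isinstance(v, float) and np.isnan(v) else v)
                     for k, v in row.items()}
            if par in self.bland_altman:
                bias, lo, hi = self.bland_altman[par]
                entry.update({"ba_bias": bias, "ba_loa_lower": lo, "ba_loa_upper": hi})
            out["parameters"][par] = entry
        return out


def agreement_report(matches, *, pooled: bool = True) -> AgreementReport:
    """Build an :class:`AgreementReport` from one or more match results.

    ``matches`` is either a single :class:`MatchResult` or a list of
    ``(subject, MatchResult)``.  With ``pooled=True`` the Bland-Altman
    statistics pool all paired cycles; otherwise they use the
    subject-side means (both conventions are in use for limits of
    agreement; the summary table always aggregates subject-side means).
    """
    if isinstance(matches, MatchResult):
        matches = [("s0", matches)]
    labelled = [(subj, m.pairs) for subj, m in matches]
    summary = error_summary(labelled)
    frames = []
    for subj, p in labelled:
        df = pair_errors(p)
        df["subject"] = subj
        frames.append(df)
    errors = pd.concat(frames, ignore_index=True)
    ba = {}
    for par in PARAMETERS:
        if pooled:
            d = errors[par].to_numpy()
        else:
            d = errors.groupby(["subject", "side"])[par].mean().to_numpy()
        d = d[np.isfinite(d)]
        if d.size >= 2:
            ba[par] = bland_altman(d)
    return AgreementReport(summary=summary, bland_altman=ba,
                           n_missed=sum(m.n_missed for _, m in matches),
                           n_extra=sum(m.n_extra for _, m in matches))
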