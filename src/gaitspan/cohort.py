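"""Synthetic-cohort evaluation: run the full pipeline against ground truth.

These helpers simulate seeded treadmill trials at the validated walking
regimes, run the sensor pipeline end to end, pair every detected stride
and event with the generator's exact truth, and aggregate the error
statistics the validation literature reports (per-trial means first, then
cohort means; Bland-Altman biases over pooled cycles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import analyze_trial, truth_records
from .synthetic import (GaitModelParams, SyntheticTrial, duration_for_strides,
                        preset, simulate_trial)
from .validation import match_event_times, match_strides, pair_errors


@dataclass
class TrialEvaluation:
    """Sensor-vs-truth outcome of one synthetic trial."""

    condition: str
    seed: int
    errors: pd.DataFrame        # per paired stride: parameter errors + refs
    ic_errors: np.ndarray       # signed IC timing errors, s (both sides)
    fc_errors: np.ndarray       # signed FC timing errors, s
    n_cycles_detected: int
    n_cycles_truth: int
    n_unmatched_cycles: int     # MSW without a truth partner or vice versa
    n_missed: int               # truth strides without sensor partner (common span)
    n_extra: int


def evaluate_trial(trial: SyntheticTrial, condition: str = "") -> TrialEvaluation:
    """Run the sensor pipeline on a synthetic trial and score it against truth."""
    result = analyze_trial(trial.imu_left, trial.imu_right)
    truth = truth_records(trial)
    t_cycle = trial.params.stride_duration

    lo = min(r.t_ic for r in result.strides)
    hi = max(r.t_ic for r in result.strides)
    truth_in = [r for r in truth if lo - 0.3 <= r.t_ic <= hi + 0.3]
    match = match_strides(result.strides, truth_in, max_offset=0.5 * t_cycle)
    errors = pair_errors(match.pairs)

    ic_err, fc_err = [], []
    n_det = n_tru = n_unmatched = 0
    for side, analysis in (("left", result.left), ("right", result.right)):
        ev, tr = analysis.events, trial.truth[side]
        ic_err.append(match_event_times(ev.ic, tr.ic, 0.5 * t_cycle))
        fc_err.append(match_event_times(ev.fc, tr.fc, 0.5 * t_cycle))
        matched = match_event_times(ev.msw, tr.msw, 0.5 * t_cycle).size
        n_det += ev.msw.size
        n_tru += tr.msw.size
        n_unmatched += (ev.msw.size - matched) + (tr.msw.size - matched)
    return TrialEvaluation(
        condition=condition, seed=trial.params.rng_seed,
        errors=errors,
        ic_errors=np.concatenate(ic_err), fc_errors=np.concatenate(fc_err),
        n_cycles_detected=n_det, n_cycles_truth=n_tru,
        n_unmatched_cycles=n_unmatched,
        n_missed=match.n_missed, n_extra=match.n_extra)


def run_cohort(conditions, seeds, *, min_strides: int = 100,
               **param_overrides) -> list[TrialEvaluation]:
    """Simulate and evaluate one trial per (condition, seed).

    Trial durations are chosen so each trial holds at least ``min_strides``
    complete strides (the validated trials lasted 180 s; the slowest regime
    needs a little longer to reach 100 strides).
    """
    out = []
    for cond in conditions:
        for seed in seeds:
            params = preset(cond, rng_seed=int(seed), **param_overrides)
            dur = max(180.0, duration_for_strides(params, min_strides))
            params = GaitModelParams(**{**params.__dict__, "trial_duration": dur})
            out.append(evaluate_trial(simulate_trial(params), condition=cond))
    return out


def _phase_errors_ms(errors: pd.DataFrame) -> dict[str, np.ndarray]:
    """Temporal-parameter errors per cycle in ms (phases via stride duration)."""
    e = errors
    dur_ref = e["stride_duration_ref"]
    out = {
        "stride_duration": e["stride_duration"].to_numpy() * 1e3,
        "step_duration": e["step_duration"].to_numpy() * 1e3,
    }
    for par in ("swing_pct", "double_support_pct"):
        sens = (e[par] + e[f"{par}_ref"]) / 100.0 * (e["stride_duration"] + dur_ref)
        ref = e[f"{par}_ref"] / 100.0 * dur_ref
        out[par] = (sens - ref).to_numpy() * 1e3
    return out


def cohort_metrics(evaluations: list[TrialEvaluation]) -> dict:
    """Cohort-level error metrics (trial means first, pooled Bland-Altman).

    Returns a dict with, among others: ``mean_stride_duration_error_ms``,
    ``mean_relative_stride_length_error_pct``, ``mean_ic_error_ms``,
    ``mean_fc_error_ms``, ``max_temporal_bias_ms``, ``max_spatial_bias_mm``
    and the missed/extra cycle counts.
    """
    per_trial = {"dur_ms": [], "len_rel": [], "len_mm": [], "ic_ms": [], "fc_ms": []}
    pooled = []
    for ev in evaluations:
        e = ev.errors
        per_trial["dur_ms"].append(e["stride_duration"].mean() * 1e3)
        per_trial["len_mm"].append(e["stride_length"].mean() * 1e3)
        per_trial["len_rel"].append(
            100.0 * e["stride_length"].mean() / e["stride_length_ref"].mean())
        per_trial["ic_ms"].append(ev.ic_errors.mean() * 1e3)
        per_trial["fc_ms"].append(ev.fc_errors.mean() * 1e3)
        pooled.append(e)
    pooled = pd.concat(pooled, ignore_index=True)
    phase = _phase_errors_ms(pooled)
    temporal_bias = {k: float(np.nanmean(v)) for k, v in phase.items()}
    spatial_bias = {par: float(pooled[par].mean() * 1e3)
                    for par in ("stride_length", "stride_width", "stride_height")}
    return {
        "mean_stride_duration_error_ms": float(np.mean(per_trial["dur_ms"])),
        "mean_stride_length_error_mm": float(np.mean(per_trial["len_mm"])),
        "mean_relative_stride_length_error_pct": float(np.mean(per_trial["len_rel"])),
        "mean_ic_error_ms": float(np.mean(per_trial["ic_ms"])),
        "mean_fc_error_ms": float(np.mean(per_trial["fc_ms"])),
        "temporal_bias_ms": temporal_bias,
        "spatial_bias_mm": spatial_bias,
        "max_temporal_bias_ms": float(max(abs(v) for v in temporal_bias.values())),
        "max_spatial_bias_mm": float(max(abs(v) for v in spatial_bias.values())),
        "n_unmatched_cycles": int(sum(ev.n_unmatched_cycles for ev in evaluations)),
        "n_missed_strides": int(sum(ev.n_missed for ev in evaluations)),
        "n_extra_strides": int(sum(ev.n_extra for ev in evaluations)),
        "n_trials": len(evaluations),
        "n_pairs": int(len(pooled)),
    }
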