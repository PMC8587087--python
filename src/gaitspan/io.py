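"""Readers and writers for the delimited-text stream formats.

All files are plain CSV (comma separated, ``.`` decimal, mandatory header
row).  Units are normalized on read to the internal convention
(s, m, m/s^2, rad/s) according to the :class:`~gaitspan.types.TrialConfig`
unit declarations, so unit normalization is idempotent by construction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import ForcePlateTrace, ImuTrace, MarkerTrace, StrideRecord, TrialConfig

log = logging.getLogger(__name__)

_DEG2RAD = np.pi / 180.0
_G = 9.81

#: maximum marker gap that is silently interpolated (s); longer gaps
#: invalidate the strides they touch (tracked via ``gap_flags``)
MARKER_GAP_INTERP_MAX = 0.1


class MissingColumnError(KeyError):
    """A required column is absent from the input file."""


class NonMonotonicTimeError(ValueError):
    """The time column jumps backwards beyond tolerance."""


class EmptyFileError(ValueError):
    """The input file contains a header but no data rows."""


def _load_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyFileError(f"{path}: no data rows")
    return df


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing column(s) {missing}")


def _uniform_time(t: np.ndarray, fs: float, path) -> tuple[np.ndarray, np.ndarray]:
    """Return a uniform time base at ``fs`` and the original stamps.

    Non-uniform stamps are tolerated and later resampled by linear
    interpolation; time running backwards is a hard error.
    """
    if np.any(np.diff(t) <= 0):
        raise NonMonotonicTimeError(f"{path}: non-monotonic time")
    n = int(round((t[-1] - t[0]) * fs)) + 1
    return t[0] + np.arange(n) / fs, t


def read_imu(path, config: TrialConfig | None = None, *, fs: float = 200.0,
             side: str = "left") -> ImuTrace:
    """Read a 7-column IMU CSV (time, 3 acc, 3 gyro) into an :class:`ImuTrace`.

    Units are converted to m/s^2 and rad/s per the config declarations and
    non-uniform timestamps are resampled to ``fs`` by linear interpolation.
    """
    config = config or TrialConfig()
    df = _load_csv(path)
    cols = (config.time_column, *config.acc_columns, *config.gyro_columns)
    _require(df, cols, path)
    t_raw = df[config.time_column].to_numpy(dtype=float)
    acc = df[list(config.acc_columns)].to_numpy(dtype=float)
    gyro = df[list(config.gyro_columns)].to_numpy(dtype=float)
    if config.acc_units == "g":
        acc = acc * _G
    if config.gyro_units == "deg/s":
        gyro = gyro * _DEG2RAD
    t, t_raw = _uniform_time(t_raw, fs, path)
    if t.size != t_raw.size or np.max(np.abs(t - t_raw)) > 1e-6:
        acc = np.column_stack([np.interp(t, t_raw, acc[:, i]) for i in range(3)])
        gyro = np.column_stack([np.interp(t, t_raw, gyro[:, i]) for i in range(3)])
    return ImuTrace(t=t, acc=acc, gyro=gyro, fs=fs, side=side)


def read_forceplate(path, *, fs: float = 1000.0, side: str = "left",
                    time_column: str = "t", force_column: str = "vgrf") -> ForcePlateTrace:
    """Read a 2-column (t, vGRF in N) CSV into a :class:`ForcePlateTrace`."""
    df = _load_csv(path)
    _require(df, (time_column, force_column), path)
    t_raw = df[time_column].to_numpy(dtype=float)
    f = df[force_column].to_numpy(dtype=float)
    t, t_raw = _uniform_time(t_raw, fs, path)
    if t.size != t_raw.size or np.max(np.abs(t - t_raw)) > 1e-6:
        f = np.interp(t, t_raw, f)
    return ForcePlateTrace(t=t, vgrf=f, fs=fs, side=side)


def read_markers(path, *, fs: float = 100.0, side: str = "left",
                 belt_speed: float = 0.0, time_column: str = "t",
                 pos_columns=("x", "y", "z")) -> MarkerTrace:
    """Read a marker CSV (t, x, y, z in m) into a :class:`MarkerTrace`.

    NaN gaps up to ``MARKER_GAP_INTERP_MAX`` seconds are linearly
    interpolated; every interpolated sample is flagged in ``gap_flags`` so
    longer dropouts can invalidate the strides they overlap.
    """
    df = _load_csv(path)
    _require(df, (time_column, *pos_columns), path)
    t_raw = df[time_column].to_numpy(dtype=float)
    pos = df[list(pos_columns)].to_numpy(dtype=float)
    t, t_raw = _uniform_time(t_raw, fs, path)
    if t.size != t_raw.size:
        pos = np.column_stack([np.interp(t, t_raw, pos[:, i]) for i in range(3)])
        t_raw = t
    gap = np.any(~np.isfinite(pos), axis=1)
    if gap.any():
        ok = ~gap
        if not ok.any():
            raise EmptyFileError(f"{path}: all marker samples are NaN")
        pos = np.column_stack(
            [np.interp(t, t[ok], pos[ok, i]) for i in range(3)])
        n_gaps = int(np.sum(np.diff(np.concatenate(([0], gap.view(np.int8), [0]))) == 1))
        log.info("%s: interpolated %d marker gap(s), %d samples", path, n_gaps, gap.sum())
    return MarkerTrace(t=t, pos=pos, fs=fs, belt_speed=belt_speed, side=side,
                       gap_flags=gap if gap.any() else None)


def marker_gap_spans(trace: MarkerTrace) -> list[tuple[float, float]]:
    """Return [start, end) time spans of interpolated marker gaps."""
    if trace.gap_flags is None:
        return []
    g = np.concatenate(([False], trace.gap_flags, [False]))
    edges = np.flatnonzero(np.diff(g.view(np.int8)))
    return [(float(trace.t[a]), float(trace.t[min(b, len(trace.t) - 1)]))
            for a, b in zip(edges[::2], edges[1::2])]


def stride_table(records) -> pd.DataFrame:
    """Stride records as a DataFrame, one row per stride."""
    return pd.DataFrame([{f: getattr(r, f) for f in StrideRecord.FIELDS}
                         for r in records], columns=list(StrideRecord.FIELDS))


def write_stride_table(records, path) -> None:
    """Write one CSV row per :class:`StrideRecord` (lossless round trip)."""
    if not records:
        warnings.warn("writing empty stride table (header only)", stacklevel=2)
    stride_table(records).to_csv(path, index=False, float_format="%.12g")


def read_stride_table(path) -> list[StrideRecord]:
    df = pd.read_csv(path)
    recs = []
    for _, row in df.iterrows():
        kw = {f: row[f] for f in StrideRecord.FIELDS}
        kw["valid"] = bool(kw["valid"])
        recs.append(StrideRecord(**kw))
    return recs


def load_config(path) -> TrialConfig:
    """Load a :class:`TrialConfig` from YAML or JSON."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    data = data or {}
    for key in ("acc_columns", "gyro_columns"):
        if key in data:
            data[key] = tuple(data[key])
    return TrialConfig(**data)


def save_config(config: TrialConfig, path) -> None:
    data = asdict(config)
    data["acc_columns"] = list(data["acc_columns"])
    data["gyro_columns"] = list(data["gyro_columns"])
    Path(path).write_text(yaml.safe_dump(data))


def write_imu(trace: ImuTrace, path, config: TrialConfig | None = None) -> None:
    """Write an :class:`ImuTrace` in the dialect :func:`read_imu` expects."""
    config = config or TrialConfig()
    cols = {config.time_column: trace.t}
    for i, c in enumerate(config.acc_columns):
        cols[c] = trace.acc[:, i]
    for i, c in enumerate(config.gyro_columns):
        cols[c] = trace.gyro[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def write_forceplate(trace: ForcePlateTrace, path) -> None:
    pd.DataFrame({"t": trace.t, "vgrf": trace.vgrf}).to_csv(
        path, index=False, float_format="%.12g")


def write_markers(trace: MarkerTrace, path) -> None:
    pd.DataFrame({"t": trace.t, "x": trace.pos[:, 0], "y": trace.pos[:, 1],
                  "z": trace.pos[:, 2]}).to_csv(path, index=False, float_format="%.12g")
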