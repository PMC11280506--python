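"""Readers/writers for sensor exports, annotations, epoch tables, and
threshold files, plus annotation-to-sensor clock alignment.

Sensor exports are delimited text with a time column and three axis
columns in m/s^2 (a unit conversion factor is a reader option).
Annotations follow the plain-text interval-export family used by video
coding tools: one labelled interval per row with start and end times in
seconds or milliseconds. All internal times are seconds on the session
clock; sample index = round(time / dt).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .types import (
    LABELS3,
    AnnotationTrack,
    EpochRecord,
    Interval,
    ThresholdSet,
    TriaxialSeries,
)
from .defaults import QUANTITY_UNITS

PathLike = Union[str, Path]

#: Accepted spellings of the three intensity labels (lower-cased keys).
LABEL_ALIASES = {
    "sed": "SED",
    "sedentary": "SED",
    "light": "LIGHT",
    "mv": "MV",
    "moderate-to-vigorous": "MV",
    "moderate_to_vigorous": "MV",
    "moderate to vigorous": "MV",
    "modvig": "MV",
}

DEFAULT_COLUMN_MAP = {"time": "time_s", "ax": "ax", "ay": "ay", "az": "az"}

EPOCH_COLUMNS = [
    "subject_id",
    "window_start_s",
    "window_end_s",
    "gold_label",
    "c_a_left",
    "c_a_right",
    "c_a_total",
    "c_j_left",
    "c_j_right",
    "c_j_total",
]


def normalize_label(raw: str) -> str:
    key = str(raw).strip().lower()
    if key in LABEL_ALIASES:
        return LABEL_ALIASES[key]
    if str(raw).strip().upper() in LABELS3:
        return str(raw).strip().upper()
    raise ValueError(f"unknown activity label: {raw!r}")


def read_sensor_table(
    path: PathLike,
    column_map: Optional[dict[str, str]] = None,
    sampling_rate: Optional[float] = None,
    unit_scale: float = 1.0,
    sep: str = ",",
) -> TriaxialSeries:
    """Read a delimited sensor export into a TriaxialSeries.

    ``column_map`` maps the logical names time/ax/ay/az to file columns
    (default: time_s, ax, ay, az). ``sampling_rate`` overrides the rate
    inferred from the time column; ``unit_scale`` multiplies the axis
    values (e.g. 9.81 for a file in g units). Gaps larger than 1.5x the
    sample period and non-monotone time are errors.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"sensor file is empty: {path}")
    missing = [c for c in cmap.values() if c not in df.columns]
    if missing:
        raise ValueError(f"sensor file {path} is missing columns: {missing}")
    t = df[cmap["time"]].to_numpy(dtype=float)
    if len(t) > 1:
        dt_obs = np.diff(t)
        if (dt_obs <= 0).any():
            raise ValueError(f"time column is not strictly increasing: {path}")
        dt = 1.0 / sampling_rate if sampling_rate else float(np.median(dt_obs))
        if (dt_obs > 1.5 * dt).any():
            raise ValueError(f"sensor file {path} has gaps larger than 1.5x dt")
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for a single-sample file")
        dt = 1.0 / sampling_rate
    return TriaxialSeries(
        ax=df[cmap["ax"]].to_numpy(dtype=float) * unit_scale,
        ay=df[cmap["ay"]].to_numpy(dtype=float) * unit_scale,
        az=df[cmap["az"]].to_numpy(dtype=float) * unit_scale,
        sample_period=dt,
        start_time=float(t[0]),
    )


def write_sensor_table(series: TriaxialSeries, path: PathLike) -> None:
    """Write a TriaxialSeries as CSV with columns time_s, ax, ay, az."""
    pd.DataFrame(
        {
            "time_s": series.times,
            "ax": series.ax,
            "ay": series.ay,
            "az": series.az,
        }
    ).to_csv(path, index=False)


def read_annotations(
    path: PathLike,
    time_unit: str = "s",
    strict: bool = True,
    min_duration_s: float = 2.0,
    sep: str = "\t",
) -> AnnotationTrack:
    """Read a delimited interval export into an AnnotationTrack.

    Expects columns start, end, label (header optional; the first row is
    treated as a header when its times do not parse as numbers). Labels
    are normalised via the alias table. Out-of-order rows are sorted with
    a warning; overlapping intervals are an error. Intervals shorter than
    ``min_duration_s`` are an error under ``strict`` and a warning
    otherwise.
    """
    if time_unit not in ("s", "ms"):
        raise ValueError("time_unit must be 's' or 'ms'")
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.empty:
        raise ValueError(f"annotation file is empty: {path}")
    if df.shape[1] < 3:
        raise ValueError(f"annotation file needs 3 columns (start, end, label): {path}")
    first = df.iloc[0]
    try:
        float(first[0]), float(first[1])
    except (TypeError, ValueError):
        df = df.iloc[1:]
        if df.empty:
            raise ValueError(f"annotation file has a header but no rows: {path}")
    scale = 1e-3 if time_unit == "ms" else 1.0
    intervals = []
    for _, row in df.iterrows():
        start = float(row[0]) * scale
        end = float(row[1]) * scale
        label = normalize_label(row[2])
        iv = Interval(start, end, label)
        if iv.duration < min_duration_s - 1e-9:
            msg = (
                f"interval {start:.3f}-{end:.3f} ({label}) is shorter than "
                f"{min_duration_s} s"
            )
            if strict:
                raise ValueError(msg)
            warnings.warn(msg)
        intervals.append(iv)
    ordered = sorted(intervals, key=lambda iv: iv.start)
    if ordered != intervals:
        warnings.warn(f"annotation rows out of order in {path}; sorted by start time")
    return AnnotationTrack(ordered)


def write_annotations(
    track: AnnotationTrack, path: PathLike, time_unit: str = "s"
) -> None:
    """Write an AnnotationTrack as a tab-delimited interval file."""
    scale = 1e3 if time_unit == "ms" else 1.0
    with open(path, "w") as fh:
        fh.write("start\tend\tlabel\n")
        for iv in track:
            fh.write(f"{iv.start * scale:.6f}\t{iv.end * scale:.6f}\t{iv.label}\n")


def _snap(t: float, series: TriaxialSeries) -> float:
    """Nearest sample instant on the series grid, ties toward the
    earlier sample."""
    dt = series.sample_period
    x = (t - series.start_time) / dt
    frac = x - np.floor(x)
    idx = np.floor(x) if frac <= 0.5 + 1e-12 else np.ceil(x)
    return series.start_time + float(idx) * dt


def align_annotations(
    track: AnnotationTrack,
    series: TriaxialSeries,
    offset: float = 0.0,
) -> AnnotationTrack:
    """Shift annotation times onto the sensor clock and sample grid.

    ``offset`` is the sensor-clock minus annotation-clock difference,
    derived externally from the sync event, and is added to annotation
    times. Boundaries snap to the nearest sample instant (ties toward
    the earlier sample). Intervals falling wholly outside the recording
    are dropped with a warning; partially-outside intervals are clipped
    to the recording.
    """
    t0, t1 = series.start_time, series.end_time
    aligned = []
    for iv in track:
        start, end = iv.start + offset, iv.end + offset
        if end <= t0 or start >= t1:
            warnings.warn(
                f"interval {iv.start:.3f}-{iv.end:.3f} ({iv.label}) lies "
                "outside the recording; dropped"
            )
            continue
        start = _snap(max(start, t0), series)
        end = _snap(min(end, t1), series)
        if end > start:
            aligned.append(Interval(start, end, iv.label))
    if not aligned:
        raise ValueError("no annotation interval overlaps the recording")
    return AnnotationTrack(aligned)


def _opt(x: Optional[float]) -> object:
    return np.nan if x is None else x


def write_epochs(records: Sequence[EpochRecord], path: PathLike) -> None:
    """Write an epoch table as CSV (full precision round-trip)."""
    rows = []
    for r in records:
        both_a = r.c_a_left is not None and r.c_a_right is not None
        both_j = r.c_j_left is not None and r.c_j_right is not None
        rows.append(
            {
                "subject_id": r.subject_id,
                "window_start_s": r.window_start,
                "window_end_s": r.window_end,
                "gold_label": r.gold_label,
                "c_a_left": _opt(r.c_a_left),
                "c_a_right": _opt(r.c_a_right),
                "c_a_total": r.c_a_total if both_a else np.nan,
                "c_j_left": _opt(r.c_j_left),
                "c_j_right": _opt(r.c_j_right),
                "c_j_total": r.c_j_total if both_j else np.nan,
            }
        )
    pd.DataFrame(rows, columns=EPOCH_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_epochs(path: PathLike) -> list[EpochRecord]:
    """Read an epoch table CSV back into EpochRecord objects."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"epoch table {path} is missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        def val(col):
            v = row[col]
            return None if pd.isna(v) else float(v)

        records.append(
            EpochRecord(
                subject_id=str(row["subject_id"]),
                window_start=float(row["window_start_s"]),
                window_end=float(row["window_end_s"]),
                gold_label=normalize_label(row["gold_label"]),
                c_a_left=val("c_a_left"),
                c_a_right=val("c_a_right"),
                c_j_left=val("c_j_left"),
                c_j_right=val("c_j_right"),
            )
        )
    return records


def write_thresholds(thresholds: ThresholdSet, path: PathLike) -> None:
    """Write a threshold set as JSON with units and provenance metadata."""
    payload = {
        "quantity": thresholds.quantity,
        "placement": thresholds.placement,
        "method": thresholds.method,
        "t_sed_active": thresholds.t_sed_active,
        "t_light_mv": thresholds.t_light_mv,
        "units": thresholds.units,
        "tp_fixed": thresholds.tp_fixed,
        "provenance": {"package": "infant-pa", "version": __version__},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_thresholds(path: PathLike) -> ThresholdSet:
    """Read a threshold JSON file; schema-checked (units required and
    consistent with the quantity)."""
    payload = json.loads(Path(path).read_text())
    required = ["quantity", "placement", "method", "t_sed_active", "t_light_mv", "units"]
    missing = [k for k in required if k not in payload]
    if missing:
        raise ValueError(f"threshold file {path} is missing fields: {missing}")
    ts = ThresholdSet(
        quantity=payload["quantity"],
        placement=payload["placement"],
        method=payload["method"],
        t_sed_active=float(payload["t_sed_active"]),
        t_light_mv=float(payload["t_light_mv"]),
        tp_fixed=None if payload.get("tp_fixed") is None else float(payload["tp_fixed"]),
    )
    if payload["units"] != ts.units:
        raise ValueError(
            f"threshold file units {payload['units']!r} do not match "
            f"quantity {ts.quantity!r} ({ts.units})"
        )
    return ts
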