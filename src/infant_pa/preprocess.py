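"""Raw-signal conditioning: magnitude, gravity removal, leg-length scaling.

The pipeline is orientation-free: it reduces the tri-axial signal to the
Euclidean magnitude a_M, estimates the gravity baseline a_G from static
segments of that magnitude (median fallback when no segment qualifies),
subtracts it to get the gravity-independent magnitude a_IND, and rescales
by leg length so that infants with different leg lengths are comparable.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .defaults import (
    BASELINE_LEG_LENGTH_CM,
    STATIC_RANGE_M_S2,
    STATIC_WINDOW_SAMPLES,
)
from .types import GravityEstimate, ScalarSeries, SubjectMeta, TriaxialSeries


def magnitude(series: TriaxialSeries) -> ScalarSeries:
    """Element-wise Euclidean norm of the three axis components (m/s^2)."""
    values = np.sqrt(series.ax**2 + series.ay**2 + series.az**2)
    return ScalarSeries(values, series.sample_period, "a_M", series.start_time)


def find_static_segments(
    a_m: ScalarSeries,
    window_samples: int = STATIC_WINDOW_SAMPLES,
    range_threshold: float = STATIC_RANGE_M_S2,
) -> list[tuple[int, int]]:
    """Locate still periods of the magnitude signal.

    A length-``window_samples`` window qualifies when its max-minus-min
    range is <= ``range_threshold``; the scan slides one sample at a
    time, and overlapping qualifying windows are merged into maximal
    runs. Returns half-open index ranges (possibly empty).
    """
    v = a_m.values
    if len(v) < window_samples:
        return []
    windows = sliding_window_view(v, window_samples)
    ok = windows.max(axis=1) - windows.min(axis=1) <= range_threshold
    # mark every sample covered by a qualifying window, then extract runs
    covered = np.zeros(len(v), dtype=bool)
    for i in np.flatnonzero(ok):
        covered[i : i + window_samples] = True
    segments: list[tuple[int, int]] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
    for start, end in zip(edges[::2], edges[1::2]):
        segments.append((int(start), int(end)))
    return segments


def gravity_baseline(
    a_m: ScalarSeries,
    window_samples: int = STATIC_WINDOW_SAMPLES,
    range_threshold: float = STATIC_RANGE_M_S2,
) -> GravityEstimate:
    """Estimate the gravity magnitude a_G from the a_M series.

    Uses the mean over all samples inside static segments; when the
    recording has no qualifying static window, falls back to the median
    of the full series.
    """
    segments = find_static_segments(a_m, window_samples, range_threshold)
    if segments:
        pooled = np.concatenate([a_m.values[s:e] for s, e in segments])
        return GravityEstimate(float(pooled.mean()), "static_segments", segments)
    return GravityEstimate(float(np.median(a_m.values)), "median_fallback", [])


def remove_gravity(a_m: ScalarSeries, g: GravityEstimate) -> ScalarSeries:
    """Subtract the gravity baseline: a_IND = a_M - a_G (may go negative)."""
    return a_m.with_values(a_m.values - g.a_g, "a_IND")


def adjust_leg_length(
    a_ind: ScalarSeries,
    meta: SubjectMeta,
    baseline_cm: float = BASELINE_LEG_LENGTH_CM,
    direction: str = "baseline_over_leg",
) -> ScalarSeries:
    """Scale the gravity-independent magnitude by leg length.

    Longer legs produce higher linear acceleration at the ankle for the
    same angular movement, so the default direction divides that effect
    out: a_ADJ = a_IND * (baseline / leg_length). The opposite
    convention is available via ``direction="leg_over_baseline"`` for
    sensitivity analysis.
    """
    if direction == "baseline_over_leg":
        factor = baseline_cm / meta.leg_length_cm
    elif direction == "leg_over_baseline":
        factor = meta.leg_length_cm / baseline_cm
    else:
        raise ValueError(f"unknown adjustment direction: {direction!r}")
    return a_ind.with_values(a_ind.values * factor, "a_ADJ")


def preprocess_series(
    series: TriaxialSeries,
    meta: SubjectMeta,
    baseline_cm: float = BASELINE_LEG_LENGTH_CM,
    window_samples: int = STATIC_WINDOW_SAMPLES,
    range_threshold: float = STATIC_RANGE_M_S2,
) -> tuple[ScalarSeries, GravityEstimate]:
    """Full conditioning chain for one sensor: magnitude -> gravity
    removal -> leg-length adjustment. Returns (a_ADJ, gravity estimate)."""
    a_m = magnitude(series)
    g = gravity_baseline(a_m, window_samples, range_threshold)
    a_ind = remove_gravity(a_m, g)
    return adjust_leg_length(a_ind, meta, baseline_cm), g
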