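"""Cut-point calibration by two-stage grid search.

Two cost families are supported. The true-positive (TP) method equalises
sensitivity across the classes a cut-point separates: the primary stage
minimises |TP_SED - TP_ACTIVE| for the sedentary/active cut, and the
secondary stage drives TP_MV toward the frozen sedentary rate TP_FIXED
attained at the primary optimum. The predicted-activity-proportion (PAP)
method instead matches the share of epochs assigned to each class to the
gold standard's share, minimising the summed absolute relative deviation
of per-class counts (x100).

The printed cost formulas are raw signed differences with no interior
minimum; both costs are minimised as absolute values, which is the
crossing point the verbal description of the search implies. Grids run
from 0 to the maximum observed epoch value in steps of 0.01 m/s
(acceleration) or 0.1 m/s^2 (jerk).

Because the costs are step functions of the candidate, ties over runs of
grid points are the norm, and the tie rule is part of the estimator:
primary-stage ties break to the smallest candidate; secondary-stage ties
break to the largest. The secondary cost's minimal plateau is bounded
above by the smallest MV epoch value, so taking its upper end keeps the
light band maximal and, when the classes are perfectly separable (the
sedentary TP rate frozen at 100 makes every candidate up to the smallest
MV value cost-free), still yields a cut-point that separates light from
MV rather than collapsing onto the sedentary/active cut.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .defaults import GRID_STEP
from .types import (
    LIGHT,
    MV,
    SED,
    EpochRecord,
    OptimizationResult,
    ThresholdSet,
)
from .evaluate import confusion


def _values_labels(
    epochs: Sequence[EpochRecord], quantity: str, placement: str
) -> tuple[np.ndarray, np.ndarray]:
    values = np.array([r.total(quantity, placement) for r in epochs])
    labels = np.array([r.gold_label for r in epochs])
    return values, labels


def _tp_rates_primary(
    values: np.ndarray, labels: np.ndarray, candidate: float
) -> tuple[float, float]:
    sed = labels == SED
    if sed.sum() == 0 or (~sed).sum() == 0:
        raise ValueError("primary cost needs both SED and active gold epochs")
    tp_sed = float((values[sed] < candidate).mean() * 100.0)
    tp_active = float((values[~sed] >= candidate).mean() * 100.0)
    return tp_sed, tp_active


def cost_tp_primary(
    epochs: Sequence[EpochRecord], quantity: str, placement: str, candidate: float
) -> float:
    """|TP_SED - TP_ACTIVE| at a candidate sedentary/active cut-point."""
    values, labels = _values_labels(epochs, quantity, placement)
    tp_sed, tp_active = _tp_rates_primary(values, labels, candidate)
    return abs(tp_sed - tp_active)


def cost_tp_secondary(
    epochs: Sequence[EpochRecord],
    quantity: str,
    placement: str,
    t_primary: float,
    candidate: float,
    tp_fixed: float,
) -> float:
    """|TP_MV - TP_FIXED| at a candidate light/MV cut-point.

    TP_MV is computed from the full three-class assignment under
    (t_primary, candidate); TP_FIXED is the sedentary TP rate frozen at
    the primary optimum.
    """
    if candidate < t_primary:
        raise ValueError("light/MV candidate must be >= the sedentary/active cut")
    values, labels = _values_labels(epochs, quantity, placement)
    mv = labels == MV
    if mv.sum() == 0:
        raise ValueError("secondary cost needs MV gold epochs")
    tp_mv = float((values[mv] >= candidate).mean() * 100.0)
    return abs(tp_mv - tp_fixed)


def cost_pap_primary(
    epochs: Sequence[EpochRecord], quantity: str, placement: str, candidate: float
) -> float:
    """Summed absolute relative deviation (x100) of predicted vs. gold
    sedentary and active epoch counts."""
    values, labels = _values_labels(epochs, quantity, placement)
    gold_sed = int((labels == SED).sum())
    gold_active = int((labels != SED).sum())
    if gold_sed == 0 or gold_active == 0:
        raise ValueError("primary cost needs both SED and active gold epochs")
    pred_sed = int((values < candidate).sum())
    pred_active = len(values) - pred_sed
    d_sed = (gold_sed - pred_sed) / gold_sed
    d_active = (gold_active - pred_active) / gold_active
    return abs(d_sed) * 100.0 + abs(d_active) * 100.0


def cost_pap_secondary(
    epochs: Sequence[EpochRecord],
    quantity: str,
    placement: str,
    t_primary: float,
    candidate: float,
) -> float:
    """Summed absolute relative deviation (x100) of predicted vs. gold
    light and MV counts, under the full three-class rule."""
    if candidate < t_primary:
        raise ValueError("light/MV candidate must be >= the sedentary/active cut")
    values, labels = _values_labels(epochs, quantity, placement)
    gold_light = int((labels == LIGHT).sum())
    gold_mv = int((labels == MV).sum())
    if gold_light == 0 or gold_mv == 0:
        raise ValueError("secondary cost needs both LIGHT and MV gold epochs")
    pred_light = int(((values >= t_primary) & (values < candidate)).sum())
    pred_mv = int((values >= candidate).sum())
    d_light = (gold_light - pred_light) / gold_light
    d_mv = (gold_mv - pred_mv) / gold_mv
    return abs(d_light) * 100.0 + abs(d_mv) * 100.0


def _candidate_grid(
    values: np.ndarray, quantity: str, grid: Optional[tuple[float, float, float]]
) -> np.ndarray:
    if grid is None:
        step = GRID_STEP[quantity]
        lo, hi = 0.0, float(values.max())
    else:
        lo, hi, step = grid
    if step <= 0 or hi < lo:
        raise ValueError(f"invalid grid: ({lo}, {hi}, {step})")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    candidates = lo + step * np.arange(n)
    if len(candidates) == 0:
        raise ValueError("empty candidate grid")
    return candidates


def _primary_costs(
    values: np.ndarray, labels: np.ndarray, candidates: np.ndarray, method: str
) -> np.ndarray:
    """Vectorised primary cost over all candidates via sorted-count
    lookups (prediction rule: value < t -> SED)."""
    sed_vals = np.sort(values[labels == SED])
    act_vals = np.sort(values[labels != SED])
    n_sed, n_act = len(sed_vals), len(act_vals)
    if n_sed == 0 or n_act == 0:
        raise ValueError("degenerate label distribution: need SED and active epochs")
    sed_below = np.searchsorted(sed_vals, candidates, side="left")
    act_below = np.searchsorted(act_vals, candidates, side="left")
    if method == "TP":
        tp_sed = sed_below / n_sed * 100.0
        tp_active = (n_act - act_below) / n_act * 100.0
        return np.abs(tp_sed - tp_active)
    pred_sed = sed_below + act_below
    pred_active = (n_sed + n_act) - pred_sed
    d_sed = (n_sed - pred_sed) / n_sed
    d_active = (n_act - pred_active) / n_act
    return (np.abs(d_sed) + np.abs(d_active)) * 100.0


def _secondary_costs(
    values: np.ndarray,
    labels: np.ndarray,
    t_primary: float,
    candidates: np.ndarray,
    method: str,
    tp_fixed: Optional[float],
) -> np.ndarray:
    light_vals = np.sort(values[labels == LIGHT])
    mv_vals = np.sort(values[labels == MV])
    all_vals = np.sort(values)
    n_light, n_mv = len(light_vals), len(mv_vals)
    if n_mv == 0 or (method == "PAP" and n_light == 0):
        raise ValueError(
            "degenerate label distribution: secondary stage needs LIGHT and MV epochs"
        )
    mv_below = np.searchsorted(mv_vals, candidates, side="left")
    if method == "TP":
        tp_mv = (n_mv - mv_below) / n_mv * 100.0
        return np.abs(tp_mv - tp_fixed)
    all_below_t2 = np.searchsorted(all_vals, candidates, side="left")
    all_below_t1 = np.searchsorted(all_vals, t_primary, side="left")
    pred_light = all_below_t2 - all_below_t1
    pred_mv = len(all_vals) - all_below_t2
    d_light = (n_light - pred_light) / n_light
    d_mv = (n_mv - pred_mv) / n_mv
    return (np.abs(d_light) + np.abs(d_mv)) * 100.0


def fit_thresholds(
    epochs: Sequence[EpochRecord],
    quantity: str,
    placement: str,
    method: str,
    grid: Optional[tuple[float, float, float]] = None,
) -> OptimizationResult:
    """Two-stage cut-point calibration on pooled labelled epochs.

    The primary stage scans the full grid for the sedentary/active
    cut-point; the secondary stage scans candidates at or above it for
    the light/MV cut-point. For the TP method the sedentary TP rate at
    the primary optimum is frozen as TP_FIXED before the secondary scan.
    Primary ties break to the smallest candidate, secondary ties to the
    largest (see module docstring). All subjects' epochs are pooled
    unweighted.

    ``grid`` is (min, max, step); by default 0 to the maximum observed
    combined value in quantity-specific steps.
    """
    if method not in ("TP", "PAP"):
        raise ValueError(f"unknown method: {method!r}")
    if len(epochs) == 0:
        raise ValueError("no epochs to fit")
    values, labels = _values_labels(epochs, quantity, placement)
    present = set(labels)
    if not {SED, LIGHT, MV} <= present:
        raise ValueError(
            "degenerate label distribution: all three gold classes are "
            f"required for a two-stage fit, got {sorted(present)}"
        )
    candidates = _candidate_grid(values, quantity, grid)

    primary_cost = _primary_costs(values, labels, candidates, method)
    i1 = int(np.argmin(primary_cost))  # argmin returns the first (smallest) tie
    t1 = float(candidates[i1])

    tp_fixed = None
    if method == "TP":
        tp_fixed = float((values[labels == SED] < t1).mean() * 100.0)

    sec_candidates = candidates[candidates >= t1]
    sec_cost = _secondary_costs(values, labels, t1, sec_candidates, method, tp_fixed)
    i2 = len(sec_cost) - 1 - int(np.argmin(sec_cost[::-1]))  # largest tie
    t2 = float(sec_candidates[i2])

    thresholds = ThresholdSet(quantity, placement, method, t1, t2, tp_fixed)
    predicted = np.where(values < t1, SED, np.where(values < t2, LIGHT, MV))
    final_confusion = confusion(list(labels), list(predicted), "secondary")
    return OptimizationResult(
        thresholds=thresholds,
        primary_curve=np.column_stack([candidates, primary_cost]),
        secondary_curve=np.column_stack([sec_candidates, sec_cost]),
        tp_fixed=tp_fixed,
        confusion=final_confusion,
    )
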