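"""Core domain containers shared across the pipeline modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .defaults import QUANTITY_UNITS

SED = "SED"
LIGHT = "LIGHT"
MV = "MV"
ACTIVE = "ACTIVE"

#: Three-class (secondary stage) labels, in increasing intensity order.
LABELS3 = (SED, LIGHT, MV)
#: Two-class (primary stage) labels: sedentary vs. active (light or MV).
LABELS2 = (SED, ACTIVE)

QUANTITIES = ("acceleration", "jerk")
PLACEMENTS = ("both", "left", "right")
METHODS = ("TP", "PAP")


def to_primary(label: str) -> str:
    """Collapse a three-class label to the sedentary/active dichotomy."""
    if label == SED:
        return SED
    if label in (LIGHT, MV, ACTIVE):
        return ACTIVE
    raise ValueError(f"unknown activity label: {label!r}")


@dataclass
class TriaxialSeries:
    """Uniformly sampled tri-axial accelerometer output for one sensor.

    Axis components are in m/s^2; ``sample_period`` is the sampling
    interval in seconds; ``start_time`` places sample 0 on the session
    clock.
    """

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_period: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise ValueError("axis sequences must have equal length")
        if len(self.ax) < 1:
            raise ValueError("series must contain at least one sample")
        if not self.sample_period > 0:
            raise ValueError("sample_period must be positive")

    def __len__(self) -> int:
        return len(self.ax)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) * self.sample_period

    @property
    def end_time(self) -> float:
        """Time just past the last sample (start of the would-be next one)."""
        return self.start_time + len(self) * self.sample_period


@dataclass(frozen=True)
class Interval:
    """One gold-standard activity bout: [start, end) seconds, one label."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval start {self.start} must precede end {self.end}")
        if self.label not in LABELS3:
            raise ValueError(f"unknown activity label: {self.label!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class AnnotationTrack:
    """Ordered, non-overlapping gold-standard intervals for one session."""

    intervals: list[Interval]

    def __post_init__(self) -> None:
        ivs = list(self.intervals)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError(
                    f"intervals overlap or are unsorted: {a} followed by {b}"
                )
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def total_duration(self) -> float:
        return sum(iv.duration for iv in self.intervals)


@dataclass
class SubjectMeta:
    """Per-infant metadata needed by the pipeline (leg length drives Eq.-style
    amplitude normalisation; group/age are carried for bookkeeping)."""

    subject_id: str
    leg_length_cm: float
    group: str = "TD"
    age_days: int = 0

    def __post_init__(self) -> None:
        if not self.leg_length_cm > 0:
            raise ValueError("leg_length_cm must be positive")
        if self.group not in ("TD", "AR"):
            raise ValueError("group must be 'TD' or 'AR'")


@dataclass
class ScalarSeries:
    """A scalar time series derived from a TriaxialSeries.

    ``role`` tags the processing stage: ``a_M`` (magnitude), ``a_IND``
    (gravity-independent), ``a_ADJ`` (leg-length adjusted) in m/s^2, or
    ``jerk`` in m/s^3.
    """

    values: np.ndarray
    sample_period: float
    role: str = "a_M"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 1:
            raise ValueError("series must contain at least one sample")
        if not self.sample_period > 0:
            raise ValueError("sample_period must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def end_time(self) -> float:
        return self.start_time + len(self) * self.sample_period

    def with_values(self, values: np.ndarray, role: str) -> "ScalarSeries":
        return ScalarSeries(values, self.sample_period, role, self.start_time)


@dataclass
class GravityEstimate:
    """Gravity baseline a_G and how it was obtained.

    ``static_segments`` holds maximal merged runs of static samples as
    half-open index ranges; empty when the median fallback was used.
    """

    a_g: float
    source: str  # "static_segments" | "median_fallback"
    static_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.source not in ("static_segments", "median_fallback"):
            raise ValueError(f"unknown gravity source: {self.source!r}")


@dataclass
class EpochRecord:
    """One valid 2-s window: gold label plus per-leg epoch areas.

    ``c_a_*`` are acceleration areas (m/s), ``c_j_*`` jerk areas (m/s^2).
    A missing leg is None; totals for any placement come from ``total``.
    """

    subject_id: str
    window_start: float
    window_end: float
    gold_label: str
    c_a_left: Optional[float] = None
    c_a_right: Optional[float] = None
    c_j_left: Optional[float] = None
    c_j_right: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gold_label not in LABELS3:
            raise ValueError(f"unknown gold label: {self.gold_label!r}")

    def total(self, quantity: str, placement: str) -> float:
        """Combined derived quantity for a sensor placement.

        ``both`` sums the legs; ``left``/``right`` pass the single leg
        through. Raises if a required leg is missing.
        """
        if quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity: {quantity!r}")
        prefix = "c_a" if quantity == "acceleration" else "c_j"
        left = getattr(self, f"{prefix}_left")
        right = getattr(self, f"{prefix}_right")
        if placement == "both":
            if left is None or right is None:
                raise ValueError("placement 'both' requires both leg areas")
            return left + right
        if placement == "left":
            if left is None:
                raise ValueError("left-leg area missing")
            return left
        if placement == "right":
            if right is None:
                raise ValueError("right-leg area missing")
            return right
        raise ValueError(f"unknown placement: {placement!r}")

    @property
    def c_a_total(self) -> float:
        return self.total("acceleration", "both")

    @property
    def c_j_total(self) -> float:
        return self.total("jerk", "both")


@dataclass
class ThresholdSet:
    """A calibrated pair of intensity cut-points for one configuration.

    ``t_sed_active`` separates sedentary from active epochs and
    ``t_light_mv`` separates light from moderate-to-vigorous, on the
    scale of ``quantity`` (m/s for acceleration area, m/s^2 for jerk
    area). ``tp_fixed`` is the frozen sedentary true-positive rate used
    by the TP method's secondary stage.
    """

    quantity: str
    placement: str
    method: str
    t_sed_active: float
    t_light_mv: float
    tp_fixed: Optional[float] = None

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity: {self.quantity!r}")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"unknown placement: {self.placement!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method: {self.method!r}")
        if not 0 < self.t_sed_active <= self.t_light_mv:
            raise ValueError(
                "cut-points must satisfy 0 < t_sed_active <= t_light_mv, got "
                f"{self.t_sed_active} and {self.t_light_mv}"
            )

    @property
    def units(self) -> str:
        return QUANTITY_UNITS[self.quantity]


@dataclass
class ConfusionCounts:
    """Gold-by-predicted cross-tabulation for one evaluation stage."""

    stage: str  # "primary" | "secondary"
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.stage not in ("primary", "secondary"):
            raise ValueError(f"unknown stage: {self.stage!r}")
        k = len(self.classes)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k} for stage {self.stage}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def classes(self) -> tuple[str, ...]:
        return LABELS2 if self.stage == "primary" else LABELS3

    @classmethod
    def from_cells(cls, stage: str, cells: dict[str, int]) -> "ConfusionCounts":
        """Build counts from cell names like ``SED_ACTIVE`` or ``MV_LIGHT``
        (gold class then predicted class)."""
        classes = LABELS2 if stage == "primary" else LABELS3
        k = len(classes)
        counts = np.zeros((k, k), dtype=int)
        index = {c: i for i, c in enumerate(classes)}
        for name, value in cells.items():
            gold, pred = name.split("_", 1)
            counts[index[gold], index[pred]] = value
        return cls(stage, counts)

    def cell(self, gold: str, pred: str) -> int:
        classes = self.classes
        return int(self.counts[classes.index(gold), classes.index(pred)])

    def row_total(self, gold: str) -> int:
        return int(self.counts[self.classes.index(gold)].sum())

    def col_total(self, pred: str) -> int:
        return int(self.counts[:, self.classes.index(pred)].sum())

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvaluationReport:
    """Per-class rates (percent) for one stage, plus the two overall
    ratings: MTPR (minimum true-positive rate over sedentary and the top
    active class) and PMR (100 minus total absolute deviation between
    gold and predicted activity proportions)."""

    stage: str
    tp_rate: dict[str, float]
    tn_rate: dict[str, float]
    pap: dict[str, float]
    pap_gold: dict[str, float]
    mtpr: Optional[float] = None
    pmr: Optional[float] = None


@dataclass
class OptimizationResult:
    """Outcome of the two-stage cut-point grid search."""

    thresholds: ThresholdSet
    primary_curve: np.ndarray  # (candidate, cost) rows
    secondary_curve: np.ndarray
    tp_fixed: Optional[float] = None
    confusion: Optional[ConfusionCounts] = None
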