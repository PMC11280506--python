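"""Seeded synthetic two-leg accelerometer sessions with gold annotations.

The generator emulates the statistical structure the pipeline assumes: a
20 Hz tri-axial signal whose magnitude is gravity plus a bout-structured
movement component, a guaranteed static prefix for gravity estimation,
and intensity classes that differ by movement amplitude. Movement within
a bout is a sinusoid burst (random 1-4 Hz frequency and phase per leg,
below the Nyquist limit at 20 Hz) directed along a slowly rotating
gravity unit vector, so the magnitude sees gravity + movement directly;
white sensor noise is added per axis. Longer legs scale the movement
amplitude up by leg_length/baseline, the physical effect the leg-length
adjustment removes.

Default condition choices: class proportions (0.406, 0.186, 0.408) match
the gold-standard validation proportions of the calibration study;
session length defaults to the study's 5.73 min mean; amplitude bands
are set so both-leg epoch areas straddle the published 1.0 / 2.6 m/s
acceleration cut-points with mild class overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .defaults import BASELINE_LEG_LENGTH_CM, GRAVITY_M_S2, SAMPLING_RATE_HZ
from .types import (
    LABELS2,
    LABELS3,
    SED,
    AnnotationTrack,
    ConfusionCounts,
    Interval,
    SubjectMeta,
    TriaxialSeries,
)


@dataclass
class SimulationConfig:
    """Generating conditions for one synthetic session."""

    sampling_rate: float = SAMPLING_RATE_HZ
    session_length: float = 343.8  # seconds (5.73 min study mean)
    bout_length_range: tuple[float, float] = (2.0, 10.0)
    class_proportions: tuple[float, float, float] = (0.406, 0.186, 0.408)
    #: Per-class movement amplitude bands (m/s^2) at baseline leg length,
    #: ordered SED < LIGHT < MV.
    amplitude_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "SED": (0.02, 0.40),
            "LIGHT": (0.35, 1.00),
            "MV": (0.90, 2.00),
        }
    )
    freq_range_hz: tuple[float, float] = (1.0, 4.0)
    gravity_magnitude: float = GRAVITY_M_S2
    orientation_drift_scale: float = 1.0  # multiplies a 0.01 rad/step walk
    noise_sd: float = 0.01  # m/s^2 per axis
    static_prefix: float = 2.0  # seconds of guaranteed stillness (SED)
    leg_length_cm: float = BASELINE_LEG_LENGTH_CM
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.static_prefix < 0.5:
            raise ValueError("static_prefix must be >= 0.5 s so a static segment exists")
        if self.bout_length_range[0] < 2.0:
            raise ValueError("bout lengths must be >= 2 s")
        if self.bout_length_range[0] > self.session_length - self.static_prefix:
            raise ValueError("minimum bout length exceeds available session time")
        lo = [self.amplitude_bands[c][0] for c in LABELS3]
        hi = [self.amplitude_bands[c][1] for c in LABELS3]
        if not (lo[0] <= lo[1] <= lo[2] and hi[0] <= hi[1] <= hi[2]):
            raise ValueError("amplitude bands must be ordered SED <= LIGHT <= MV")


def _rotating_unit_vectors(
    rng: np.random.Generator, n: int, drift_scale: float
) -> np.ndarray:
    """Slow random-walk rotation of an initial unit vector, n x 3."""
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    out = np.empty((n, 3))
    step = 0.01 * drift_scale
    for i in range(n):
        out[i] = u
        if step > 0:
            u = u + rng.normal(scale=step, size=3)
            u /= np.linalg.norm(u)
    return out


def _draw_bouts(
    rng: np.random.Generator, config: SimulationConfig
) -> list[tuple[float, float, str]]:
    """Bout schedule (start, duration, label) covering the session after
    the static prefix; bout boundaries land on the sample grid."""
    dt = 1.0 / config.sampling_rate
    t = config.static_prefix
    lo, hi = config.bout_length_range
    labels = list(LABELS3)
    p = np.asarray(config.class_proportions)
    bouts = []
    while t < config.session_length - lo:
        length = rng.uniform(lo, hi)
        length = max(lo, round(length / dt) * dt)
        length = min(length, config.session_length - t)
        label = labels[rng.choice(3, p=p)]
        bouts.append((t, length, label))
        t += length
    return bouts


def _leg_movement(
    rng: np.random.Generator,
    config: SimulationConfig,
    bouts: Sequence[tuple[float, float, str]],
    n: int,
) -> np.ndarray:
    """Scalar movement component for one leg along the gravity axis."""
    dt = 1.0 / config.sampling_rate
    times = np.arange(n) * dt
    m = np.zeros(n)
    amp_scale = config.leg_length_cm / BASELINE_LEG_LENGTH_CM
    for start, length, label in bouts:
        lo, hi = config.amplitude_bands[label]
        amp = rng.uniform(lo, hi) * amp_scale
        freq = rng.uniform(*config.freq_range_hz)
        phase = rng.uniform(0, 2 * np.pi)
        i0 = int(round(start / dt))
        i1 = min(n, int(round((start + length) / dt)))
        m[i0:i1] = amp * np.sin(2 * np.pi * freq * times[i0:i1] + phase)
    return m


def generate_session(
    config: SimulationConfig,
) -> tuple[TriaxialSeries, TriaxialSeries, AnnotationTrack, SubjectMeta, dict]:
    """Generate one synthetic two-leg session.

    Returns (left, right, annotation track, subject metadata, truth).
    Deterministic for a given config seed. The truth dict records the
    bout schedule, the gravity magnitude, and per-class expected
    both-leg acceleration-area bands (for a rectified sinusoid of
    amplitude A the 2-s epoch area per leg is ~ 4A/pi, so the both-leg
    band for a class with amplitudes [lo, hi] is ~ [8*lo/pi, 8*hi/pi]
    after leg-length adjustment).
    """
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sampling_rate
    n = int(round(config.session_length / dt))
    bouts = _draw_bouts(rng, config)
    if not bouts:
        raise ValueError("infeasible config: no bout fits in the session")

    legs = []
    for _ in ("left", "right"):
        u = _rotating_unit_vectors(rng, n, config.orientation_drift_scale)
        m = _leg_movement(rng, config, bouts, n)
        vec = (config.gravity_magnitude + m)[:, None] * u
        vec = vec + rng.normal(scale=config.noise_sd, size=(n, 3))
        legs.append(
            TriaxialSeries(vec[:, 0], vec[:, 1], vec[:, 2], dt, start_time=0.0)
        )

    intervals = [Interval(0.0, config.static_prefix, SED)] if config.static_prefix else []
    for start, length, label in bouts:
        intervals.append(Interval(start, start + length, label))
    track = AnnotationTrack(intervals)

    meta = SubjectMeta(
        subject_id=f"sim{config.seed}",
        leg_length_cm=config.leg_length_cm,
        group="TD",
        age_days=120,
    )
    truth = {
        "bouts": bouts,
        "gravity_magnitude": config.gravity_magnitude,
        "amplitude_bands": dict(config.amplitude_bands),
        "expected_c_a_band_both": {
            c: (8 * lo / np.pi, 8 * hi / np.pi)
            for c, (lo, hi) in config.amplitude_bands.items()
        },
    }
    return legs[0], legs[1], track, meta, truth


def generate_confusion_fixture(
    stage: str, cell_counts: dict[str, int], seed: int = 0
) -> tuple[list[str], list[str]]:
    """Label-list pair whose cross-tabulation equals ``cell_counts``.

    ``cell_counts`` uses gold_predicted cell names (e.g. ``SED_ACTIVE``,
    ``MV_LIGHT``); the paired lists are shuffled by ``seed``.
    """
    counts = ConfusionCounts.from_cells(stage, cell_counts)
    gold, predicted = [], []
    for g in counts.classes:
        for p in counts.classes:
            k = counts.cell(g, p)
            gold.extend([g] * k)
            predicted.extend([p] * k)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(gold))
    return [gold[i] for i in order], [predicted[i] for i in order]
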