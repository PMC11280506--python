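# Methods

## Signal model and assumptions

The pipeline assumes a uniformly sampled (default 20 Hz) tri-axial
accelerometer on each ankle, measuring in m/s², and a gold-standard track
of non-overlapping activity intervals (sedentary / light / MV) with
boundaries known to millisecond precision on a clock that can be mapped
to the sensor clock by a single constant offset (from a sync event; the
offset is an input, not estimated here).

The reduction to the magnitude `a_M` makes the pipeline orientation-free:
no attitude estimation is performed, and gravity is removed as a scalar
baseline `a_G` rather than as a rotating vector. This is adequate when
movements are short relative to orientation changes, which holds for
supine infants; it underestimates movement that exactly opposes gravity.
`a_G` is estimated per sensor per session (static segments, with a
median-of-series fallback for recordings that are never still).

Both epoch areas rectify the integrand (`Σ|·|Δt`). Without rectification
the gravity-independent magnitude, which oscillates around zero during
movement, would largely cancel over an epoch; rectified areas are also
what classic actigraphy counts compute. Signed integration remains
available (`rectify=False`) for sensitivity analysis. Integration is a
left-Riemann sum, not trapezoidal, matching the definition of the epoch
features as scaled sample sums.

Jerk is the backward finite difference of `a_ADJ` computed once on the
continuous recording; windows therefore use the sample preceding their
first sample, and only the recording's very first jerk sample is defined
as 0. The derived quantities and their units: acceleration area `c_A`
in m/s (total speed change), jerk area `c_J` in m/s² (total acceleration
change).

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| sampling rate | 20 | Hz | sensor output rate; epoch windows are 40 samples |
| epoch length | 2.0 | s | minimum gold-standard interval length; windows tile intervals from their start, sub-window tails discarded |
| static window | 10 | samples | 0.5 s stillness test for gravity estimation |
| static range bound | 0.1 | m/s² | max−min of `a_M` within a qualifying window (inclusive) |
| baseline leg length | 26.5 | cm | median rump–sole length of 3–5-month-old infants; `a_ADJ = a_IND × 26.5/leg` |
| grid step | 0.01 / 0.1 | m/s, m/s² | cut-point search resolution for acceleration / jerk areas |

The leg-length adjustment direction (divide by leg length) follows from
its purpose — a longer leg yields higher linear acceleration for the
same angular movement, and the adjustment removes that effect; the
opposite convention is available as an argument.

## Cut-point search: numerical choices

Both calibration costs are minimised as absolute values: the raw signed
differences (`TP_SED − TP_ACTIVE`; signed relative count deviations)
cross zero at the intended operating point and have no interior minimum,
so the absolute value is what "adjust until optimal" means operationally.

Costs are step functions of the candidate (they change only when the
candidate crosses an observed epoch value), so minimal-cost plateaus
spanning many grid points are the norm and the tie rule is part of the
estimator:

- primary stage: smallest candidate attaining the minimal cost
  (deterministic, reproducible, lands just above the critical observed
  value);
- secondary stage: largest such candidate. The secondary plateau is
  bounded above by the smallest MV epoch value; taking its upper end
  keeps the light band maximal, and in the perfectly separable limit —
  where `TP_FIXED` freezes at 100 and every candidate from the primary
  cut-point up to the smallest MV value has zero cost — it still yields
  a cut-point that separates light from MV instead of collapsing onto
  the sedentary/active cut. With this rule both methods recover
  identical separating cut-points (within one grid step) on disjoint
  class supports.

The secondary search is constrained to candidates at or above the
primary cut-point, so `t₁ ≤ t₂` always. The grid runs from 0 to the
maximum observed epoch value. Degenerate inputs (a missing gold class,
an empty grid, single-class annotation tracks) raise errors rather than
returning extrapolated cut-points. Classification is left-closed: a
value exactly at a cut-point takes the higher class.

Evaluation rates are computed at full precision and rounded (1 decimal)
only for display; evaluation always recomputes predictions from the
cut-points, never reusing optimizer internals, since validation uses
held-out subjects. Epochs are pooled across subjects without weighting.

## Synthetic data: what it emulates, and what it does not

`generate_session` produces two-leg tri-axial sessions with the
structure the pipeline relies on: a gravity vector of constant magnitude
with slow orientation drift, a guaranteed static prefix (default 2 s), a
bout schedule (bouts ≥ 2 s) with class-dependent movement amplitude, and
per-axis white sensor noise. Movement is a per-bout sinusoid burst
(random 1–4 Hz frequency and phase per leg) directed along the gravity
axis, so the magnitude sees gravity + movement directly and epoch areas
are analytically predictable (a rectified sinusoid of amplitude A gives
a per-leg 2-s area of ≈ 4A/π). Movement amplitude scales with
leg length / 26.5 cm, the physical effect the adjustment step removes.

Defaults are the study conditions: class proportions
(0.406, 0.186, 0.408) equal the gold-standard validation proportions;
session length defaults to the 5.73 min study mean; amplitude bands
(SED 0.02–0.40, LIGHT 0.35–1.00, MV 0.90–2.00 m/s² at baseline leg
length) were chosen once so that both-leg acceleration areas straddle
the published 1.0 / 2.6 m/s cut-points with mild class overlap.

What the generator does **not** emulate: arm/head movement invisible to
ankle sensors (the dominant source of light/MV confusion in real data),
caregiver background motion, non-sinusoidal kick kinematics, and
annotation/sensor misalignment beyond a constant offset. Passing
recovery tests on this generator therefore demonstrates correctness of
the estimation machinery — not that real infant classes are separable;
on real data the published validation sensitivities are in the 65–80%
range precisely because of that overlap.

## Acceptance run design

`scripts/acceptance.py` mirrors the study design at its natural size:
ten synthetic subjects with the study's leg lengths and session lengths
(2.71–8.45 min), an 8/2 train/validation split holding out one
typically-developing and one at-risk subject (the study does not name
the held-out pair; the last of each group is used), four
quantity × method fits on both-leg epochs, and held-out MTPR/PMR. The
whole run takes a few seconds; every random draw derives from `--seed`.

## Known limitations

- Scalar gravity removal ignores orientation; fast posture changes leak
  into `a_IND`.
- The magnitude-based features cannot distinguish which limb (or the
  trunk) moved; single-leg placements see systematically smaller areas,
  which is why published single-leg cut-points are roughly half the
  both-leg ones.
- The annotation reader supports the plain tab-separated interval export
  family; proprietary binary sensor formats are out of scope.
- Cut-points are population-specific: values calibrated for
  pre-ambulatory infants do not transfer to other populations without
  re-validation.
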