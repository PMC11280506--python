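# infant-pa

Physical-activity intensity of **pre-ambulatory infants** from ankle-worn
tri-axial accelerometers.

Accelerometer cut-points for sedentary / light / moderate-to-vigorous (MV)
activity exist for ambulatory children but not for infants, whose activity
is dominated by limb movements in supine. This package implements a complete
calibration-and-classification pipeline for that population: it turns raw
20 Hz ankle accelerometer signals into epoch-level "activity count"
features, calibrates intensity cut-points against gold-standard video-coded
activity intervals, evaluates classifications, and ships the published
cut-points for immediate use. It is aimed at researchers in infant motor
development and physical-activity measurement.

## Model

For each sensor, at each sample `i`:

1. magnitude: `a_M,i = sqrt(a_x,i² + a_y,i² + a_z,i²)`
2. gravity removal: `a_IND,i = a_M,i − a_G`, where the gravity baseline
   `a_G` is the mean of `a_M` over *static segments* (10-sample windows,
   0.5 s at 20 Hz, with max−min ≤ 0.1 m/s²; merged into maximal runs), or
   the median of `a_M` when no window qualifies
3. leg-length adjustment: `a_ADJ,i = a_IND,i × (26.5 cm / leg length)`,
   removing the higher linear acceleration a longer leg produces for the
   same angular movement
4. epoch areas over non-overlapping 2-s windows (40 samples) that start at
   the start of each gold-standard interval and lie wholly inside it:
   - acceleration area `c_A = Σ |a_ADJ,i| Δt` (m/s) — the analogue of
     classic actigraphy activity counts
   - jerk area `c_J = Σ |j_i| Δt` (m/s²), with `j_i = (a_ADJ,i − a_ADJ,i−1)/Δt`
5. leg combination: `c_TOTAL = c_LEFT + c_RIGHT` (or a single leg)

An epoch is classified by two cut-points: `c < t₁ → SED`,
`t₁ ≤ c < t₂ → LIGHT`, `c ≥ t₂ → MV`. Cut-points are calibrated by grid
search with one of two costs:

- **TP** (true-positive-rate matching): primary stage minimises
  `|TP_SED − TP_ACTIVE|`; the secondary stage freezes `TP_FIXED = TP_SED`
  at the primary optimum and minimises `|TP_MV − TP_FIXED|`.
- **PAP** (predicted-activity-proportion matching): each stage minimises
  the summed absolute relative deviation (×100) between predicted and
  gold per-class epoch counts.

Evaluation reports per-class sensitivity (TP rate), specificity (TN rate)
and predicted activity proportion (PAP), plus two overall ratings:
`MTPR = min(TP_SED, TP_MV)` (primary stage: `min(TP_SED, TP_ACTIVE)`) and
`PMR = 100 − Σ_classes |PAP_gold − PAP_predicted|`.

## Worked example

A seeded synthetic session stands in for a real recording (no public
dataset exists for this population):

```sh
$ infant-pa simulate --out-dir demo --seed 7 --session-length 300
wrote session (6000 samples, 52 intervals) to demo

$ infant-pa features --left demo/left.csv --right demo/right.csv \
    --annotations demo/annotations.tsv --leg-length-cm 26.5 \
    --subject-id demo --out demo/epochs.csv
wrote 128 epochs to demo/epochs.csv

$ infant-pa fit --epochs demo/epochs.csv --quantity acceleration \
    --placement both --method PAP --out demo/thresholds.json
acceleration/both/PAP: sedentary/active 0.96 m/s, light/MV 2.35 m/s

$ infant-pa evaluate --epochs demo/epochs.csv \
    --thresholds demo/thresholds.json --stage secondary
stage: secondary
metric                             SED     LIGHT        MV
true positive rate (%)            98.2      95.0     100.0
true negative rate (%)            98.6      99.1     100.0
predicted proportion (%)          44.5      15.6      39.8
gold proportion (%)               44.5      15.6      39.8
MTPR (%)                          98.2
PMR (%)                          100.0
```

The 300-s session yields 128 valid 2-s epochs (sub-2-s interval tails are
discarded). The PAP fit places the sedentary/active cut-point at 0.96 m/s
and the light/MV cut-point at 2.35 m/s of both-leg acceleration area; at
those cut-points the predicted class proportions match the gold standard
exactly (PMR 100.0) and the worst per-class sensitivity is 98.2%
(in-sample, on cleanly separated synthetic classes — real infant data
overlap far more).

The published cut-points are one flag away — e.g. the recommended
typical-use configuration (both-leg acceleration area, PAP method: 1.00
and 2.60 m/s):

```sh
$ infant-pa classify --epochs demo/epochs.csv --published
SED: 46.1% of epochs
LIGHT: 18.0% of epochs
MV: 35.9% of epochs
```

Everything the CLI does is also a library call (`infant_pa.generate_session`,
`infant_pa.fit_thresholds`, `infant_pa.evaluate_epochs`, ...).

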