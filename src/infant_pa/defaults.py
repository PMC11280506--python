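"""Study-default constants for the infant activity-intensity pipeline.

All defaults mirror the calibration protocol: 20 Hz ankle accelerometers,
2-s analysis epochs, static-segment gravity estimation, and leg-length
normalisation to a 26.5 cm baseline (median rump-sole length of 3-5
month-old infants).
"""

#: Sensor sampling rate (Hz).
SAMPLING_RATE_HZ: float = 20.0

#: Epoch (analysis window) length in seconds; the minimum video-coding
#: epoch length, so each sensor window sits inside one rated interval.
EPOCH_S: float = 2.0

#: Static-segment detection: window length in samples (0.5 s at 20 Hz).
STATIC_WINDOW_SAMPLES: int = 10

#: Static-segment detection: max-minus-min range bound on the acceleration
#: magnitude within a window, in m/s^2 (10 mg).
STATIC_RANGE_M_S2: float = 0.1

#: Baseline leg length (thigh + shank) in cm used for amplitude scaling.
BASELINE_LEG_LENGTH_CM: float = 26.5

#: Standard gravity magnitude (m/s^2).
GRAVITY_M_S2: float = 9.81

#: Cut-point grid-search step per derived quantity. The acceleration-area
#: step is 0.01 m/s and the jerk-area step 0.1 m/s^2, fine enough to
#: resolve cut-points reported to three significant figures.
GRID_STEP = {"acceleration": 0.01, "jerk": 0.1}

#: Units of the epoch-area derived quantities.
QUANTITY_UNITS = {"acceleration": "m/s", "jerk": "m/s^2"}
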