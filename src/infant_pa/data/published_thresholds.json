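{
  "version": "2024.1",
  "description": "Calibrated infant activity-intensity cut-points for ankle accelerometers (10-infant calibration study; epoch areas over 2 s at 20 Hz, leg-length adjusted). t_sed_active separates sedentary from active epochs, t_light_mv separates light from moderate-to-vigorous. Units: m/s for acceleration area, m/s^2 for jerk area.",
  "thresholds": [
    {"quantity": "jerk", "placement": "both", "method": "TP", "t_sed_active": 27.0, "t_light_mv": 41.0},
    {"quantity": "jerk", "placement": "both", "method": "PAP", "t_sed_active": 18.0, "t_light_mv": 56.0},
    {"quantity": "acceleration", "placement": "both", "method": "TP", "t_sed_active": 1.30, "t_light_mv": 1.80},
    {"quantity": "acceleration", "placement": "both", "method": "PAP", "t_sed_active": 1.00, "t_light_mv": 2.60},
    {"quantity": "jerk", "placement": "left", "method": "TP", "t_sed_active": 10.0, "t_light_mv": 16.0},
    {"quantity": "jerk", "placement": "left", "method": "PAP", "t_sed_active": 8.00, "t_light_mv": 27.0},
    {"quantity": "acceleration", "placement": "left", "method": "TP", "t_sed_active": 0.600, "t_light_mv": 0.800},
    {"quantity": "acceleration", "placement": "left", "method": "PAP", "t_sed_active": 0.500, "t_light_mv": 1.30},
    {"quantity": "jerk", "placement": "right", "method": "TP", "t_sed_active": 11.0, "t_light_mv": 17.0},
    {"quantity": "jerk", "placement": "right", "method": "PAP", "t_sed_active": 7.00, "t_light_mv": 24.0},
    {"quantity": "acceleration", "placement": "right", "method": "TP", "t_sed_active": 0.400, "t_light_mv": 0.800},
    {"quantity": "acceleration", "placement": "right", "method": "PAP", "t_sed_active": 0.300, "t_light_mv": 1.00}
  ]
}
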