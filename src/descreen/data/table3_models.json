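{
  "provenance": "Published piecewise-linear QSAR models for the glycerol-DES screening study. Coefficients are on raw predictor scales. Note: the NADH half-life model was printed with segment conditions '<= 23.872' and '> 22.872'; the second value is a typographical slip and 23.872 is stored as the single breakpoint.",
  "fdh_activity": {
    "response": "FDH residual activity (%)",
    "input_names": ["viscosity", "density", "ph", "smix1", "smix2", "smix3", "smix4", "smix5", "smix6", "smix7", "smix8", "smix9"],
    "breakpoint": 30.081,
    "coef_low": [31.635, 0.024, -81.589, -0.257, 0.382, 41.465, -98.311, -93.683, 8.822, 201.025, 123.045, 80.146, 46.359],
    "coef_high": [25.079, 35.851, 1782.264, -25.075, 0.080, 42.087, -99.096, -67.368, -36.899, 22.587, 29.178, -29.264, -70.624],
    "metrics": {
      "r2_cal": 0.914, "r2_cal_adj": 0.913, "rmsec": 7.203,
      "r2_pred": 0.905, "r2_pred_adj": 0.903, "rmsep": 7.379,
      "rpd": 5.589, "rer": 18.324
    }
  },
  "fdh_half_life": {
    "response": "FDH half-life (days)",
    "input_names": ["viscosity", "density", "ph", "smix1", "smix2", "smix3", "smix4", "smix5", "smix6", "smix7", "smix8", "smix9"],
    "breakpoint": 14.041,
    "coef_low": [3.489, -0.015, -7.078, -1.359, 0.113, 7.413, -6.365, -6.827, 2.733, 12.839, 8.943, 2.277, -3.795],
    "coef_high": [4.429, -0.229, -285.320, 11.223, 0.109, 19.063, 10.294, -10.294, -10.649, 9.620, 12.795, 8.317, 1.174],
    "metrics": {
      "r2_cal": 0.829, "r2_cal_adj": 0.827, "rmsec": 4.775,
      "r2_pred": 0.738, "r2_pred_adj": 0.731, "rmsep": 4.944,
      "rpd": 3.292, "rer": 10.456
    }
  },
  "nadh_half_life": {
    "response": "NADH half-life (days)",
    "input_names": ["viscosity", "density", "smix1", "smix2", "smix3", "smix4", "smix5", "smix6", "smix7", "smix8", "smix9"],
    "breakpoint": 23.872,
    "coef_low": [11.199, 0.001, 4.581, 0.121, 21.634, -26.329, -10.074, -0.219, 29.394, 25.508, 11.581, -11.355],
    "coef_high": [-0.217, -0.175, 691.395, 0.157, -30.392, -58.475, -3.406, -7.604, 28.916, 14.168, 28.553, -24.523],
    "metrics": {
      "r2_cal": 0.930, "r2_cal_adj": 0.929, "rmsec": 4.789,
      "r2_pred": 0.856, "r2_pred_adj": 0.853, "rmsep": 6.150,
      "rpd": 3.595, "rer": 14.193
    }
  }
}
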