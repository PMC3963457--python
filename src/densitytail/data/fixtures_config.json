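{
  "version": 1,
  "comment": "Constants for the synthetic fixtures. These are artifact choices emulating the statistical structure of the published experiments; they do not reproduce any unpublished model numerically.",
  "bivariate_mixture": {
    "comment": "8-component 2-D mixture with two dominant modes of unequal height (global modal density near 0.33, secondary image-space peak well below it) plus six low-weight satellites with differing covariance orientations.",
    "default_count": 100000,
    "components": [
      {"weight": 0.35, "mean": [0.0, 0.0], "covariance": [[0.16, 0.0], [0.0, 0.2]]},
      {"weight": 0.3, "mean": [3.0, 2.0], "covariance": [[0.35, 0.05], [0.05, 0.3]]},
      {"weight": 0.07, "mean": [-2.5, 1.5], "covariance": [[0.5, 0.2], [0.2, 0.4]]},
      {"weight": 0.07, "mean": [1.5, -2.5], "covariance": [[0.8, -0.3], [-0.3, 0.5]]},
      {"weight": 0.06, "mean": [-1.5, -2.0], "covariance": [[0.4, 0.1], [0.1, 0.9]]},
      {"weight": 0.06, "mean": [4.5, -1.0], "covariance": [[0.6, 0.0], [0.0, 0.3]]},
      {"weight": 0.05, "mean": [-3.5, -0.5], "covariance": [[0.3, -0.1], [-0.1, 0.6]]},
      {"weight": 0.04, "mean": [1.0, 3.5], "covariance": [[0.9, 0.25], [0.25, 0.35]]}
    ]
  },
  "vitalsign": {
    "comment": "4-D vital-sign stream: heart rate (beats/min), respiration rate (breaths/min), SpO2 (%), systolic BP (mmHg). Plausible physiological ranges: HR 40-180, RR 4-60, SpO2 70-100, SBP 60-220. The normal model is a 400-kernel Parzen mixture fitted to seeded draws from the two-component base below; the abnormal regime raises RR and HR while SpO2 falls, and includes a jointly-improbable-but-individually-moderate sub-regime with inverted HR-RR correlation.",
    "variables": ["heart_rate", "respiration_rate", "spo2", "systolic_bp"],
    "n_train": 4000,
    "n_kernels": 400,
    "bandwidth_rule": "silverman",
    "normal_base": {
      "weights": [0.65, 0.35],
      "means": [[75.0, 16.0, 97.0, 120.0], [85.0, 18.5, 96.5, 126.0]],
      "covariances": [
        [[64.0, 8.5, 0.0, 26.4], [8.5, 7.0, -0.58, 0.0], [0.0, -0.58, 1.2, 0.0], [26.4, 0.0, 0.0, 120.0]],
        [[81.0, 9.0, -0.5, 30.0], [9.0, 9.0, -0.7, 0.0], [-0.5, -0.7, 1.4, 0.0], [30.0, 0.0, 0.0, 140.0]]
      ]
    },
    "abnormal": {
      "weights": [0.6, 0.4],
      "means": [[112.0, 30.0, 86.0, 98.0], [88.0, 24.0, 92.5, 112.0]],
      "covariances": [
        [[144.0, 30.0, -12.0, 20.0], [30.0, 36.0, -6.0, 0.0], [-12.0, -6.0, 16.0, 0.0], [20.0, 0.0, 0.0, 220.0]],
        [[36.0, -8.0, 2.0, 0.0], [-8.0, 9.0, 1.2, 0.0], [2.0, 1.2, 2.25, 0.0], [0.0, 0.0, 0.0, 90.0]]
      ]
    }
  }
}
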