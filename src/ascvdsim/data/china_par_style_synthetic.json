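{
  "name": "china-par-style-synthetic",
  "version": "1.0",
  "description": "SYNTHETIC China-PAR-style 10-year ASCVD risk coefficients. Same Cox functional form and covariates as the published equation, with plausible but NOT transcribed effect magnitudes; for pipeline exercise and testing. Replace with a transcription of the published coefficients for applied use.",
  "male": {
    "coefficients": {
      "age": 0.061,
      "sbp_untreated": 0.016,
      "sbp_treated": 0.018,
      "tc": 0.08,
      "hdl": -0.45,
      "wc": 0.01,
      "smoker": 0.38,
      "diabetes": 0.55
    },
    "s0_10yr": 0.944,
    "mean_lp": 6.6539,
    "reference_covariate_means": {
      "age": 59.0,
      "sbp": 132.0,
      "antihtn": 0.15,
      "tc": 4.7,
      "hdl": 1.25,
      "wc": 86.0,
      "smoker": 0.46,
      "diabetes": 0.1
    }
  },
  "female": {
    "coefficients": {
      "age": 0.068,
      "sbp_untreated": 0.017,
      "sbp_treated": 0.019,
      "tc": 0.07,
      "hdl": -0.5,
      "wc": 0.009,
      "smoker": 0.42,
      "diabetes": 0.6
    },
    "s0_10yr": 0.975,
    "mean_lp": 6.7928,
    "reference_covariate_means": {
      "age": 59.0,
      "sbp": 130.0,
      "antihtn": 0.18,
      "tc": 5.0,
      "hdl": 1.35,
      "wc": 84.0,
      "smoker": 0.05,
      "diabetes": 0.12
    }
  }
}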