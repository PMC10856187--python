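{
  "provenance": "Student-t error-model parameters for DP4+ candidate discrimination. Scaled-branch parameters follow the widely republished DP4 statistics (mean-zero by construction after regression scaling). Unscaled-branch parameters are package defaults calibrated to the magnitude of raw GIAO errors at mPW1PW91-family levels; edit this file to match the published table for your level of theory before quoting probabilities in a publication.",
  "level": "mPW1PW91/6-311+G(d,p) [default]",
  "scaled": {
    "C": {"mu": 0.0, "sigma": 2.306, "nu": 11.38},
    "H": {"mu": 0.0, "sigma": 0.185, "nu": 14.18}
  },
  "unscaled": {
    "C": {
      "sp2": {"mu": 6.0, "sigma": 2.9, "nu": 12.0},
      "sp3": {"mu": 2.0, "sigma": 2.5, "nu": 12.0}
    },
    "H": {
      "sp3": {"mu": 0.3, "sigma": 0.25, "nu": 14.0}
    }
  }
}
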