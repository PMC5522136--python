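{
  "intercept": -13.83,
  "coefficients": {
    "SUVpeak": 1.19,
    "Homogeneity": 12.70,
    "LGZE": 87.25,
    "HGZE": -0.01
  },
  "training_group": "G2",
  "aic": null
}
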