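{
  "intercept": -11.27,
  "coefficients": {
    "Entropy": 3.57,
    "SUVmean": -1.02,
    "SUVmax": 0.72,
    "SRE": -22.08
  },
  "training_group": "G1",
  "aic": null
}
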