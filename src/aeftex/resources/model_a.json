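{
  "name": "A",
  "outcome": "Improved",
  "intercept": -7.1555,
  "coefficients": {
    "MinIntensity": -8.586,
    "MaxIntensity": -17.1622,
    "MedianIntensity": 1.992,
    "Uniformity": 12.5851,
    "Inertia": 4.2988,
    "ClusterProminence": 10.9129,
    "RunLengthNonuniformity": 0.5123,
    "ShortRunHighGreyLevelEmphasis": -4.6584,
    "LongRunHighGreyLevelEmphasis": -12.0604
  },
  "z": {
    "Intercept": -0.0,
    "MinIntensity": -1.1469,
    "MaxIntensity": -1.1696,
    "MedianIntensity": 0.7683,
    "Uniformity": 1.1778,
    "Inertia": 1.2518,
    "ClusterProminence": 1.2056,
    "RunLengthNonuniformity": 0.311,
    "ShortRunHighGreyLevelEmphasis": -1.0423,
    "LongRunHighGreyLevelEmphasis": -0.0
  },
  "p": {
    "Intercept": 1.0,
    "MinIntensity": 0.251,
    "MaxIntensity": 0.242,
    "MedianIntensity": 0.442,
    "Uniformity": 0.239,
    "Inertia": 0.211,
    "ClusterProminence": 0.228,
    "RunLengthNonuniformity": 0.756,
    "ShortRunHighGreyLevelEmphasis": 0.297,
    "LongRunHighGreyLevelEmphasis": 1.0
  },
  "reported_performance": {
    "auc": 0.941,
    "accuracy": 0.911,
    "sensitivity": 1.0,
    "specificity": 0.826
  }
}
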