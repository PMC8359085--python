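{
  "name": "B",
  "outcome": "Un-worsened",
  "intercept": 3.1287,
  "coefficients": {
    "Kurtosis": -0.5309,
    "ClusterProminence": 1.889,
    "HighGreyLevelRunEmphasis": 0.5523,
    "LongRunHighGreyLevelEmphasis": 5.2633
  },
  "z": {
    "Intercept": 0.023,
    "Kurtosis": -0.8292,
    "ClusterProminence": 1.734,
    "HighGreyLevelRunEmphasis": 1.1414,
    "LongRunHighGreyLevelEmphasis": 0.0152
  },
  "p": {
    "Intercept": 0.982,
    "Kurtosis": 0.407,
    "ClusterProminence": 0.083,
    "HighGreyLevelRunEmphasis": 0.254,
    "LongRunHighGreyLevelEmphasis": 0.988
  },
  "reported_performance": {
    "auc": 0.824,
    "accuracy": 0.711,
    "sensitivity": 0.581,
    "specificity": 1.0
  }
}
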