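{
  "outcome": "unfavourable",
  "tier": "core",
  "intercept": -1.88,
  "terms": [
    {
      "predictor": "age",
      "level": "linear",
      "coef": 0.035
    },
    {
      "predictor": "hypertension",
      "level": "yes",
      "coef": 0.25
    },
    {
      "predictor": "wfns",
      "level": "2",
      "coef": 0.4
    },
    {
      "predictor": "wfns",
      "level": "3",
      "coef": 0.75
    },
    {
      "predictor": "wfns",
      "level": "4",
      "coef": 1.3
    },
    {
      "predictor": "wfns",
      "level": "5",
      "coef": 2.0
    }
  ],
  "encoding": {
    "age": {
      "type": "continuous",
      "center": 50,
      "scale": 1.0
    },
    "hypertension": {
      "type": "categorical",
      "reference": "no",
      "levels": [
        "no",
        "yes"
      ]
    },
    "wfns": {
      "type": "categorical",
      "reference": "1",
      "levels": [
        "1",
        "2",
        "3",
        "4",
        "5"
      ]
    }
  },
  "provenance": "synthetic fixture"
}
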