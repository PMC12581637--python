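{
  "outcome": "unfavourable",
  "tier": "full",
  "intercept": -2.92,
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
    },
    {
      "predictor": "fisher",
      "level": "2",
      "coef": 0.1
    },
    {
      "predictor": "fisher",
      "level": "3",
      "coef": 0.35
    },
    {
      "predictor": "fisher",
      "level": "4",
      "coef": 0.75
    },
    {
      "predictor": "size_band",
      "level": "13-24",
      "coef": 0.25
    },
    {
      "predictor": "size_band",
      "level": ">=25",
      "coef": 0.6
    },
    {
      "predictor": "location",
      "level": "ICA",
      "coef": 0.1
    },
    {
      "predictor": "location",
      "level": "MCA",
      "coef": 0.1
    },
    {
      "predictor": "location",
      "level": "POST",
      "coef": 0.4
    },
    {
      "predictor": "treatment",
      "level": "EVT",
      "coef": -0.05
    },
    {
      "predictor": "treatment",
      "level": "CONS",
      "coef": 1.4
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
    },
    "fisher": {
      "type": "categorical",
      "reference": "1",
      "levels": [
        "1",
        "2",
        "3",
        "4"
      ]
    },
    "size_band": {
      "type": "categorical",
      "reference": "0-12",
      "levels": [
        "0-12",
        "13-24",
        ">=25"
      ]
    },
    "location": {
      "type": "categorical",
      "reference": "ACA",
      "levels": [
        "ACA",
        "ICA",
        "MCA",
        "POST"
      ]
    },
    "treatment": {
      "type": "categorical",
      "reference": "SURG",
      "levels": [
        "SURG",
        "EVT",
        "CONS"
      ]
    }
  },
  "provenance": "synthetic fixture"
}
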