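{
  "outcome": "mortality",
  "tier": "neuroimaging",
  "intercept": -4.15,
  "terms": [
    {
      "predictor": "age",
      "level": "linear",
      "coef": 0.03
    },
    {
      "predictor": "hypertension",
      "level": "yes",
      "coef": 0.3
    },
    {
      "predictor": "wfns",
      "level": "2",
      "coef": 0.45
    },
    {
      "predictor": "wfns",
      "level": "3",
      "coef": 0.85
    },
    {
      "predictor": "wfns",
      "level": "4",
      "coef": 1.5
    },
    {
      "predictor": "wfns",
      "level": "5",
      "coef": 2.3
    },
    {
      "predictor": "fisher",
      "level": "2",
      "coef": 0.15
    },
    {
      "predictor": "fisher",
      "level": "3",
      "coef": 0.4
    },
    {
      "predictor": "fisher",
      "level": "4",
      "coef": 0.85
    },
    {
      "predictor": "size_band",
      "level": "13-24",
      "coef": 0.3
    },
    {
      "predictor": "size_band",
      "level": ">=25",
      "coef": 0.7
    },
    {
      "predictor": "location",
      "level": "ICA",
      "coef": 0.1
    },
    {
      "predictor": "location",
      "level": "MCA",
      "coef": 0.15
    },
    {
      "predictor": "location",
      "level": "POST",
      "coef": 0.5
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
    }
  },
  "provenance": "synthetic fixture"
}
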