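# Marginal presets for the synthetic aSAH cohort generator.
#
# Entries are category *weights* (here: published baseline-characteristic
# counts); they are normalised to probabilities at load time.  "pa" is the
# ICU validation cohort profile (high-acuity: 75% Fisher 4, 47% WFNS 4-5,
# 34% posterior circulation); "sahit" is the pooled trial development-cohort
# profile (lower acuity).  Age is normal, truncated to >= 18 years.
pa:
  age:
    mean: 56.0
    sd: 13.0
  hypertension: {"yes": 83, "no": 68}
  wfns: {"1": 40, "2": 26, "3": 15, "4": 32, "5": 39}
  fisher: {"1": 4, "2": 9, "3": 25, "4": 114}
  location: {ACA: 55, ICA: 11, MCA: 35, POST: 51}
  size_band: {"0-12": 135, "13-24": 16, ">=25": 1}
  treatment: {SURG: 47, EVT: 81, CONS: 24}
sahit:
  age:
    mean: 53.0
    sd: 9.0
  hypertension: {"yes": 2725, "no": 8211}
  wfns: {"1": 5088, "2": 2711, "3": 774, "4": 1222, "5": 1039}
  fisher: {"1": 786, "2": 1635, "3": 5226, "4": 1909}
  # location weights describe the subset with a known location and are
  # normalised to sum to 1
  location: {ACA: 3469, ICA: 2834, MCA: 1708, POST: 1033}
  size_band: {"0-12": 7328, "13-24": 1337, ">=25": 566}
  treatment: {SURG: 7497, EVT: 2503, CONS: 936}
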