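# sahitval

External validation of the SAHIT clinicoradiological prediction models for
aneurysmal subarachnoid haemorrhage (aSAH), aimed at intensive-care cohorts.

## The problem

The SAHIT (Subarachnoid Haemorrhage International Trialists) family is six
fixed-coefficient binary logistic models — {12-month mortality, unfavourable
functional outcome} × {core, neuroimaging, full} — derived from a pooled
trial repository of >10,000 aSAH patients. The *core* tier uses age,
premorbid hypertension and WFNS clinical grade; *neuroimaging* adds Fisher
grade, aneurysm size and location; *full* adds treatment modality. When such
a model is transported to a higher-acuity population (e.g. an ICU-only
cohort, enriched for poor WFNS grades and Fisher 4 bleeds), its
discrimination and calibration can degrade in ways that matter clinically:
a systematically positive calibration intercept means the model
under-estimates every patient's risk.

`sahitval` implements the full external-validation workflow as a reusable,
tested pipeline:

- **Cohort handling** — typed patient records, strict/lenient CSV I/O, and
  the clinical coding rules: worse-of-two GCS reconciliation, WFNS
  derivation from GCS + focal deficit, GOS mapping and the standard
  poor (GOS 1–3) / good (GOS 4–5) dichotomisation, and the treated-only
  sensitivity subset.
- **Risk scoring** — model coefficients are *configuration*, loaded from
  declarative JSON (intercept β₀, dummy-coded categorical terms, continuous
  terms with declared centring/scaling). LP = β₀ + Σβᵢxᵢ, p = expit(LP).
  The repo ships six clearly labelled synthetic placeholder specs; published
  coefficient tables drop in without code change.
- **Discrimination & calibration** — AUC (Mann–Whitney concordance, ties ½)
  with DeLong or bootstrap CI; calibration intercept-in-the-large
  (logit y = a + offset(LP)) and calibration slope (logit y = a + b·LP),
  both fitted by a from-scratch Newton–Raphson logistic MLE with Wald CIs;
  Brier score; equal-frequency calibration curves.
- **Observed-vs-expected mortality** — the predicted death count in a cohort
  with risks p₁…pₙ is Poisson-binomial; the package computes both the exact
  pmf (dynamic-programming convolution, authoritative) and a seeded Monte
  Carlo simulation (default B = 10,000, kept for density plots and fidelity
  to common practice), the central 95% interval, and P(X ≥ observed).
- **Synthetic cohorts** — a generator with published marginal presets
  (`pa`: high-acuity ICU profile; `sahit`: pooled trial profile) and
  outcomes drawn from a ground-truth model with injectable calibration
  drift: P(event) = expit(a₀ + b₀·LP). This makes every estimator testable
  against planted truth.

## Worked example

```sh
sahitval make-fixtures --seed 7 --out demo/fixtures
sahitval validate --cohort demo/fixtures/cohort.csv \
                  --models demo/fixtures/models \
                  --out demo/report --seed 3 --sensitivity
```

`metrics_full.tsv` (151 synthetic patients, six models):

```
model                   tier          outcome       cohort  n    events  auc   auc_lo  auc_hi  cal_int  cal_int_lo  cal_int_hi  cal_slope  cal_slope_lo  cal_slope_hi  brier
mortality_core          core          mortality     full    151  33      0.72  0.63    0.81    0.16     -0.25       0.57        0.89       0.42          1.37          0.155
mortality_neuroimaging  neuroimaging  mortality     full    151  33      0.73  0.64    0.83    0.26     -0.16       0.68        0.90       0.44          1.36          0.153
mortality_full          full          mortality     full    151  33      0.74  0.65    0.83    0.48     0.05        0.91        0.70       0.33          1.08          0.164
unfavourable_core       core          unfavourable  full    151  55      0.75  0.66    0.83    -0.03    -0.39       0.33        1.10       0.64          1.56          0.192
unfavourable_neuroimaging neuroimaging unfavourable full    151  55      0.75  0.67    0.83    -0.01    -0.38       0.35        1.07       0.62          1.52          0.192
unfavourable_full       full          unfavourable  full    151  55      0.77  0.70    0.85    0.02     -0.35       0.39        1.06       0.63          1.50          0.186
```

Reading it: each row is one model validated on the cohort. The fixture
cohort's functional outcomes were generated *by* the unfavourable full
model, so that row shows near-perfect calibration (intercept 0.02, slope
1.06 ≈ the ideal 0, 1); its deaths are a thinned subset of poor outcomes,
so the mortality models under-estimate (positive intercepts) — the
transported-model phenomenon the toolkit exists to measure. AUC ~0.72–0.77
is moderate discrimination; Brier < 0.25 throughout.

`oe_mortality.json` from the same run:

```json
{
  "observed": 33,
  "expected_mean": 23.99535971740834,
  "interval": [16, 32],
  "level": 0.95,
  "outside_interval": true,
  "exceedance_prob": 0.021371958518396395,
  "method": "exact",
  "n_sims": 10000,
  "seed": 3
}
```

The full mortality model expected ~24 deaths (95% interval 16–32) in a
cohort of this size; 33 were observed, outside the interval with
P(X ≥ 33) ≈ 0.02 — the cohort died at a rate the model cannot explain.

The run also writes `metrics_sensitivity.tsv` (conservatively managed
patients excluded), per-model ROC and calibration point files, the exact
death-count density (`oe_density.tsv`), and a `manifest.json` recording
every seed and convention in force. Reruns with the same seed are
bit-identical.

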