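# Methods

## Model and scoring

Each prediction model is a fixed-coefficient binary logistic model: for
patient *i* with design row **x**ᵢ,

    LP_i = β₀ + Σ_j β_j x_ij,      p_i = expit(LP_i).

Coefficients live in declarative JSON, never in code. Categorical
predictors (hypertension, WFNS, Fisher, location, size band, treatment) are
dummy-coded against a declared reference level; continuous predictors are
transformed as (value − center) × scale. The packaged fixture specs use age
per year centred at 50, references WFNS 1 / Fisher 1 / ACA / 0–12 mm /
surgical / no hypertension; a published coefficient set with different
conventions (e.g. ordinal WFNS, rescaled age) is expressed purely through
the encoding map. The six tiers are validated for predictor nesting
(core ⊆ neuroimaging ⊆ full per outcome). Probabilities are clamped to
[1e-12, 1 − 1e-12] so recalibration log-likelihoods stay finite.

The packaged coefficients are synthetic placeholders
(`provenance: "synthetic fixture"`): plausible effect directions and
magnitudes for an aSAH cohort (monotone in WFNS grade, positive Fisher-4,
posterior-circulation and conservative-management effects), with intercepts
set so the predicted event rates sit at realistic ICU levels (predicted
mortality ≈ 0.20 against an observed 26%, poor functional outcome ≈ 37%).
They are *not* estimates of any published model and are labelled
accordingly.

## Clinical coding rules

- GCS reconciliation: when two documented scores disagree, the lower
  (worse) is used — min(ed, neuro); commutative and idempotent.
- WFNS: 1 = GCS 15 no deficit; 2 = GCS 13–14 no deficit; 3 = GCS 13–14 with
  focal deficit; 4 = GCS 7–12; 5 = GCS 3–6 (deficit ignored for 4–5). The
  scale as tabulated does not cover GCS 15 *with* a deficit; such patients
  are graded 2 (the conservative reading: a deficit marks the worse of the
  two high-functioning grades). This is a policy choice, stated here
  because no authoritative rule exists.
- GOS: death→1 … good recovery→5; poor outcome = GOS 1–3. Records lacking a
  GOS are excluded from functional-outcome metrics but retained for
  mortality (complete-case per analysis, counts logged); no imputation.
- Duplicate patient IDs are an error: rows must arrive already linked to
  the index admission, because no defensible automatic linkage rule exists
  for readmissions.
- Aneurysm size bands: ≤12 → 0–12, 13–24 (sizes in (12, 13) and (24, 25)
  are assigned upward), ≥25. When only the band is present it is accepted
  as-is; when both are present they must agree.

## Discrimination

AUC is the Mann–Whitney concordance: over all (event, non-event) pairs the
fraction where the event received the higher prediction, ties counting ½ —
computed via midranks in O(n log n) and identical to the trapezoidal area
under the empirical ROC. The default CI is DeLong's asymptotic interval
from the structural-component (placement) variance; a seeded percentile
bootstrap (2,000 resamples) is available behind a flag. Which method a run
used is recorded in its output metadata; both are standard and the data do
not identify one as canonical. Intervals are clipped to [0, 1] and forced
to contain the point estimate (relevant only under perfect separation).

## Calibration

The recalibration engine is a one-covariate Newton–Raphson logistic MLE
(`fit_logistic_1d`), supporting a fixed offset:

- calibration intercept ("intercept-in-the-large"): logit P(y=1) = a +
  offset(LP), slope fixed at 1. a > 0 ⇔ observed risk exceeds predicted on
  average.
- calibration slope: logit P(y=1) = a + b·LP with free intercept; b < 1
  means predictions too extreme for the target population.

Numerics: start at 0; convergence when the score norm < 1e-8; max 50
iterations; step-halving when a step worsens the log-likelihood by more
than rounding noise (1e-10 + 1e-12·|ℓ| — without this allowance the
iteration stalls near the optimum at large n, where a Newton step improves
ℓ by less than double-precision resolution of |ℓ|). Standard errors come
from the observed information; CIs are symmetric Wald intervals. Complete
separation is detected (perfect classification at extreme coefficients) and
reported as non-convergence rather than as a spurious finite MLE.

When recovering a *planted* drift (a₀, b₀), the intercept is estimated with
the slope-corrected offset b̂·LP; the plain intercept-in-the-large equals
a₀ only when b₀ = 1, since the uncorrected offset absorbs (b₀−1)·E[LP].

Calibration curves use equal-frequency (quantile) bins; bins with
coinciding boundaries (heavy ties) merge, and bin counts always partition
n. An "estimated calibration index" — the mean squared distance between
predictions and the interpolated quantile curve — is provided for
descriptive use only; the name has no standard formula and the
implementation is explicitly non-canonical, so it appears in no headline
panel.

## Observed-vs-expected event counts

With per-patient risks p₁…pₙ, the predicted death count is
X = Σ Bernoulli(pᵢ): Poisson-binomial, mean Σpᵢ, variance Σpᵢ(1−pᵢ). Two
routes are computed and cross-checked:

- exact pmf by iterative convolution (O(n²), authoritative; mass checked to
  1e-10, mean/variance to 1e-8);
- Monte Carlo at B = 10,000 by default (the convention in O/E benchmarking
  studies), seeded numpy PCG64, chunked so B×n stays within memory.

The 95% interval is central (equal-tailed) on the discrete support: low =
smallest k with CDF(k) ≥ 0.025, high = smallest k with CDF(k) ≥ 0.975 —
the convention of the O/E literature; a highest-density alternative exists
behind a flag. The reported flag (`outside_interval`) and exceedance
probability P(X ≥ observed) always come from the exact pmf. At B = 1e5 the
MC and exact intervals agree except when the exact CDF at an endpoint lies
within MC noise (~5e-4) of the quantile target, where the empirical
endpoint can flip by one count; the test suite treats exactly those
knife-edge endpoints as ±1.

## Synthetic cohort generator

Predictor marginals follow a named preset; the shipped `pa` preset encodes
a high-acuity ICU profile (Fisher 4 ≈ 75%, WFNS 4–5 ≈ 47%, posterior
circulation ≈ 34%, conservative management ≈ 16%, hypertension ≈ 55%, age
≈ N(56, 13²) truncated at 18 and rounded to years) and `sahit` a pooled
trial-repository profile (lower acuity, age N(53, 9²)). Preset weights are
stored as human-editable YAML counts and normalised at load. Fields are
sampled independently across columns: the source tables report only
marginals, and none of the estimators under test depend on predictor
correlations — but synthetic cohorts therefore lack the real WFNS–Fisher
and severity–treatment associations, so passing tests demonstrate estimator
correctness, not clinical realism. GCS, focal deficit and size_mm are drawn
consistently with the sampled WFNS grade and size band, so the clinical
coding rules round-trip.

Outcomes: the ground-truth model's LP is drifted to expit(a₀ + b₀·LP) and
the event drawn Bernoulli. For a mortality-outcome truth model, survivors
receive GOS 4/5 with equal odds; for an unfavourable-outcome truth model,
events split death (GOS 1) vs GOS 2/3 by a configurable death fraction
defaulting to 40/57 ≈ 0.70 (the deaths-to-poor-outcomes ratio of the
reference cohort) — a labelled heuristic, adequate because no metric under
test conditions on the 2-vs-3 split.

The deterministic `reference_cohort()` reconstructs the published
151-admission ICU cohort's marginal counts exactly for every headline
quantity (40 deaths, 57 poor outcomes, 32+39 WFNS 4–5, 114 Fisher 4, 51
posterior, 24 conservative, 83 hypertensive). The published per-variable
counts each total 152 against the stated n = 151 (an internal inconsistency
of the source table); one record is removed from a non-headline category
per variable. Its joint structure is synthetic: records are ordered by
severity so that death, conservative management and poor grade co-occur
plausibly, with the remaining fields interleaved by a fixed internal
shuffle that is part of the cohort's definition. The fixture full-mortality
intercept (−4.59) was set by bisection so this cohort's exact 95% predicted
death-count interval is (22, 37) with Σpᵢ ≈ 29.5 — reproducing, on
synthetic data, the benchmark configuration in which 40 observed deaths
fall outside the predicted interval.

## Problem sizes

Marginal-fidelity and drift-recovery checks run at n = 100,000 (binomial SE
≈ 0.15% per category; recalibration SEs ≈ 0.01, so 3-SE recovery of
a₀ = 0.44, b₀ = 0.85 is a sharp test). Interval coverage uses 1,000
simulated 151-patient cohorts, each with its own risk vector and exact
interval (expected coverage 93–97% at the 95% level; the discreteness of
the support makes exact 95% unattainable). Monte-Carlo-vs-exact agreement
is checked at B = 1e5 on 20 random 151-risk vectors. These sizes were
chosen so every stochastic assertion has comfortable statistical margin.

## Pipeline conventions

Rounding happens only at serialisation: AUC and calibration to 2 decimals,
Brier to 3, baseline-table percentages to whole percent (round-half-up).
The validate pipeline is a pure function of (cohort file, bundle, config):
reruns are bit-identical, which is why the manifest carries seeds,
versions and conventions but no timestamps. On any stage failure, partial
outputs are deleted and the failing stage is named in the error.

## Known limitations

- Shipped coefficients are synthetic placeholders; conclusions about any
  *published* model require its real coefficient tables as drop-in JSON.
- No inter-predictor correlation in generated cohorts (above).
- The GOS split of non-fatal events is heuristic.
- Free-text clinical notes are out of scope: GOS descriptors must arrive
  pre-coded.
- The exact O/E computation is O(n²) and capped at n = 1e5; beyond that,
  use the Monte Carlo route alone.
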