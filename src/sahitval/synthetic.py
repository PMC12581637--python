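"""Synthetic aSAH ICU cohort generator.

Real ICU validation cohorts of this kind are not publicly deposited, so the
whole pipeline is exercised on synthetic cohorts that reproduce the marginal
structure of a published baseline-characteristics table (the ``pa`` and
``sahit`` presets) and draw outcomes from a known ground-truth logistic
model with injectable calibration drift:

    P(event) = expit(a0 + b0 * LP_true)

where (a0, b0) = (0, 1) yields a perfectly calibrated cohort and any other
value plants a known miscalibration for the metrics to recover.

Predictor fields are sampled independently across columns — the published
table reports only marginals, and the correctness of discrimination and
calibration estimators does not depend on predictor correlations. This is a
documented limitation: synthetic cohorts carry no realistic clinical
correlation structure (e.g. WFNS-Fisher association).

:func:`reference_cohort` builds the deterministic 151-admission cohort whose
category counts match the published ICU cohort table, used for summary
arithmetic and the observed-vs-expected fixture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from .cohort import CohortTable, PatientRecord, write_cohort
from .models import ModelBundle, ModelSpec, encode_patient, linear_predictor, load_model_bundle, predict_risk

__all__ = [
    "MarginalPreset",
    "DriftConfig",
    "SyntheticCohortConfig",
    "load_preset",
    "packaged_model_dir",
    "load_packaged_bundle",
    "generate_predictors",
    "generate_outcomes",
    "generate_cohort",
    "true_risks",
    "make_fixture_bundle",
    "published_pa_counts",
    "reference_cohort",
    "DEATH_FRACTION",
]

#: default death share among poor-outcome events: the published ratio of
#: 12-month deaths (40) to poor functional outcomes (57). Heuristic.
DEATH_FRACTION = 40 / 57


@dataclass
class MarginalPreset:
    """Marginal category probabilities plus an age distribution."""

    name: str
    wfns: Dict[str, float]
    fisher: Dict[str, float]
    location: Dict[str, float]
    size_band: Dict[str, float]
    treatment: Dict[str, float]
    hypertension: float  # P(premorbid hypertension)
    age_mean: float
    age_sd: float

    def validate(self) -> None:
        if self.age_sd <= 0:
            raise ValueError("age_sd must be > 0")
        for name in ("wfns", "fisher", "location", "size_band", "treatment"):
            probs = getattr(self, name)
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
            if any(v < 0 for v in probs.values()):
                raise ValueError(f"{name} has a negative probability")
        if not 0 <= self.hypertension <= 1:
            raise ValueError("hypertension probability outside [0, 1]")


def _normalise(weights: Dict) -> Dict[str, float]:
    total = float(sum(weights.values()))
    return {str(k): float(v) / total for k, v in weights.items()}


def load_preset(name: str) -> MarginalPreset:
    """Load a named preset (``pa`` or ``sahit``) from the packaged YAML."""
    text = resources.files("sahitval.data").joinpath("presets.yaml").read_text(encoding="utf-8")
    presets = yaml.safe_load(text)
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    doc = presets[name]
    htn = _normalise(doc["hypertension"])
    preset = MarginalPreset(
        name=name,
        wfns=_normalise(doc["wfns"]),
        fisher=_normalise(doc["fisher"]),
        location=_normalise(doc["location"]),
        size_band=_normalise(doc["size_band"]),
        treatment=_normalise(doc["treatment"]),
        hypertension=htn["yes"],
        age_mean=float(doc["age"]["mean"]),
        age_sd=float(doc["age"]["sd"]),
    )
    preset.validate()
    return preset


def packaged_model_dir() -> Path:
    """Directory of the packaged synthetic placeholder model specs."""
    return Path(str(resources.files("sahitval.data").joinpath("models")))


def load_packaged_bundle() -> ModelBundle:
    return load_model_bundle(packaged_model_dir())


@dataclass
class DriftConfig:
    """Calibration drift planted between true linear predictor and outcome:
    event probability = expit(intercept_shift + slope_scale * LP)."""

    intercept_shift: float = 0.0
    slope_scale: float = 1.0

    def validate(self) -> None:
        if self.slope_scale <= 0:
            raise ValueError("slope_scale must be > 0")


@dataclass
class SyntheticCohortConfig:
    n: int
    preset: MarginalPreset
    true_model: ModelSpec
    drift: DriftConfig = field(default_factory=DriftConfig)
    seed: int = 0
    death_fraction: float = DEATH_FRACTION

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        self.preset.validate()
        self.drift.validate()


def _draw_categorical(rng: np.random.Generator, probs: Dict[str, float], n: int) -> np.ndarray:
    levels = list(probs)
    p = np.array([probs[k] for k in levels])
    return rng.choice(np.array(levels, dtype=object), size=n, p=p / p.sum())


_GCS_BY_WFNS = {1: (15, 15), 2: (13, 14), 3: (13, 14), 4: (7, 12), 5: (3, 6)}
_SIZE_RANGE = {"0-12": (1.0, 12.0), "13-24": (13.0, 24.0), ">=25": (25.0, 35.0)}


def generate_predictors(config: SyntheticCohortConfig) -> CohortTable:
    """Draw n records with preset marginals; outcomes left absent.

    Age is normal truncated to >= 18 (rejection sampling), rounded to whole
    years. GCS and focal deficit are generated consistently with the drawn
    WFNS grade, and size_mm uniformly within the drawn size band, so derived
    fields round-trip through the clinical coding rules.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, preset = config.n, config.preset

    ages = np.empty(n)
    remaining = np.arange(n)
    while remaining.size:
        draw = rng.normal(preset.age_mean, preset.age_sd, size=remaining.size)
        ok = draw >= 18
        ages[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    ages = np.round(ages).astype(int)

    wfns = _draw_categorical(rng, preset.wfns, n).astype(int)
    fisher = _draw_categorical(rng, preset.fisher, n).astype(int)
    location = _draw_categorical(rng, preset.location, n)
    size_band = _draw_categorical(rng, preset.size_band, n)
    treatment = _draw_categorical(rng, preset.treatment, n)
    htn = rng.random(n) < preset.hypertension

    records = []
    for i in range(n):
        lo, hi = _GCS_BY_WFNS[int(wfns[i])]
        gcs = int(rng.integers(lo, hi + 1))
        band = str(size_band[i])
        s_lo, s_hi = _SIZE_RANGE[band]
        size_mm = float(np.round(rng.uniform(s_lo, s_hi), 1))
        records.append(
            PatientRecord(
                patient_id=f"{preset.name.upper()}-{i + 1:05d}",
                age=int(ages[i]),
                hypertension=bool(htn[i]),
                gcs_ed=gcs,
                gcs_neuro=gcs,
                focal_deficit=bool(wfns[i] == 3),
                wfns=int(wfns[i]),
                fisher=int(fisher[i]),
                location=str(location[i]),
                size_mm=size_mm,
                size_band=band,
                treatment=str(treatment[i]),
                dead_12m=False,
            )
        )
    table = CohortTable(records=records, label=f"synthetic-{preset.name}")
    table.validate()
    return table


def true_risks(cohort: CohortTable, model: ModelSpec, drift: Optional[DriftConfig] = None) -> np.ndarray:
    """Drifted ground-truth event probabilities expit(a0 + b0 * LP)."""
    drift = drift or DriftConfig()
    drift.validate()
    lp = np.array([linear_predictor(encode_patient(r, model), model) for r in cohort])
    return predict_risk(drift.intercept_shift + drift.slope_scale * lp)


def generate_outcomes(
    cohort: CohortTable,
    true_model: ModelSpec,
    drift: Optional[DriftConfig] = None,
    seed: int = 0,
    death_fraction: float = DEATH_FRACTION,
) -> CohortTable:
    """Fill outcomes by Bernoulli draws from the drifted true risks.

    The Bernoulli event is the outcome named by ``true_model.outcome``:

    * ``mortality`` — the event is 12-month death (GOS 1); survivors receive
      GOS 4 or 5 with equal odds.
    * ``unfavourable`` — the event is poor functional outcome (GOS 1-3);
      events split into death (GOS 1) vs GOS 2/3 by ``death_fraction``
      (default: the published 40/57 deaths-to-poor-outcomes ratio);
      non-events receive GOS 4 or 5 with equal odds.
    """
    drift = drift or DriftConfig()
    rng = np.random.default_rng(seed)
    p = true_risks(cohort, true_model, drift)
    events = rng.random(len(cohort)) < p

    records = []
    for rec, ev in zip(cohort, events):
        if true_model.outcome == "mortality":
            if ev:
                gos, dead = 1, True
            else:
                gos, dead = int(rng.choice([4, 5])), False
        else:
            if ev:
                if rng.random() < death_fraction:
                    gos, dead = 1, True
                else:
                    gos, dead = int(rng.choice([2, 3])), False
            else:
                gos, dead = int(rng.choice([4, 5])), False
        followup = float(np.round(rng.uniform(2.0, 12.0), 1))
        records.append(replace(rec, dead_12m=dead, gos=gos, gos_followup_months=followup))
    table = CohortTable(records=records, label=cohort.label)
    table.validate()
    return table


def generate_cohort(config: SyntheticCohortConfig) -> CohortTable:
    """Predictors and outcomes in one call (predictor seed and outcome seed
    derived from ``config.seed`` so the two stages stay independent)."""
    predictors = generate_predictors(config)
    return generate_outcomes(
        predictors,
        config.true_model,
        config.drift,
        seed=config.seed + 1,
        death_fraction=config.death_fraction,
    )


# ---------------------------------------------------------------------------
# Deterministic reference cohort matching the published ICU cohort counts.
# ---------------------------------------------------------------------------

def published_pa_counts() -> dict:
    """Headline counts of the published 151-admission ICU cohort."""
    return {
        "n": 151,
        "deaths": 40,
        "poor_outcome": 57,
        "wfns_4": 32,
        "wfns_5": 39,
        "fisher_4": 114,
        "posterior": 51,
        "conservative": 24,
        "hypertension": 83,
    }


def reference_cohort() -> CohortTable:
    """Deterministic synthetic 151-record reconstruction of the published
    ICU cohort's marginal counts.

    Every headline count (40 deaths, 57 poor outcomes, 32+39 WFNS 4-5, 114
    Fisher 4, 51 posterior circulation, 24 conservative, 83 hypertensive) is
    exact. The published per-variable counts total 152 against the stated
    n = 151; one record is removed from a non-headline category per variable
    (WFNS 2, Fisher 3, MCA, size 0-12, endovascular). The joint structure is
    synthetic: records are ordered by increasing severity so that severity,
    conservative management and death co-occur plausibly.
    """
    n = 151

    def expand(pairs):
        out = []
        for value, count in pairs:
            out.extend([value] * count)
        assert len(out) == n
        return out

    wfns = expand([(1, 40), (2, 25), (3, 15), (4, 32), (5, 39)])
    fisher = list(reversed(expand([(4, 114), (3, 24), (2, 9), (1, 4)])))
    # interleave location / size / hypertension deterministically (fixed
    # internal shuffle seed is part of this cohort's definition)
    rng = np.random.default_rng(20140101)
    location = expand([("ACA", 55), ("ICA", 11), ("MCA", 34), ("POST", 51)])
    rng.shuffle(location)
    size_band = expand([("0-12", 134), ("13-24", 16), (">=25", 1)])
    rng.shuffle(size_band)
    htn = expand([(True, 83), (False, 68)])
    rng.shuffle(htn)
    ages = np.clip(np.round(rng.normal(56, 13, size=n)), 18, 95).astype(int)
    # treated patients first; the 24 conservatively managed are the sickest
    treatment = expand([("SURG", 47), ("EVT", 80), ("CONS", 24)])
    treated = treatment[:127]
    rng.shuffle(treated)
    treatment = treated + treatment[127:]
    # outcomes: worst 40 die (GOS 1), next-worst 17 survive with GOS 2-3
    gos = [4 if i % 2 == 0 else 5 for i in range(94)] + [2, 3] * 8 + [3] + [1] * 40
    dead = [g == 1 for g in gos]

    gcs_mid = {1: 15, 2: 14, 3: 14, 4: 9, 5: 5}
    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"PA-{i + 1:03d}",
                age=int(ages[i]),
                hypertension=bool(htn[i]),
                gcs_ed=gcs_mid[wfns[i]],
                gcs_neuro=gcs_mid[wfns[i]],
                focal_deficit=wfns[i] == 3,
                wfns=wfns[i],
                fisher=fisher[i],
                location=location[i],
                size_band=size_band[i],
                treatment=treatment[i],
                dead_12m=dead[i],
                gos=gos[i],
                gos_followup_months=None if dead[i] else 9.0,
            )
        )
    table = CohortTable(records=records, label="reference-pa")
    table.validate()
    return table


def make_fixture_bundle(seed: int, out_dir) -> dict:
    """Write the deterministic test/demo fixture set.

    ``cohort.csv`` — a 151-admission synthetic cohort (pa preset, outcomes
    from the packaged ground-truth unfavourable full model, no drift);
    ``models/*.json`` — the six synthetic placeholder model specs;
    ``expected_metrics.json`` — the metric panel for every model computed at
    write time, frozen for regression testing. Regeneration with the same
    seed is byte-identical.
    """
    from .metrics import validation_report  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = load_packaged_bundle()

    config = SyntheticCohortConfig(
        n=151,
        preset=load_preset("pa"),
        true_model=bundle[("unfavourable", "full")],
        drift=DriftConfig(),
        seed=seed,
    )
    cohort = generate_cohort(config)
    cohort_path = out_dir / "cohort.csv"
    write_cohort(cohort, cohort_path)

    model_dir = out_dir / "models"
    model_dir.mkdir(exist_ok=True)
    for src in sorted(packaged_model_dir().glob("*.json")):
        (model_dir / src.name).write_text(src.read_text(encoding="utf-8"), encoding="utf-8")

    from .models import score_cohort

    risks = score_cohort(cohort, bundle)
    mortality = np.array(cohort.mortality())
    gos_idx, poor = cohort.poor_outcomes()
    expected = {}
    for spec in bundle:
        lp, p = risks.column(spec.outcome, spec.tier)
        if spec.outcome == "mortality":
            y = mortality
        else:
            lp, p, y = lp[gos_idx], p[gos_idx], np.array(poor)
        rep = validation_report(p, lp, y, spec.outcome, spec.tier, cohort_label="fixture")
        expected[spec.key] = {
            "n": rep.n,
            "events": rep.events,
            "auc": rep.auc.value,
            "auc_ci": [rep.auc.low, rep.auc.high],
            "cal_intercept": rep.cal_intercept.value,
            "cal_slope": rep.cal_slope.value,
            "brier": rep.brier,
        }
    metrics_path = out_dir / "expected_metrics.json"
    metrics_path.write_text(json.dumps({"seed": seed, "metrics": expected}, indent=2) + "\n", encoding="utf-8")
    return {"cohort": cohort_path, "models": model_dir, "expected_metrics": metrics_path}
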