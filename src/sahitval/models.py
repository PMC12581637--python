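"""Declarative logistic prediction models and deterministic risk scoring.

The SAHIT model family is six fixed-coefficient binary logistic models:
{mortality, unfavourable functional outcome} x {core, neuroimaging, full}.
The *core* tier uses age, premorbid hypertension and WFNS grade; the
*neuroimaging* tier adds Fisher grade, aneurysm size band and location; the
*full* tier adds treatment modality. Tiers are nested: every predictor of a
lower tier appears in all higher tiers for the same outcome.

Coefficients are configuration, never code constants. A :class:`ModelSpec`
is loaded from JSON holding the intercept (beta_0 on the logit scale), one
coefficient per non-reference level of each categorical predictor (dummy
coding) or a single "linear" coefficient for continuous predictors, plus an
``encoding`` map declaring reference levels and continuous centring/scaling.
The repository ships six clearly labelled synthetic placeholder specs
(``provenance: "synthetic fixture"``); published coefficient tables drop in
as JSON without code change.

Scoring is pure arithmetic: LP = beta_0 + sum(beta_i * x_i),
p = expit(LP) clamped to [1e-12, 1 - 1e-12] so downstream log-likelihoods
stay finite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .cohort import CohortTable, PatientRecord

__all__ = [
    "ModelSpecError",
    "ScoringError",
    "Term",
    "ModelSpec",
    "ModelBundle",
    "RiskMatrix",
    "OUTCOMES",
    "TIERS",
    "PROB_EPS",
    "load_model_spec",
    "load_model_bundle",
    "encode_patient",
    "linear_predictor",
    "predict_risk",
    "score_cohort",
]

OUTCOMES = ("mortality", "unfavourable")
TIERS = ("core", "neuroimaging", "full")

#: probabilities are clamped to [PROB_EPS, 1 - PROB_EPS]
PROB_EPS = 1e-12


class ModelSpecError(Exception):
    """A model-spec document violates the schema or the tier-nesting rule."""


class ScoringError(Exception):
    """A patient record cannot be scored under a given spec."""


@dataclass(frozen=True)
class Term:
    """One additive term: a dummy indicator (categorical level) or a linear
    continuous contribution, with its coefficient on the logit scale."""

    predictor: str
    level: str  # a categorical level, or "linear" for continuous terms
    coef: float


@dataclass
class ModelSpec:
    outcome: str
    tier: str
    intercept: float
    terms: List[Term]
    encoding: Dict[str, dict]
    provenance: str = "unspecified"

    @property
    def key(self) -> str:
        return f"{self.outcome}_{self.tier}"

    def predictors(self) -> set:
        return {t.predictor for t in self.terms}

    def validate(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ModelSpecError(f"unknown outcome {self.outcome!r}")
        if self.tier not in TIERS:
            raise ModelSpecError(f"unknown tier {self.tier!r}")
        if not isinstance(self.intercept, (int, float)) or not math.isfinite(self.intercept):
            raise ModelSpecError(f"{self.key}: intercept must be a finite number")
        for t in self.terms:
            if not isinstance(t.coef, (int, float)) or not math.isfinite(t.coef):
                raise ModelSpecError(f"{self.key}: coefficient for {t.predictor}/{t.level} not numeric")
            enc = self.encoding.get(t.predictor)
            if enc is None:
                raise ModelSpecError(f"{self.key}: term references undeclared predictor {t.predictor!r}")
            kind = enc.get("type")
            if kind == "continuous":
                if t.level != "linear":
                    raise ModelSpecError(
                        f"{self.key}: continuous predictor {t.predictor!r} must use level 'linear'"
                    )
            elif kind == "categorical":
                levels = enc.get("levels", [])
                if t.level not in levels:
                    raise ModelSpecError(
                        f"{self.key}: level {t.level!r} not among declared levels of {t.predictor!r}"
                    )
                if t.level == enc.get("reference"):
                    raise ModelSpecError(
                        f"{self.key}: reference level {t.level!r} of {t.predictor!r} must carry no term"
                    )
            else:
                raise ModelSpecError(f"{self.key}: predictor {t.predictor!r} has unknown type {kind!r}")


def _spec_from_dict(doc: Mapping) -> ModelSpec:
    try:
        terms = [Term(str(t["predictor"]), str(t["level"]), t["coef"]) for t in doc["terms"]]
        spec = ModelSpec(
            outcome=str(doc["outcome"]),
            tier=str(doc["tier"]),
            intercept=doc["intercept"],
            terms=terms,
            encoding=dict(doc.get("encoding", {})),
            provenance=str(doc.get("provenance", "unspecified")),
        )
    except (KeyError, TypeError) as e:
        raise ModelSpecError(f"malformed model-spec document: {e}") from None
    spec.validate()
    return spec


def load_model_spec(source: Union[str, Path, Mapping]) -> ModelSpec:
    """Load and validate one model spec from a JSON file, stream, or dict."""
    if isinstance(source, Mapping):
        return _spec_from_dict(source)
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    else:  # open stream
        doc = json.load(source)
    return _spec_from_dict(doc)


@dataclass
class ModelBundle:
    """The complete six-model set, keyed by (outcome, tier)."""

    specs: Dict[Tuple[str, str], ModelSpec]

    def __getitem__(self, key: Tuple[str, str]) -> ModelSpec:
        return self.specs[key]

    def __iter__(self):
        # deterministic order: outcome major, tier minor
        for outcome in OUTCOMES:
            for tier in TIERS:
                yield self.specs[(outcome, tier)]

    def validate(self) -> None:
        missing = [(o, t) for o in OUTCOMES for t in TIERS if (o, t) not in self.specs]
        if missing:
            raise ModelSpecError(f"bundle incomplete, missing {missing}")
        for spec in self.specs.values():
            spec.validate()
        for outcome in OUTCOMES:
            chain = [self.specs[(outcome, t)].predictors() for t in TIERS]
            for lo, hi, lo_name, hi_name in (
                (chain[0], chain[1], "core", "neuroimaging"),
                (chain[1], chain[2], "neuroimaging", "full"),
            ):
                if not lo <= hi:
                    raise ModelSpecError(
                        f"{outcome}: {hi_name} tier omits {lo_name} predictor(s) {sorted(lo - hi)}"
                    )


def load_model_bundle(path: Union[str, Path]) -> ModelBundle:
    """Load a bundle from a directory of six JSONs or a single JSON array."""
    path = Path(path)
    docs: List[ModelSpec] = []
    if path.is_dir():
        files = sorted(path.glob("*.json"))
        if not files:
            raise ModelSpecError(f"no .json model specs under {path}")
        docs = [load_model_spec(f) for f in files]
    else:
        with open(path, "r", encoding="utf-8") as fh:
            arr = json.load(fh)
        if not isinstance(arr, list):
            raise ModelSpecError("single-file bundle must be a JSON array")
        docs = [_spec_from_dict(d) for d in arr]
    specs: Dict[Tuple[str, str], ModelSpec] = {}
    for spec in docs:
        key = (spec.outcome, spec.tier)
        if key in specs:
            raise ModelSpecError(f"duplicate spec for {key}")
        specs[key] = spec
    bundle = ModelBundle(specs)
    bundle.validate()
    return bundle


def _raw_value(record: PatientRecord, predictor: str):
    if predictor == "age":
        return record.age
    if predictor == "hypertension":
        return "yes" if record.hypertension else "no"
    if predictor == "wfns":
        return str(record.wfns)
    if predictor == "fisher":
        return str(record.fisher)
    if predictor == "location":
        return record.location
    if predictor == "size_band":
        return record.size_band
    if predictor == "size_mm":
        return record.size_mm
    if predictor == "treatment":
        return record.treatment
    return None


def encode_patient(record: PatientRecord, spec: ModelSpec) -> np.ndarray:
    """Design row for one patient, ordered as ``spec.terms``.

    Categorical predictors are dummy-coded against the declared reference
    level; continuous ones are transformed as ``(value - center) * scale``.
    """
    x = np.empty(len(spec.terms))
    for j, term in enumerate(spec.terms):
        raw = _raw_value(record, term.predictor)
        if raw is None:
            raise ScoringError(
                f"patient {record.patient_id}: missing predictor {term.predictor!r} "
                f"required by model {spec.key}"
            )
        enc = spec.encoding[term.predictor]
        if enc["type"] == "continuous":
            center = enc.get("center", 0.0)
            scale = enc.get("scale", 1.0)
            x[j] = (float(raw) - center) * scale
        else:
            if str(raw) not in enc["levels"]:
                raise ScoringError(
                    f"patient {record.patient_id}: value {raw!r} of {term.predictor!r} "
                    f"not among declared levels {enc['levels']}"
                )
            x[j] = 1.0 if str(raw) == term.level else 0.0
    return x


def linear_predictor(design_row: np.ndarray, spec: ModelSpec) -> float:
    """LP = intercept + sum(beta_i * x_i) on the logit scale."""
    design_row = np.asarray(design_row, dtype=float)
    if design_row.shape != (len(spec.terms),):
        raise ScoringError(
            f"design row length {design_row.shape} does not match {len(spec.terms)} terms"
        )
    coefs = np.array([t.coef for t in spec.terms])
    return float(spec.intercept + design_row @ coefs)


def predict_risk(lp):
    """expit(LP), clamped to (0, 1) by :data:`PROB_EPS`; scalar or array."""
    lp = np.asarray(lp, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ScoringError("non-finite linear predictor")
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-lp))
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    return float(p) if p.ndim == 0 else p


@dataclass
class RiskMatrix:
    """Per-patient linear predictors and probabilities for all bundle models.

    Both frames are indexed by ``patient_id`` in cohort record order, with one
    column per model key (``mortality_core`` ... ``unfavourable_full``).
    """

    lp: pd.DataFrame
    probability: pd.DataFrame

    def column(self, outcome: str, tier: str) -> Tuple[np.ndarray, np.ndarray]:
        key = f"{outcome}_{tier}"
        return self.lp[key].to_numpy(), self.probability[key].to_numpy()


def score_cohort(cohort: CohortTable, bundle: ModelBundle) -> RiskMatrix:
    """Score every patient under every model of the bundle (pure, deterministic)."""
    if len(cohort) == 0:
        raise ScoringError("cannot score an empty cohort")
    bundle.validate()
    ids = [r.patient_id for r in cohort]
    lp_cols, p_cols = {}, {}
    for spec in bundle:
        lps = np.array([linear_predictor(encode_patient(r, spec), spec) for r in cohort])
        lp_cols[spec.key] = lps
        p_cols[spec.key] = predict_risk(lps)
    idx = pd.Index(ids, name="patient_id")
    return RiskMatrix(
        lp=pd.DataFrame(lp_cols, index=idx),
        probability=pd.DataFrame(p_cols, index=idx),
    )
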