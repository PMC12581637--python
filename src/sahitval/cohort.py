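"""Cohort domain types, CSV I/O, and clinical coding rules.

One :class:`PatientRecord` is one index ICU admission of an aneurysmal
subarachnoid haemorrhage (aSAH) patient, carrying the predictors the SAHIT
models require (age, premorbid hypertension, WFNS clinical grade, Fisher
radiological grade, aneurysm location and size, treatment modality) and the
two study outcomes (12-month mortality and the Glasgow Outcome Scale, GOS).

The coding rules implemented here are the ones applied when abstracting such
a cohort from clinical records:

* :func:`reconcile_gcs` — when emergency-department and neurosurgical Glasgow
  Coma Scale scores disagree, the lower (worse) score is used.
* :func:`derive_wfns` — WFNS grade from GCS and presence of a focal motor
  deficit/aphasia.
* :func:`map_gos` / :func:`dichotomise_outcome` — GOS category codes to the
  1–5 scale, and the standard poor (GOS 1–3) vs good (GOS 4–5) split.
* :func:`filter_treated` — the sensitivity-analysis subset excluding
  conservatively managed patients.

Free-text chart phrases are never parsed: the reader accepts pre-coded
values only. Duplicate ``patient_id`` is an error (rows must already be
linked to the index admission), never auto-deduplicated.
"""

from __future__ import annotations

import csv
import enum
import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO, Union

import pandas as pd

__all__ = [
    "CohortError",
    "SchemaError",
    "ValidationError",
    "GosDescriptor",
    "PatientRecord",
    "CohortTable",
    "LoadReport",
    "COHORT_COLUMNS",
    "LOCATIONS",
    "SIZE_BANDS",
    "TREATMENTS",
    "read_cohort",
    "write_cohort",
    "reconcile_gcs",
    "derive_wfns",
    "map_gos",
    "dichotomise_outcome",
    "filter_treated",
    "size_band_from_mm",
]


class CohortError(Exception):
    """Base class for cohort-level failures."""


class SchemaError(CohortError):
    """The input does not have the documented shape (e.g. missing column)."""


class ValidationError(CohortError):
    """A value violates a record invariant (range, consistency, duplication)."""


#: Exact CSV column order for cohort files.
COHORT_COLUMNS = [
    "patient_id",
    "age",
    "hypertension",
    "gcs_ed",
    "gcs_neuro",
    "focal_deficit",
    "wfns",
    "fisher",
    "location",
    "size_mm",
    "size_band",
    "treatment",
    "dead_12m",
    "gos",
    "gos_followup_months",
]

LOCATIONS = ("ACA", "ICA", "MCA", "POST")
SIZE_BANDS = ("0-12", "13-24", ">=25")
TREATMENTS = ("SURG", "EVT", "CONS")

#: Columns that must be non-empty in every row.
_MANDATORY = ("patient_id", "age", "hypertension", "fisher", "location", "treatment", "dead_12m")


class GosDescriptor(str, enum.Enum):
    """Qualitative Glasgow Outcome Scale category, as coded by an abstractor."""

    DEATH = "death"
    VEGETATIVE = "vegetative"
    SEVERE_DISABILITY = "severe_disability"
    MODERATE_DISABILITY = "moderate_disability"
    GOOD_RECOVERY = "good_recovery"


_GOS_SCORE = {
    GosDescriptor.DEATH: 1,
    GosDescriptor.VEGETATIVE: 2,
    GosDescriptor.SEVERE_DISABILITY: 3,
    GosDescriptor.MODERATE_DISABILITY: 4,
    GosDescriptor.GOOD_RECOVERY: 5,
}


def reconcile_gcs(gcs_ed: int, gcs_neuro: int) -> int:
    """Reconcile disagreeing ED and neurosurgical GCS scores.

    The lower (worse) of the two documented scores is retained.
    Commutative and idempotent by construction.
    """
    for name, v in (("gcs_ed", gcs_ed), ("gcs_neuro", gcs_neuro)):
        if not 3 <= int(v) <= 15:
            raise ValidationError(f"{name}={v} outside the GCS range 3-15")
    return min(int(gcs_ed), int(gcs_neuro))


def derive_wfns(gcs: int, focal_deficit: bool) -> int:
    """WFNS grade (1-5) from GCS and focal motor deficit/aphasia.

    Grade 1: GCS 15 without deficit; grade 2: GCS 13-14 without deficit;
    grade 3: GCS 13-14 with deficit; grade 4: GCS 7-12; grade 5: GCS 3-6.
    The deficit is ignored for grades 4-5. GCS 15 *with* a deficit is not
    covered by the scale as usually tabulated; such patients are graded 2.
    """
    gcs = int(gcs)
    if not 3 <= gcs <= 15:
        raise ValidationError(f"gcs={gcs} outside 3-15")
    if gcs <= 6:
        return 5
    if gcs <= 12:
        return 4
    if gcs == 15:
        return 2 if focal_deficit else 1
    return 3 if focal_deficit else 2


def map_gos(descriptor: Union[GosDescriptor, str]) -> int:
    """Map a qualitative GOS category to the ordinal 1-5 score."""
    try:
        descriptor = GosDescriptor(descriptor)
    except ValueError:
        raise ValidationError(f"unknown GOS descriptor {descriptor!r}") from None
    return _GOS_SCORE[descriptor]


def dichotomise_outcome(gos: int) -> str:
    """Dichotomise GOS: 1-3 (dead, vegetative, severe disability) -> ``"poor"``,
    4-5 -> ``"good"``."""
    gos = int(gos)
    if not 1 <= gos <= 5:
        raise ValidationError(f"gos={gos} outside 1-5")
    return "poor" if gos <= 3 else "good"


def size_band_from_mm(size_mm: float) -> str:
    """Aneurysm size band from the measured maximum diameter in millimetres."""
    if not size_mm > 0:
        raise ValidationError(f"size_mm={size_mm} must be > 0")
    if size_mm <= 12:
        return "0-12"
    if size_mm < 25:
        return "13-24"
    return ">=25"


@dataclass
class PatientRecord:
    """One index ICU admission with SAHIT predictors and dichotomous outcomes.

    ``gcs_ed``/``gcs_neuro``, ``size_mm``, ``gos`` and ``gos_followup_months``
    may be absent (``None``); everything else is mandatory. ``wfns`` may be
    supplied directly or derived from the GCS fields at read time.
    """

    patient_id: str
    age: int
    hypertension: bool
    wfns: int
    fisher: int
    location: str
    size_band: str
    treatment: str
    dead_12m: bool
    size_mm: Optional[float] = None
    gcs_ed: Optional[int] = None
    gcs_neuro: Optional[int] = None
    focal_deficit: bool = False
    gos: Optional[int] = None
    gos_followup_months: Optional[float] = None

    def validate(self) -> None:
        """Raise :class:`ValidationError` on the first violated invariant."""
        pid = self.patient_id
        if not pid:
            raise ValidationError("empty patient_id")
        if self.age < 18:
            raise ValidationError(f"patient {pid}: age={self.age} below 18")
        if self.wfns not in (1, 2, 3, 4, 5):
            raise ValidationError(f"patient {pid}: wfns={self.wfns} outside 1-5")
        if self.fisher not in (1, 2, 3, 4):
            raise ValidationError(f"patient {pid}: fisher={self.fisher} outside 1-4")
        if self.location not in LOCATIONS:
            raise ValidationError(f"patient {pid}: location={self.location!r} not in {LOCATIONS}")
        if self.size_band not in SIZE_BANDS:
            raise ValidationError(f"patient {pid}: size_band={self.size_band!r} not in {SIZE_BANDS}")
        if self.treatment not in TREATMENTS:
            raise ValidationError(f"patient {pid}: treatment={self.treatment!r} not in {TREATMENTS}")
        for name in ("gcs_ed", "gcs_neuro"):
            v = getattr(self, name)
            if v is not None and not 3 <= v <= 15:
                raise ValidationError(f"patient {pid}: {name}={v} outside 3-15")
        if self.size_mm is not None:
            if self.size_mm <= 0:
                raise ValidationError(f"patient {pid}: size_mm={self.size_mm} must be > 0")
            if size_band_from_mm(self.size_mm) != self.size_band:
                raise ValidationError(
                    f"patient {pid}: size_mm={self.size_mm} inconsistent with "
                    f"size_band={self.size_band!r}"
                )
        if self.gos is not None:
            if not 1 <= self.gos <= 5:
                raise ValidationError(f"patient {pid}: gos={self.gos} outside 1-5")
            if self.dead_12m and self.gos != 1:
                raise ValidationError(
                    f"patient {pid}: dead_12m=1 requires gos=1, got gos={self.gos}"
                )
        if self.gos_followup_months is not None and not 2 <= self.gos_followup_months <= 12:
            raise ValidationError(
                f"patient {pid}: gos_followup_months={self.gos_followup_months} outside [2, 12]"
            )

    @property
    def poor_outcome(self) -> Optional[bool]:
        """Dichotomised functional outcome; ``None`` when GOS is missing."""
        if self.gos is None:
            return None
        return dichotomise_outcome(self.gos) == "poor"


@dataclass
class LoadReport:
    """Accounting of a lenient cohort load: rows read, kept, and dropped."""

    n_read: int = 0
    n_kept: int = 0
    dropped: list = field(default_factory=list)  # (row number, reason)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


@dataclass
class CohortTable:
    """Ordered collection of validated :class:`PatientRecord` with a label."""

    records: list
    label: str = "full"
    load_report: Optional[LoadReport] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    def validate(self) -> None:
        seen = set()
        for rec in self.records:
            rec.validate()
            if rec.patient_id in seen:
                raise ValidationError(f"duplicate patient_id {rec.patient_id!r}")
            seen.add(rec.patient_id)

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a DataFrame in the documented column order."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "age": r.age,
                    "hypertension": r.hypertension,
                    "gcs_ed": r.gcs_ed,
                    "gcs_neuro": r.gcs_neuro,
                    "focal_deficit": r.focal_deficit,
                    "wfns": r.wfns,
                    "fisher": r.fisher,
                    "location": r.location,
                    "size_mm": r.size_mm,
                    "size_band": r.size_band,
                    "treatment": r.treatment,
                    "dead_12m": r.dead_12m,
                    "gos": r.gos,
                    "gos_followup_months": r.gos_followup_months,
                }
            )
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)

    def mortality(self) -> list:
        """12-month mortality as a 0/1 list aligned with record order."""
        return [int(r.dead_12m) for r in self.records]

    def poor_outcomes(self) -> "tuple[list, list]":
        """(record indices with a GOS, 0/1 poor-outcome list) — complete case.

        Records lacking a GOS are excluded from functional-outcome analyses
        but retained for mortality; the caller gets the kept indices so
        predictions can be aligned.
        """
        idx, y = [], []
        for i, r in enumerate(self.records):
            if r.gos is not None:
                idx.append(i)
                y.append(int(r.poor_outcome))
        return idx, y


def filter_treated(cohort: CohortTable) -> CohortTable:
    """Sensitivity-analysis subset: drop conservatively managed patients."""
    kept = [r for r in cohort.records if r.treatment != "CONS"]
    return CohortTable(records=kept, label="treated-only")


# ---------------------------------------------------------------------------
# CSV I/O.  Fixed dialect: comma separated, UTF-8, "." decimal, booleans 0/1,
# empty cell = absent.  Writing a cohort read from a canonical file
# round-trips byte-identically.
# ---------------------------------------------------------------------------

def _parse_bool(raw: str, row: int, col: str) -> bool:
    if raw == "0":
        return False
    if raw == "1":
        return True
    raise ValidationError(f"row {row}: {col}={raw!r} is not a 0/1 boolean")


def _parse_int(raw: str, row: int, col: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise ValidationError(f"row {row}: {col}={raw!r} is not an integer") from None


def _parse_float(raw: str, row: int, col: str) -> float:
    try:
        v = float(raw)
    except ValueError:
        raise ValidationError(f"row {row}: {col}={raw!r} is not a number") from None
    if not math.isfinite(v):
        raise ValidationError(f"row {row}: {col}={raw!r} is not finite")
    return v


def _record_from_row(row: dict, rownum: int) -> PatientRecord:
    get = lambda c: (row.get(c) or "").strip()

    for col in _MANDATORY:
        if get(col) == "":
            raise ValidationError(f"row {rownum}: mandatory field {col!r} is empty")

    gcs_ed = _parse_int(get("gcs_ed"), rownum, "gcs_ed") if get("gcs_ed") else None
    gcs_neuro = _parse_int(get("gcs_neuro"), rownum, "gcs_neuro") if get("gcs_neuro") else None
    focal = _parse_bool(get("focal_deficit"), rownum, "focal_deficit") if get("focal_deficit") else False

    wfns_raw = get("wfns")
    if wfns_raw:
        wfns = _parse_int(wfns_raw, rownum, "wfns")
    else:
        # derive from the documented GCS fields (reconciled when both exist)
        if gcs_ed is None and gcs_neuro is None:
            raise ValidationError(f"row {rownum}: wfns missing and no GCS to derive it from")
        if gcs_ed is not None and gcs_neuro is not None:
            gcs = reconcile_gcs(gcs_ed, gcs_neuro)
        else:
            gcs = gcs_ed if gcs_ed is not None else gcs_neuro
        wfns = derive_wfns(gcs, focal)

    size_mm = _parse_float(get("size_mm"), rownum, "size_mm") if get("size_mm") else None
    band_raw = get("size_band")
    if band_raw:
        size_band = band_raw
    elif size_mm is not None:
        size_band = size_band_from_mm(size_mm)
    else:
        raise ValidationError(f"row {rownum}: neither size_mm nor size_band present")

    rec = PatientRecord(
        patient_id=get("patient_id"),
        age=_parse_int(get("age"), rownum, "age"),
        hypertension=_parse_bool(get("hypertension"), rownum, "hypertension"),
        gcs_ed=gcs_ed,
        gcs_neuro=gcs_neuro,
        focal_deficit=focal,
        wfns=wfns,
        fisher=_parse_int(get("fisher"), rownum, "fisher"),
        location=get("location"),
        size_mm=size_mm,
        size_band=size_band,
        treatment=get("treatment"),
        dead_12m=_parse_bool(get("dead_12m"), rownum, "dead_12m"),
        gos=_parse_int(get("gos"), rownum, "gos") if get("gos") else None,
        gos_followup_months=(
            _parse_float(get("gos_followup_months"), rownum, "gos_followup_months")
            if get("gos_followup_months")
            else None
        ),
    )
    try:
        rec.validate()
    except ValidationError as e:
        raise ValidationError(f"row {rownum}: {e}") from None
    return rec


def read_cohort(
    source: Union[str, Path, TextIO],
    strict: bool = True,
    label: str = "full",
) -> CohortTable:
    """Read a cohort CSV.

    Parameters
    ----------
    source
        Path or open text stream of a CSV with the documented header.
    strict
        If True (default) any invariant violation aborts the load. If False,
        offending rows are dropped and counted in ``CohortTable.load_report``.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_cohort(fh, strict=strict, label=label)

    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        raise SchemaError("empty input: no header row")
    missing = [c for c in COHORT_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    report = LoadReport()
    records: list = []
    seen: set = set()
    for rownum, row in enumerate(reader, start=2):  # header is line 1
        report.n_read += 1
        try:
            rec = _record_from_row(row, rownum)
            if rec.patient_id in seen:
                raise ValidationError(f"row {rownum}: duplicate patient_id {rec.patient_id!r}")
        except ValidationError as e:
            if strict:
                raise
            report.dropped.append((rownum, str(e)))
            continue
        seen.add(rec.patient_id)
        records.append(rec)
        report.n_kept += 1

    return CohortTable(records=records, label=label, load_report=report)


def _fmt_num(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return str(int(v)) if v == int(v) else repr(v)
    return str(v)


def write_cohort(cohort: CohortTable, dest: Union[str, Path, TextIO]) -> None:
    """Write a cohort in the canonical CSV dialect (read -> write round-trips)."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            write_cohort(cohort, fh)
        return
    writer = csv.writer(dest, lineterminator="\n")
    writer.writerow(COHORT_COLUMNS)
    for r in cohort.records:
        writer.writerow(
            [
                r.patient_id,
                _fmt_num(r.age),
                _fmt_num(r.hypertension),
                _fmt_num(r.gcs_ed),
                _fmt_num(r.gcs_neuro),
                _fmt_num(r.focal_deficit),
                _fmt_num(r.wfns),
                _fmt_num(r.fisher),
                r.location,
                _fmt_num(r.size_mm),
                r.size_band,
                r.treatment,
                _fmt_num(r.dead_12m),
                _fmt_num(r.gos),
                _fmt_num(r.gos_followup_months),
            ]
        )
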