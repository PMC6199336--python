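"""Clinical-table I/O, cohort summaries and inclusion filtering.

The clinical table mirrors the standard per-patient summary for a
Parkinson's disease cohort: gender, age, disease duration, dominantly
affected side, Hoehn-Yahr stage, UPDRS-III motor score, ACE-R and MMSE
cognitive screens, and the levodopa dose equivalent (LDE, mg/day; taken as
an input — conversion from drug regimens is out of scope).  The published
18-patient table ships with the package as a fixture
(``load_packaged_patients``).

Cohort tables may carry extra ``subject_id`` and ``group`` columns; for
control subjects the patient-only scores are missing values, never zeros,
and group membership is always an explicit column.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ClinicalParseError, EmptyInputError

__all__ = [
    "ClinicalRecord",
    "InclusionCriteria",
    "CLINICAL_COLUMNS",
    "load_clinical_table",
    "write_clinical_table",
    "load_packaged_patients",
    "packaged_patients_path",
    "summarize_cohort",
    "apply_inclusion_filters",
]

CLINICAL_COLUMNS = [
    "patient_no",
    "gender",
    "age",
    "disease_duration_y",
    "dominant_side",
    "hoehn_yahr",
    "updrs_motor",
    "ace_r",
    "mmse",
    "lde",
]

_NUMERIC = [
    "age",
    "disease_duration_y",
    "hoehn_yahr",
    "updrs_motor",
    "ace_r",
    "mmse",
    "lde",
]

_HY_STAGES = {1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 4.5, 5.0}


@dataclass(frozen=True)
class ClinicalRecord:
    """One row of the clinical table.  ``None`` marks a missing value
    (controls carry no disease scores)."""

    patient_no: int | None
    gender: str
    age: float
    disease_duration_y: float | None
    dominant_side: str | None
    hoehn_yahr: float | None
    updrs_motor: float | None
    ace_r: float | None
    mmse: float | None
    lde: float | None
    subject_id: str | None = None
    group: str = "patient"


def _missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or v == ""


def _validate_row(row: dict, rownum: int, problems: list[str]) -> ClinicalRecord | None:
    vals: dict = {}
    ok = True

    gender = row.get("gender")
    if _missing(gender) or str(gender).upper() not in ("M", "F"):
        problems.append(f"row {rownum}: gender must be M or F, got {gender!r}")
        ok = False
    else:
        vals["gender"] = str(gender).upper()

    for col in _NUMERIC:
        raw = row.get(col)
        if _missing(raw):
            vals[col] = None
            continue
        try:
            vals[col] = float(raw)
        except (TypeError, ValueError):
            problems.append(f"row {rownum}: column {col!r} is not numeric: {raw!r}")
            ok = False

    if ok:
        if vals["age"] is None or vals["age"] <= 0:
            problems.append(f"row {rownum}: age must be a positive number")
            ok = False
        if vals["ace_r"] is not None and not (0 <= vals["ace_r"] <= 100):
            problems.append(f"row {rownum}: ace_r must lie in 0-100")
            ok = False
        if vals["mmse"] is not None and not (0 <= vals["mmse"] <= 30):
            problems.append(f"row {rownum}: mmse must lie in 0-30")
            ok = False
        if vals["lde"] is not None and vals["lde"] < 0:
            problems.append(f"row {rownum}: lde must be >= 0")
            ok = False
        if vals["hoehn_yahr"] is not None and vals["hoehn_yahr"] not in _HY_STAGES:
            problems.append(
                f"row {rownum}: hoehn_yahr must be one of {sorted(_HY_STAGES)}"
            )
            ok = False
    if not ok:
        return None

    side = row.get("dominant_side")
    side = None if _missing(side) else str(side).upper()
    if side is not None and side not in ("L", "R", "B"):
        problems.append(f"row {rownum}: dominant_side must be L, R or B")
        return None

    pn = row.get("patient_no")
    group = row.get("group")
    group = "patient" if _missing(group) else str(group)
    sid = row.get("subject_id")
    return ClinicalRecord(
        patient_no=None if _missing(pn) else int(float(pn)),
        gender=vals["gender"],
        age=vals["age"],
        disease_duration_y=vals["disease_duration_y"],
        dominant_side=side,
        hoehn_yahr=vals["hoehn_yahr"],
        updrs_motor=vals["updrs_motor"],
        ace_r=vals["ace_r"],
        mmse=vals["mmse"],
        lde=vals["lde"],
        subject_id=None if _missing(sid) else str(sid),
        group=group,
    )


def load_clinical_table(path) -> list[ClinicalRecord]:
    """Read and validate a clinical CSV.

    Raises :class:`ClinicalParseError` listing every malformed cell with
    its row number; an empty table is also a parse error.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ClinicalParseError(f"{path}: unreadable clinical table ({exc})")
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ClinicalParseError(
            f"{path}: missing required columns {missing_cols}", missing_cols
        )
    if len(frame) == 0:
        raise ClinicalParseError(f"{path}: clinical table has no rows")
    problems: list[str] = []
    records: list[ClinicalRecord] = []
    for i, row in enumerate(frame.to_dict("records")):
        rec = _validate_row(row, i + 2, problems)  # +2: header + 1-based
        if rec is not None:
            records.append(rec)
    if problems:
        raise ClinicalParseError(
            f"{path}: {len(problems)} malformed value(s)", problems
        )
    return records


def write_clinical_table(records: list[ClinicalRecord], path) -> None:
    """Write records back to CSV in the canonical column order."""
    rows = []
    for rec in records:
        d = asdict(rec)
        rows.append({c: d[c] for c in CLINICAL_COLUMNS})
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False)


def packaged_patients_path() -> Path:
    """Path of the packaged 18-patient clinical fixture."""
    return Path(resources.files("forcematch").joinpath("data/table1_patients.csv"))


def load_packaged_patients() -> list[ClinicalRecord]:
    """The published 18-patient clinical table as validated records."""
    return load_clinical_table(packaged_patients_path())


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def summarize_cohort(records: list[ClinicalRecord], *, rounded: bool = True) -> dict:
    """Mean age/duration/UPDRS/ACE-R/MMSE/LDE plus gender counts.

    With ``rounded=True`` means are rounded half-away-from-zero to
    integers, the convention of the printed summary row.  Missing values
    are skipped, not imputed.
    """
    if not records:
        raise EmptyInputError("no clinical records")

    def mean_of(attr: str) -> float:
        vals = [getattr(r, attr) for r in records if getattr(r, attr) is not None]
        return float(np.mean(vals)) if vals else float("nan")

    means = {
        "age": mean_of("age"),
        "disease_duration_y": mean_of("disease_duration_y"),
        "updrs_motor": mean_of("updrs_motor"),
        "ace_r": mean_of("ace_r"),
        "mmse": mean_of("mmse"),
        "lde": mean_of("lde"),
    }
    if rounded:
        means = {
            k: (_round_half_away(v) if not math.isnan(v) else v)
            for k, v in means.items()
        }
    means["n"] = len(records)
    means["n_male"] = sum(1 for r in records if r.gender == "M")
    means["n_female"] = sum(1 for r in records if r.gender == "F")
    return means


@dataclass(frozen=True)
class InclusionCriteria:
    """Study inclusion rules.

    Patients: ACE-R of at least ``min_ace_r`` (scores *below* 84 are
    excluded, 84 itself is included) and Hoehn-Yahr stage within
    ``hoehn_yahr_range``.  Controls: age within ``patient_age_range`` when
    given (normally the included patients' min-max age).
    """

    min_ace_r: float = 84.0
    hoehn_yahr_range: tuple[float, float] = (1.0, 3.0)
    patient_age_range: tuple[float, float] | None = None


def apply_inclusion_filters(
    records: list[ClinicalRecord],
    criteria: InclusionCriteria | None = None,
) -> tuple[list[ClinicalRecord], list[tuple[ClinicalRecord, tuple[str, ...]]]]:
    """Partition records into (included, excluded-with-reasons).

    Reasons are machine-readable strings: ``ace_r_below_<threshold>``,
    ``hoehn_yahr_out_of_range``, ``age_outside_patient_range``.  When
    ``criteria.patient_age_range`` is None it is derived from the included
    patients and applied to control records only.
    """
    criteria = criteria or InclusionCriteria()
    included: list[ClinicalRecord] = []
    excluded: list[tuple[ClinicalRecord, tuple[str, ...]]] = []

    patients = [r for r in records if r.group == "patient"]
    controls = [r for r in records if r.group != "patient"]

    kept_patients = []
    for rec in patients:
        reasons = []
        if rec.ace_r is not None and rec.ace_r < criteria.min_ace_r:
            reasons.append(f"ace_r_below_{criteria.min_ace_r:g}")
        lo, hi = criteria.hoehn_yahr_range
        if rec.hoehn_yahr is not None and not (lo <= rec.hoehn_yahr <= hi):
            reasons.append("hoehn_yahr_out_of_range")
        if reasons:
            excluded.append((rec, tuple(reasons)))
        else:
            kept_patients.append(rec)
    included.extend(kept_patients)

    age_range = criteria.patient_age_range
    if age_range is None and kept_patients:
        ages = [r.age for r in kept_patients]
        age_range = (min(ages), max(ages))
    for rec in controls:
        if age_range is not None and not (age_range[0] <= rec.age <= age_range[1]):
            excluded.append((rec, ("age_outside_patient_range",)))
        else:
            included.append(rec)
    return included, excluded
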