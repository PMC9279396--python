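"""Domain types for structured EHR extracts and flat-file readers/writers.

The screening pipeline consumes de-identified EHR data as three flat tables
(patients, encounters, diagnoses) plus two knowledge tables: a CCSR-style
mapping of ICD-10-CM codes to clinical categories, and an expert rating of
each code's association with borderline personality disorder (BoPD).

All diagnosis codes are normalized to uppercase with the dot stripped
(``F60.3`` -> ``F603``); every downstream rule matches on normalized codes.
All temporal logic is anchored on encounter discharge dates.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "CodeSystem",
    "EncounterType",
    "Gender",
    "Rating",
    "DiagnosisEvent",
    "Encounter",
    "PatientRecord",
    "CcsrMap",
    "AssociationRatings",
    "StudyConfig",
    "FormatError",
    "RecordError",
    "normalize_code",
    "age_at",
    "read_ehr_tables",
    "write_ehr_tables",
    "read_ccsr_map",
    "write_ccsr_map",
    "read_association_ratings",
    "write_association_ratings",
]


class FormatError(ValueError):
    """A flat input file violates its documented format."""


class RecordError(ValueError):
    """A record is internally inconsistent (e.g. dangling encounter id)."""


class CodeSystem(str, enum.Enum):
    ICD9CM = "ICD9CM"
    ICD10CM = "ICD10CM"


class EncounterType(str, enum.Enum):
    EMERGENCY = "emergency"
    INPATIENT = "inpatient"
    OUTPATIENT_OTHER = "outpatient_other"


class Gender(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN_OTHER = "unknown_other"


class Rating(str, enum.Enum):
    """Expert-judged association of a diagnosis code with BoPD."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNRELATED = "unrelated"
    UNSURE = "unsure"


def normalize_code(code: str) -> str:
    """Normalize a diagnosis code: uppercase, strip the dot and whitespace."""
    return str(code).strip().upper().replace(".", "")


@dataclass(frozen=True)
class DiagnosisEvent:
    """One diagnosis code recorded at one encounter."""

    patient_id: str
    encounter_id: str
    code_system: CodeSystem
    code: str

    def __post_init__(self) -> None:
        if not self.code:
            raise RecordError(
                f"empty diagnosis code for patient {self.patient_id!r}"
            )


@dataclass(frozen=True)
class Encounter:
    encounter_id: str
    patient_id: str
    encounter_type: EncounterType
    discharge_date: datetime.date


@dataclass(frozen=True)
class PatientRecord:
    """One subject's demographics plus encounter and diagnosis history."""

    patient_id: str
    gender: Gender
    birth_date: datetime.date
    encounters: tuple[Encounter, ...] = ()
    diagnoses: tuple[DiagnosisEvent, ...] = ()

    def __post_init__(self) -> None:
        known = {e.encounter_id for e in self.encounters}
        for dx in self.diagnoses:
            if dx.encounter_id not in known:
                raise RecordError(
                    f"patient {self.patient_id!r}: diagnosis {dx.code!r} "
                    f"references unknown encounter {dx.encounter_id!r}"
                )

    @property
    def encounter_by_id(self) -> dict[str, Encounter]:
        return {e.encounter_id: e for e in self.encounters}

    def encounters_with_diagnoses(self) -> tuple[Encounter, ...]:
        """Encounters that carry at least one diagnosis code."""
        coded = {dx.encounter_id for dx in self.diagnoses}
        return tuple(e for e in self.encounters if e.encounter_id in coded)


def age_at(patient: PatientRecord, date: datetime.date) -> int:
    """Completed years of age at ``date``.

    Raises ValueError if ``date`` precedes the birth date.
    """
    birth = patient.birth_date
    if date < birth:
        raise ValueError(
            f"patient {patient.patient_id!r}: date {date} precedes birth {birth}"
        )
    return (
        date.year
        - birth.year
        - ((date.month, date.day) < (birth.month, birth.day))
    )


@dataclass(frozen=True)
class CcsrMap:
    """Default CCSR category for each ICD-10-CM code (one category per code)."""

    entries: Mapping[str, str]

    def category(self, code: str) -> str | None:
        return self.entries.get(normalize_code(code))

    def __contains__(self, code: str) -> bool:
        return normalize_code(code) in self.entries


@dataclass(frozen=True)
class AssociationRatings:
    """Expert BoPD-association rating per diagnosis code."""

    entries: Mapping[str, Rating]

    def rating(self, code: str, default: Rating = Rating.UNSURE) -> Rating:
        return self.entries.get(normalize_code(code), default)


@dataclass
class StudyConfig:
    """Constants of the screening study design.

    Defaults reflect a ~3-year ICD-10-CM era study window, the 5-encounter /
    2-emergency history minimum, the 18-65 age window, the 3-category
    comorbidity rule, a 5% code-prevalence cutoff, the 66:162 gold-label
    class ratio used to size the silver-negative set, a 0.5 decision
    threshold, 10-fold cross-validation and 1,000-replicate 95% bootstrap
    intervals.
    """

    study_start: datetime.date = datetime.date(2015, 10, 1)
    study_end: datetime.date = datetime.date(2018, 7, 11)
    min_encounter_dates: int = 5
    min_emergency_dates: int = 2
    age_low: int = 18
    age_high: int = 65
    min_other_categories: int = 3
    prevalence_cutoff: float = 0.05
    gold_ratio_pos: int = 66
    gold_ratio_neg: int = 162
    decision_threshold: float = 0.5
    cv_folds: int = 10
    bootstrap_reps: int = 1000
    ci_level: float = 0.95
    random_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        for name in (
            "min_encounter_dates",
            "min_emergency_dates",
            "min_other_categories",
            "gold_ratio_pos",
            "gold_ratio_neg",
            "cv_folds",
            "bootstrap_reps",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must lie in (0, 1)")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if not 0.0 <= self.prevalence_cutoff <= 1.0:
            raise ValueError("prevalence_cutoff must lie in [0, 1]")
        if not 0 <= self.age_low <= self.age_high <= 120:
            raise ValueError("require 0 <= age_low <= age_high <= 120")

    def in_study_period(self, date: datetime.date) -> bool:
        """Both boundary dates are inside the study period."""
        return self.study_start <= date <= self.study_end

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        kwargs = dict(d)
        for key in ("study_start", "study_end"):
            if key in kwargs and isinstance(kwargs[key], str):
                kwargs[key] = datetime.date.fromisoformat(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# flat-file IO
# ---------------------------------------------------------------------------

_PATIENT_COLS = ["patient_id", "gender", "birth_date"]
_ENCOUNTER_COLS = ["encounter_id", "patient_id", "encounter_type", "discharge_date"]
_DIAGNOSIS_COLS = ["patient_id", "encounter_id", "code_system", "code"]


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def _parse_dates(series: pd.Series, path: str | Path, column: str) -> list[datetime.date]:
    out = []
    for row, value in enumerate(series, start=2):  # header is line 1
        try:
            out.append(datetime.date.fromisoformat(value))
        except ValueError as exc:
            raise FormatError(
                f"{path}: unparseable date {value!r} in column {column!r} "
                f"at line {row}"
            ) from exc
    return out


def _parse_gender(value: str, patient_id: str) -> Gender:
    v = value.strip().lower()
    if v in ("female", "f"):
        return Gender.FEMALE
    if v in ("male", "m"):
        return Gender.MALE
    if v not in ("unknown_other", "unknown", "other", ""):
        logger.warning(
            "patient %s: unrecognized gender %r mapped to unknown_other",
            patient_id, value,
        )
    return Gender.UNKNOWN_OTHER


def read_ehr_tables(
    patients_path: str | Path,
    encounters_path: str | Path,
    diagnoses_path: str | Path,
) -> list[PatientRecord]:
    """Read the three flat tables and join them into :class:`PatientRecord`s.

    Diagnosis codes are normalized on read; rows are joined on patient and
    encounter ids. Output order is sorted by patient id so the reader is
    insensitive to input row order.
    """
    pat = _read_table(patients_path, _PATIENT_COLS)
    enc = _read_table(encounters_path, _ENCOUNTER_COLS)
    dx = _read_table(diagnoses_path, _DIAGNOSIS_COLS)

    birth_dates = _parse_dates(pat["birth_date"], patients_path, "birth_date")
    discharge_dates = _parse_dates(
        enc["discharge_date"], encounters_path, "discharge_date"
    )

    try:
        enc_types = [EncounterType(t) for t in enc["encounter_type"]]
    except ValueError as exc:
        raise FormatError(f"{encounters_path}: {exc}") from exc
    try:
        systems = [CodeSystem(s) for s in dx["code_system"]]
    except ValueError as exc:
        raise FormatError(f"{diagnoses_path}: {exc}") from exc

    encounters_by_patient: dict[str, list[Encounter]] = {}
    for i in range(len(enc)):
        e = Encounter(
            encounter_id=enc["encounter_id"].iat[i],
            patient_id=enc["patient_id"].iat[i],
            encounter_type=enc_types[i],
            discharge_date=discharge_dates[i],
        )
        encounters_by_patient.setdefault(e.patient_id, []).append(e)

    diagnoses_by_patient: dict[str, list[DiagnosisEvent]] = {}
    for i in range(len(dx)):
        d = DiagnosisEvent(
            patient_id=dx["patient_id"].iat[i],
            encounter_id=dx["encounter_id"].iat[i],
            code_system=systems[i],
            code=normalize_code(dx["code"].iat[i]),
        )
        diagnoses_by_patient.setdefault(d.patient_id, []).append(d)

    records = []
    for i, pid in enumerate(pat["patient_id"]):
        enc_list = sorted(
            encounters_by_patient.get(pid, []),
            key=lambda e: (e.discharge_date, e.encounter_id),
        )
        dx_list = sorted(
            diagnoses_by_patient.get(pid, []),
            key=lambda d: (d.encounter_id, d.code_system.value, d.code),
        )
        records.append(
            PatientRecord(
                patient_id=pid,
                gender=_parse_gender(pat["gender"].iat[i], pid),
                birth_date=birth_dates[i],
                encounters=tuple(enc_list),
                diagnoses=tuple(dx_list),
            )
        )

    known_patients = {r.patient_id for r in records}
    for pid in diagnoses_by_patient:
        if pid not in known_patients:
            raise RecordError(f"diagnosis for unknown patient {pid!r}")

    return sorted(records, key=lambda r: r.patient_id)


def write_ehr_tables(
    records: Iterable[PatientRecord],
    patients_path: str | Path,
    encounters_path: str | Path,
    diagnoses_path: str | Path,
) -> None:
    """Write records back to the three-table interchange format."""
    records = list(records)
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "gender": r.gender.value,
                "birth_date": r.birth_date.isoformat(),
            }
            for r in records
        ],
        columns=_PATIENT_COLS,
    ).to_csv(patients_path, index=False)
    pd.DataFrame(
        [
            {
                "encounter_id": e.encounter_id,
                "patient_id": e.patient_id,
                "encounter_type": e.encounter_type.value,
                "discharge_date": e.discharge_date.isoformat(),
            }
            for r in records
            for e in r.encounters
        ],
        columns=_ENCOUNTER_COLS,
    ).to_csv(encounters_path, index=False)
    pd.DataFrame(
        [
            {
                "patient_id": d.patient_id,
                "encounter_id": d.encounter_id,
                "code_system": d.code_system.value,
                "code": d.code,
            }
            for r in records
            for d in r.diagnoses
        ],
        columns=_DIAGNOSIS_COLS,
    ).to_csv(diagnoses_path, index=False)


def read_ccsr_map(path: str | Path) -> CcsrMap:
    df = _read_table(path, ["code", "ccsr_category"])
    entries: dict[str, str] = {}
    for code, cat in zip(df["code"], df["ccsr_category"]):
        norm = normalize_code(code)
        if norm in entries and entries[norm] != cat:
            raise FormatError(
                f"{path}: code {norm!r} mapped to multiple categories"
            )
        entries[norm] = cat
    return CcsrMap(entries=entries)


def write_ccsr_map(ccsr: CcsrMap, path: str | Path) -> None:
    pd.DataFrame(
        sorted(ccsr.entries.items()), columns=["code", "ccsr_category"]
    ).to_csv(path, index=False)


def read_association_ratings(path: str | Path) -> AssociationRatings:
    df = _read_table(path, ["code", "rating"])
    entries: dict[str, Rating] = {}
    for code, rating in zip(df["code"], df["rating"]):
        try:
            r = Rating(rating.strip().lower())
        except ValueError as exc:
            raise FormatError(f"{path}: unknown rating {rating!r}") from exc
        norm = normalize_code(code)
        if norm in entries and entries[norm] != r:
            raise FormatError(f"{path}: code {norm!r} rated more than once")
        entries[norm] = r
    return AssociationRatings(entries=entries)


def write_association_ratings(ratings: AssociationRatings, path: str | Path) -> None:
    pd.DataFrame(
        sorted((c, r.value) for c, r in ratings.entries.items()),
        columns=["code", "rating"],
    ).to_csv(path, index=False)
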