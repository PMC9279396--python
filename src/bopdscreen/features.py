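"""Boolean feature engineering for the screening classifier.

The feature vocabulary combines:

* demographic bins — age band at the last study-period encounter
  (18-39 / 40-59 / 60-65) and a female indicator;
* encounter-frequency bins (low / median / high) with tertile cutoffs of
  the distinct-discharge-date counts frozen from a training cohort;
* encounter-type presence (emergency, inpatient, outpatient/other);
* diagnosis-group features — the prevalence-filtered ICD-10-CM codes are
  mapped to their default CCSR category, each category is further split by
  the expert association rating (positive / negative / unrelated / unsure),
  and each non-empty (category x rating) cell becomes one Boolean feature
  that fires when the patient has any member code in the study period.

Every feature is Boolean, and the fitted specification round-trips through
JSON so new data can be featurized identically later.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ehr import (
    AssociationRatings,
    CcsrMap,
    CodeSystem,
    Gender,
    PatientRecord,
    Rating,
    StudyConfig,
    age_at,
)

logger = logging.getLogger(__name__)

__all__ = [
    "UNMAPPED_CATEGORY",
    "Feature",
    "FeatureSpec",
    "select_prevalent_codes",
    "build_feature_spec",
    "featurize",
]

UNMAPPED_CATEGORY = "UNMAPPED"

_RATING_ORDER = [Rating.POSITIVE, Rating.NEGATIVE, Rating.UNRELATED, Rating.UNSURE]


@dataclass(frozen=True)
class Feature:
    """One Boolean feature.

    ``kind`` is one of ``age_band``, ``gender``, ``encounter_frequency``,
    ``encounter_type`` or ``diagnosis_group``; ``params`` carries the
    kind-specific definition (band label, type label, or category/rating
    plus the sorted member code tuple).
    """

    name: str
    kind: str
    params: tuple = ()


@dataclass
class FeatureSpec:
    """Ordered feature definitions plus frozen frequency-bin cutoffs."""

    features: list[Feature]
    freq_cutoffs: tuple[float, float]

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def diagnosis_features(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "diagnosis_group"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "freq_cutoffs": list(self.freq_cutoffs),
            "features": [
                {"name": f.name, "kind": f.kind, "params": list(f.params)}
                for f in self.features
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSpec":
        with open(path) as fh:
            payload = json.load(fh)
        features = [
            Feature(
                name=f["name"],
                kind=f["kind"],
                params=tuple(
                    tuple(p) if isinstance(p, list) else p for p in f["params"]
                ),
            )
            for f in payload["features"]
        ]
        return cls(features=features, freq_cutoffs=tuple(payload["freq_cutoffs"]))


def _study_period_icd10_codes(
    patient: PatientRecord, config: StudyConfig
) -> set[str]:
    dates = {e.encounter_id: e.discharge_date for e in patient.encounters}
    return {
        dx.code
        for dx in patient.diagnoses
        if dx.code_system is CodeSystem.ICD10CM
        and config.in_study_period(dates[dx.encounter_id])
    }


def select_prevalent_codes(
    cohort_a: Sequence[PatientRecord],
    cohort_b: Sequence[PatientRecord],
    config: StudyConfig,
) -> set[str]:
    """Union of ICD-10-CM codes prevalent (>= cutoff) in either cohort.

    Prevalence is patient-level: the fraction of the cohort with at least
    one study-period event of the code; the cutoff is inclusive.
    """
    selected: set[str] = set()
    for cohort in (cohort_a, cohort_b):
        if not cohort:
            raise ValueError("prevalence requires a non-empty cohort")
        counts: dict[str, int] = {}
        for p in cohort:
            for code in _study_period_icd10_codes(p, config):
                counts[code] = counts.get(code, 0) + 1
        n = len(cohort)
        selected.update(
            c for c, k in counts.items() if k / n >= config.prevalence_cutoff
        )
    return selected


def _distinct_date_count(patient: PatientRecord, config: StudyConfig) -> int:
    """Distinct discharge dates of diagnosis-bearing study-period encounters."""
    return len(
        {
            e.discharge_date
            for e in patient.encounters_with_diagnoses()
            if config.in_study_period(e.discharge_date)
        }
    )


def build_feature_spec(
    codes: Iterable[str],
    ccsr_map: CcsrMap,
    ratings: AssociationRatings,
    training_cohort: Sequence[PatientRecord],
    config: StudyConfig,
) -> FeatureSpec:
    """Build the full Boolean feature specification.

    Diagnosis features partition the selected codes into (CCSR category x
    association rating) cells; codes absent from the CCSR map fall into a
    reserved UNMAPPED category, and unrated codes default to ``unsure``.
    Encounter-frequency cutoffs are the tertiles of the training cohort's
    distinct-discharge-date counts, frozen into the spec.
    """
    cells: dict[tuple[str, str], set[str]] = {}
    for code in codes:
        cat = ccsr_map.category(code)
        if cat is None:
            logger.warning(
                "code %s missing from CCSR map; assigned to %s",
                code,
                UNMAPPED_CATEGORY,
            )
            cat = UNMAPPED_CATEGORY
        rating = ratings.rating(code, default=Rating.UNSURE)
        cells.setdefault((cat, rating.value), set()).add(code)

    counts = [_distinct_date_count(p, config) for p in training_cohort]
    if not counts:
        raise ValueError("training cohort must be non-empty")
    c1, c2 = np.quantile(counts, [1 / 3, 2 / 3])

    features: list[Feature] = [
        Feature("age:18-39", "age_band", ("18-39",)),
        Feature("age:40-59", "age_band", ("40-59",)),
        Feature("age:60-65", "age_band", ("60-65",)),
        Feature("gender:female", "gender", ("female",)),
        Feature("enc_freq:low", "encounter_frequency", ("low",)),
        Feature("enc_freq:median", "encounter_frequency", ("median",)),
        Feature("enc_freq:high", "encounter_frequency", ("high",)),
        Feature("enc_type:emergency", "encounter_type", ("emergency",)),
        Feature("enc_type:inpatient", "encounter_type", ("inpatient",)),
        Feature("enc_type:outpatient_other", "encounter_type", ("outpatient_other",)),
    ]
    rating_rank = {r.value: i for i, r in enumerate(_RATING_ORDER)}
    for (cat, rating), members in sorted(
        cells.items(), key=lambda kv: (kv[0][0], rating_rank[kv[0][1]])
    ):
        features.append(
            Feature(
                name=f"dx:{cat}:{rating}",
                kind="diagnosis_group",
                params=(cat, rating, tuple(sorted(members))),
            )
        )
    return FeatureSpec(features=features, freq_cutoffs=(float(c1), float(c2)))


def _freq_bin(count: int, cutoffs: tuple[float, float]) -> str:
    # boundary counts fall to the lower bin
    if count <= cutoffs[0]:
        return "low"
    if count <= cutoffs[1]:
        return "median"
    return "high"


def featurize(
    patients: Sequence[PatientRecord],
    spec: FeatureSpec,
    config: StudyConfig,
) -> pd.DataFrame:
    """Boolean feature matrix (patients x spec features).

    Row index is the patient id in input order; columns follow the spec
    order exactly. Patients with no study-period events get all-false
    diagnosis, age and encounter features.
    """
    rows = np.zeros((len(patients), len(spec.features)), dtype=bool)
    col = {f.name: i for i, f in enumerate(spec.features)}
    for i, p in enumerate(patients):
        period_encounters = [
            e for e in p.encounters if config.in_study_period(e.discharge_date)
        ]
        if period_encounters:
            age = age_at(p, max(e.discharge_date for e in period_encounters))
            if age <= 39:
                rows[i, col["age:18-39"]] = True
            elif age <= 59:
                rows[i, col["age:40-59"]] = True
            else:
                rows[i, col["age:60-65"]] = True
        rows[i, col["gender:female"]] = p.gender is Gender.FEMALE
        n_dates = _distinct_date_count(p, config)
        if n_dates:
            rows[i, col[f"enc_freq:{_freq_bin(n_dates, spec.freq_cutoffs)}"]] = True
        for e in period_encounters:
            rows[i, col[f"enc_type:{e.encounter_type.value}"]] = True
        codes = _study_period_icd10_codes(p, config)
        for f in spec.features:
            if f.kind == "diagnosis_group" and codes.intersection(f.params[2]):
                rows[i, col[f.name]] = True
    return pd.DataFrame(
        rows, index=[p.patient_id for p in patients], columns=spec.names
    )
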