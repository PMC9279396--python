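"""Rule engine for cohort selection.

Implements the staged inclusion/exclusion funnel that defines the *potential
BoPD cohort* (patients without a BoPD code whose comorbidity and encounter
history suggests possible undiagnosed borderline personality disorder), the
*EHR-diagnosed BoPD cohort* (patients carrying F60.3 in the study period),
and the rule-selected *silver-positive* subset of the diagnosed cohort.

Inclusion criteria for the potential cohort:

i.   >= 5 encounters on distinct discharge dates, or >= 2 emergency visits on
     distinct discharge dates, in the study period (only encounters carrying
     at least one diagnosis code count);
ii.  any diagnosis in the BoPD-associated CCSR mental-disorder categories at
     age 18-65 in the study period;
iii. a suicidal / intentional self-harm code (MBD012/MBD027) or bipolar code
     (MBD003) in the study period; or, failing that,
iv.  diagnoses in at least 3 of the associated mental-disorder groups.

Exclusions: any BoPD code (ICD-10-CM F60.3 / ICD-9-CM 301.83) anywhere in
the record, and any study-period code in F01-F09 (mental disorders due to
physiological conditions) or F70-F79 (intellectual disabilities).

Group counting follows the published category table: the substance-related
CCSR categories count as ONE combined group, and MBD012+MBD027 count jointly
as one suicidal/self-harm group.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .ehr import (
    CcsrMap,
    CodeSystem,
    PatientRecord,
    StudyConfig,
    age_at,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SUICIDAL_CATEGORIES",
    "BIPOLAR_CATEGORY",
    "SUBSTANCE_CATEGORIES",
    "TABLE_CATEGORIES",
    "BOPD_ICD10",
    "BOPD_ICD9",
    "MentalDisorderProfile",
    "CohortSelectionResult",
    "encounter_criterion",
    "mental_disorder_profile",
    "exclusion_criterion",
    "select_potential_cohort",
    "select_diagnosed_cohort",
    "select_silver_positives",
]

# BoPD-associated CCSR mental-disorder categories
SUICIDAL_CATEGORIES = frozenset({"MBD012", "MBD027"})
BIPOLAR_CATEGORY = "MBD003"
SUBSTANCE_CATEGORIES = frozenset(
    {"MBD017", "MBD018", "MBD019", "MBD020", "MBD021", "MBD022", "MBD023", "MBD025"}
)
_SINGLE_CATEGORIES = frozenset(
    {"MBD002", "MBD003", "MBD004", "MBD005", "MBD007", "MBD008", "MBD009"}
)
TABLE_CATEGORIES = _SINGLE_CATEGORIES | SUICIDAL_CATEGORIES | SUBSTANCE_CATEGORIES

BOPD_ICD10 = "F603"
BOPD_ICD9 = "30183"

# normalized 3-character prefixes excluded in the study period
_EXCLUDED_PREFIXES = frozenset(
    {f"F0{i}" for i in range(1, 10)} | {f"F7{i}" for i in range(0, 10)}
)


@dataclass(frozen=True)
class MentalDisorderProfile:
    """BoPD-associated CCSR categories observed for one patient.

    ``categories_present`` holds the raw CCSR category codes; ``n_groups``
    collapses them to the published group structure (substance categories as
    one combined group, MBD012/MBD027 as one suicidal/self-harm group).
    """

    categories_present: frozenset[str]
    has_suicidal_selfharm: bool
    has_bipolar: bool

    @property
    def n_groups(self) -> int:
        groups: set[str] = set()
        for cat in self.categories_present:
            if cat in SUBSTANCE_CATEGORIES:
                groups.add("SUBSTANCE")
            elif cat in SUICIDAL_CATEGORIES:
                groups.add("SUICIDAL")
            else:
                groups.add(cat)
        return len(groups)


@dataclass
class CohortSelectionResult:
    included_ids: set[str]
    per_patient_trace: dict[str, list[tuple[str, bool]]]
    counts_per_stage: dict[str, int]

    @property
    def n_input(self) -> int:
        return len(self.per_patient_trace)


def _coded_study_encounters(
    patient: PatientRecord, config: StudyConfig
) -> list:
    """Study-period encounters carrying at least one diagnosis code."""
    return [
        e
        for e in patient.encounters_with_diagnoses()
        if config.in_study_period(e.discharge_date)
    ]


def encounter_criterion(patient: PatientRecord, config: StudyConfig) -> bool:
    """Sufficient-history rule (criterion i).

    True iff the patient has >= ``min_encounter_dates`` distinct discharge
    dates, or >= ``min_emergency_dates`` distinct emergency discharge dates,
    among diagnosis-bearing encounters in the study period.
    """
    coded = _coded_study_encounters(patient, config)
    all_dates = {e.discharge_date for e in coded}
    er_dates = {
        e.discharge_date for e in coded if e.encounter_type.value == "emergency"
    }
    return (
        len(all_dates) >= config.min_encounter_dates
        or len(er_dates) >= config.min_emergency_dates
    )


def mental_disorder_profile(
    patient: PatientRecord,
    ccsr_map: CcsrMap,
    config: StudyConfig,
    *,
    ignore_bopd_code: bool = False,
) -> MentalDisorderProfile:
    """BoPD-associated categories with a study-period diagnosis at age 18-65.

    ICD-10-CM codes only; unmapped codes and categories outside the
    association table contribute nothing. With ``ignore_bopd_code`` the F60.3
    events themselves are skipped (used when profiling the diagnosed cohort
    for silver-positive selection).
    """
    enc_dates = {
        e.encounter_id: e.discharge_date for e in patient.encounters
    }
    cats: set[str] = set()
    for dx in patient.diagnoses:
        if dx.code_system is not CodeSystem.ICD10CM:
            continue
        if ignore_bopd_code and dx.code == BOPD_ICD10:
            continue
        date = enc_dates.get(dx.encounter_id)
        if date is None or not config.in_study_period(date):
            continue
        if date < patient.birth_date:
            continue
        if not config.age_low <= age_at(patient, date) <= config.age_high:
            continue
        cat = ccsr_map.category(dx.code)
        if cat is None:
            logger.debug(
                "patient %s: unmapped code %s ignored", patient.patient_id, dx.code
            )
            continue
        if cat in TABLE_CATEGORIES:
            cats.add(cat)
    return MentalDisorderProfile(
        categories_present=frozenset(cats),
        has_suicidal_selfharm=bool(cats & SUICIDAL_CATEGORIES),
        has_bipolar=BIPOLAR_CATEGORY in cats,
    )


def _has_bopd_code_ever(patient: PatientRecord) -> bool:
    return any(
        (dx.code_system is CodeSystem.ICD10CM and dx.code == BOPD_ICD10)
        or (dx.code_system is CodeSystem.ICD9CM and dx.code == BOPD_ICD9)
        for dx in patient.diagnoses
    )


def _has_bopd_code_in_period(patient: PatientRecord, config: StudyConfig) -> bool:
    enc_dates = patient.encounter_by_id
    return any(
        dx.code_system is CodeSystem.ICD10CM
        and dx.code == BOPD_ICD10
        and config.in_study_period(enc_dates[dx.encounter_id].discharge_date)
        for dx in patient.diagnoses
    )


def _has_excluded_prefix_in_period(
    patient: PatientRecord, config: StudyConfig
) -> bool:
    enc_dates = patient.encounter_by_id
    return any(
        dx.code_system is CodeSystem.ICD10CM
        and dx.code[:3] in _EXCLUDED_PREFIXES
        and config.in_study_period(enc_dates[dx.encounter_id].discharge_date)
        for dx in patient.diagnoses
    )


def exclusion_criterion(
    patient: PatientRecord, config: StudyConfig
) -> tuple[bool, str | None]:
    """Exclusion rules for the potential cohort.

    A prior BoPD code (F60.3 / 301.83) excludes over the entire record; the
    F01-F09 and F70-F79 prefix ranges exclude within the study period.
    Returns ``(excluded, reason)``.
    """
    if _has_bopd_code_ever(patient):
        return True, "prior BoPD code"
    if _has_excluded_prefix_in_period(patient, config):
        return True, "physiological/intellectual-disability code"
    return False, None


def _symptom_or_category_rule(
    profile: MentalDisorderProfile, config: StudyConfig
) -> bool:
    return (
        profile.has_suicidal_selfharm
        or profile.has_bipolar
        or profile.n_groups >= config.min_other_categories
    )


def select_potential_cohort(
    patients: Iterable[PatientRecord],
    ccsr_map: CcsrMap,
    config: StudyConfig,
) -> CohortSelectionResult:
    """Staged selection of the potential BoPD cohort.

    Stage order: mental-disorder presence -> sufficient encounter history ->
    suicidal/bipolar-or-3-categories rule -> exclusions. The trace records
    every rule outcome for every patient; the funnel counts survivors after
    each stage in order.
    """
    stages = [
        "mental_disorder",
        "encounter_history",
        "symptom_or_category",
        "no_exclusion",
    ]
    trace: dict[str, list[tuple[str, bool]]] = {}
    counts = {s: 0 for s in stages}
    included: set[str] = set()
    for p in patients:
        profile = mental_disorder_profile(p, ccsr_map, config)
        excluded, _ = exclusion_criterion(p, config)
        outcomes = [
            ("mental_disorder", bool(profile.categories_present)),
            ("encounter_history", encounter_criterion(p, config)),
            ("symptom_or_category", _symptom_or_category_rule(profile, config)),
            ("no_exclusion", not excluded),
        ]
        trace[p.patient_id] = outcomes
        surviving = True
        for stage, ok in outcomes:
            surviving = surviving and ok
            if surviving:
                counts[stage] += 1
        if surviving:
            included.add(p.patient_id)
    return CohortSelectionResult(
        included_ids=included, per_patient_trace=trace, counts_per_stage=counts
    )


def select_diagnosed_cohort(
    patients: Iterable[PatientRecord],
    ccsr_map: CcsrMap,
    config: StudyConfig,
) -> CohortSelectionResult:
    """Patients with an F60.3 diagnosis in the study period.

    The age, encounter-history and physiological/intellectual-disability
    exclusion criteria are shared with the potential cohort; the BoPD code
    itself is of course not an exclusion here.
    """
    stages = [
        "bopd_code_in_period",
        "encounter_history",
        "mental_disorder",
        "no_exclusion",
    ]
    trace: dict[str, list[tuple[str, bool]]] = {}
    counts = {s: 0 for s in stages}
    included: set[str] = set()
    for p in patients:
        profile = mental_disorder_profile(p, ccsr_map, config)
        outcomes = [
            ("bopd_code_in_period", _has_bopd_code_in_period(p, config)),
            ("encounter_history", encounter_criterion(p, config)),
            ("mental_disorder", bool(profile.categories_present)),
            ("no_exclusion", not _has_excluded_prefix_in_period(p, config)),
        ]
        trace[p.patient_id] = outcomes
        surviving = True
        for stage, ok in outcomes:
            surviving = surviving and ok
            if surviving:
                counts[stage] += 1
        if surviving:
            included.add(p.patient_id)
    return CohortSelectionResult(
        included_ids=included, per_patient_trace=trace, counts_per_stage=counts
    )


def select_silver_positives(
    diagnosed_patients: Iterable[PatientRecord],
    ccsr_map: CcsrMap,
    config: StudyConfig,
) -> set[str]:
    """Rule-selected silver positives from the diagnosed cohort.

    Re-applies the suicidal/bipolar-or-3-categories rule with all F60.3
    events ignored, so a patient whose only mental-disorder evidence is the
    BoPD code itself is dropped.
    """
    kept: set[str] = set()
    for p in diagnosed_patients:
        profile = mental_disorder_profile(
            p, ccsr_map, config, ignore_bopd_code=True
        )
        if profile.categories_present and _symptom_or_category_rule(
            profile, config
        ):
            kept.add(p.patient_id)
    return kept
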