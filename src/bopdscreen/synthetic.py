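"""Synthetic EHR generator.

Emulates the statistical structure the screening pipeline assumes: multi-year
encounter histories with emergency/inpatient/outpatient types, ICD-10-CM
mental-disorder codes drawn from the BoPD-associated CCSR categories plus
psychotic and physical-illness codes, demographics, and planted latent
classes aligned with the expert chart-review categories:

* ``bopd_like``            -> rated E (most likely BoPD; classic subflag for
                              the most severe generated profiles),
* ``psychotic_substance``  -> rated B (severe psychotic/substance abuse),
* ``physical_primary``     -> rated A (primarily physical condition),
* ``other_mental``         -> rated C or D,
* ``healthy``              -> sparse histories, rarely enters any cohort.

A configurable fraction of ``bopd_like`` patients carry the F60.3 diagnosis
code and thereby form the EHR-diagnosed cohort; the rest are the undiagnosed
cases the screening step is meant to find. A miniature in-repo code table
(~60 ICD-10-CM-shaped codes) stands in for the full CCSR mapping; a real
``ccsr_map.csv`` can be dropped in instead.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import BOPD_ICD10, TABLE_CATEGORIES, mental_disorder_profile
from .ehr import (
    AssociationRatings,
    CcsrMap,
    CodeSystem,
    DiagnosisEvent,
    Encounter,
    EncounterType,
    Gender,
    PatientRecord,
    Rating,
    StudyConfig,
)
from .sampling import RatingCategory, RatingLabel

logger = logging.getLogger(__name__)

__all__ = [
    "CODE_TABLE",
    "ASSOCIATION_TABLE",
    "ClassProfile",
    "SimConfig",
    "SyntheticTruth",
    "fixture_ccsr_map",
    "fixture_association_ratings",
    "generate_cohort",
    "generate_ratings",
    "potential_fraction",
    "planted_logistic_features",
]

# ---------------------------------------------------------------------------
# miniature ICD-10-CM-shaped code table covering the BoPD-associated CCSR
# categories plus psychotic, physical-illness and exclusion-range codes
# ---------------------------------------------------------------------------
CODE_TABLE: dict[str, str] = {
    # depressive disorders
    "F320": "MBD002", "F321": "MBD002", "F329": "MBD002",
    "F331": "MBD002", "F332": "MBD002", "F339": "MBD002",
    # bipolar and related disorders
    "F310": "MBD003", "F313": "MBD003", "F3181": "MBD003", "F319": "MBD003",
    # other specified and unspecified mood disorders
    "F340": "MBD004", "F341": "MBD004", "F39": "MBD004",
    # anxiety and fear-related disorders
    "F410": "MBD005", "F411": "MBD005", "F419": "MBD005",
    "F4001": "MBD005", "F408": "MBD005",
    # trauma- and stressor-related disorders
    "F4310": "MBD007", "F4312": "MBD007", "F4321": "MBD007", "F4325": "MBD007",
    # disruptive, impulse-control and conduct disorders
    "F630": "MBD008", "F632": "MBD008", "F911": "MBD008", "F919": "MBD008",
    # personality disorders (F603 is the BoPD code itself)
    "F603": "MBD009", "F601": "MBD009", "F605": "MBD009", "F609": "MBD009",
    # suicidal ideation / intentional self-harm
    "R45851": "MBD012",
    "T360X2A": "MBD027", "T50992A": "MBD027", "X780XXA": "MBD027",
    # combined substance-related categories
    "F1010": "MBD017", "F1020": "MBD017", "F10129": "MBD017",
    "F1110": "MBD018", "F1120": "MBD018",
    "F1210": "MBD019", "F1220": "MBD019",
    "F1310": "MBD020",
    "F1510": "MBD021", "F1520": "MBD021",
    "F1610": "MBD022",
    "F1810": "MBD023",
    "F1910": "MBD025", "F1990": "MBD025",
    # schizophrenia-spectrum / psychotic (outside the association table)
    "F200": "MBD001", "F209": "MBD001", "F22": "MBD001",
    "F23": "MBD001", "F259": "MBD001", "F29": "MBD001",
    # physical illness
    "E119": "END002", "E785": "END010", "I10": "CIR007",
    "J449": "RSP008", "J069": "RSP006", "K219": "DIG004",
    "M545": "MUS011", "N390": "GEN004", "R079": "SYM012", "R51": "SYM009",
    # exclusion ranges: physiological mental disorders / intellectual disability
    "F059": "NVS011", "F0390": "NVS011", "F719": "MBD010", "F79": "MBD010",
}

_PHYSICAL_CODES = ("E119", "E785", "I10", "J449", "J069", "K219", "M545",
                   "N390", "R079", "R51")
_PSYCHOTIC_CODES = ("F200", "F209", "F22", "F23", "F259", "F29")
_EXCLUSION_CODES = ("F059", "F0390", "F719", "F79")

# expert-style association ratings for the fixture codes
ASSOCIATION_TABLE: dict[str, Rating] = {
    **{c: Rating.POSITIVE for c in (
        "F320", "F329", "F331",              # depressive
        "F310", "F313", "F3181", "F319",     # bipolar
        "F4310", "F4312", "F4321", "F4325",  # trauma
        "F630", "F632", "F911", "F919",      # impulse-control
        "F601", "F605", "F609", "F603",      # personality
        "R45851", "T360X2A", "T50992A", "X780XXA",  # suicidal/self-harm
        "F410", "F411",                      # anxiety
    )},
    **{c: Rating.NEGATIVE for c in (
        "F4001", "F408",                     # agoraphobia/phobias
        *_PSYCHOTIC_CODES,
        "F1010", "F1020", "F10129", "F1110", "F1120", "F1210", "F1220",
        "F1310", "F1510", "F1520", "F1610", "F1810", "F1910", "F1990",
    )},
    **{c: Rating.UNRELATED for c in (*_PHYSICAL_CODES, *_EXCLUSION_CODES)},
    **{c: Rating.UNSURE for c in (
        "F321", "F332", "F339", "F340", "F341", "F39", "F419",
    )},
}


def fixture_ccsr_map() -> CcsrMap:
    return CcsrMap(entries=dict(CODE_TABLE))


def fixture_association_ratings() -> AssociationRatings:
    return AssociationRatings(entries=dict(ASSOCIATION_TABLE))


_CODES_BY_CATEGORY: dict[str, tuple[str, ...]] = {}
for _code, _cat in CODE_TABLE.items():
    if _code == BOPD_ICD10:
        continue  # the target code is only ever planted via diagnosed labeling
    _CODES_BY_CATEGORY.setdefault(_cat, ())
    _CODES_BY_CATEGORY[_cat] += (_code,)


@dataclass(frozen=True)
class ClassProfile:
    """Generative parameters for one latent class."""

    weight: float
    category_probs: Mapping[str, float]  # CCSR category -> P(any code)
    mean_encounters: float
    emergency_frac: float
    inpatient_frac: float
    female_prob: float
    age_range: tuple[float, float]  # age at study start, years
    physical_prob: float = 0.6
    psychotic_prob: float = 0.0
    exclusion_prob: float = 0.01
    coded_encounter_frac: float = 0.92  # encounters carrying >= 1 code


def _default_profiles() -> dict[str, ClassProfile]:
    return {
        "bopd_like": ClassProfile(
            weight=0.16,
            category_probs={
                "MBD002": 0.80, "MBD003": 0.50, "MBD004": 0.25,
                "MBD005": 0.60, "MBD007": 0.45, "MBD008": 0.25,
                "MBD009": 0.30, "MBD012": 0.40, "MBD027": 0.25,
                "MBD017": 0.20, "MBD019": 0.15, "MBD021": 0.08,
            },
            mean_encounters=11.0, emergency_frac=0.30, inpatient_frac=0.08,
            female_prob=0.72, age_range=(18.0, 55.0),
            physical_prob=0.50, psychotic_prob=0.05,
        ),
        "psychotic_substance": ClassProfile(
            weight=0.08,
            category_probs={
                "MBD002": 0.45, "MBD003": 0.22, "MBD004": 0.25,
                "MBD005": 0.35, "MBD007": 0.15, "MBD008": 0.10,
                "MBD009": 0.10, "MBD012": 0.18, "MBD027": 0.12,
                "MBD017": 0.60, "MBD018": 0.25, "MBD019": 0.30,
                "MBD021": 0.30, "MBD025": 0.15,
            },
            mean_encounters=10.0, emergency_frac=0.35, inpatient_frac=0.12,
            female_prob=0.45, age_range=(20.0, 60.0),
            physical_prob=0.50, psychotic_prob=0.85, exclusion_prob=0.02,
        ),
        "physical_primary": ClassProfile(
            weight=0.25,
            category_probs={
                "MBD002": 0.60, "MBD003": 0.02, "MBD004": 0.30,
                "MBD005": 0.55, "MBD007": 0.20, "MBD008": 0.05,
                "MBD009": 0.03, "MBD012": 0.01,
                "MBD017": 0.10, "MBD019": 0.05,
            },
            mean_encounters=9.0, emergency_frac=0.18, inpatient_frac=0.10,
            female_prob=0.55, age_range=(25.0, 70.0),
            physical_prob=0.95, psychotic_prob=0.01, exclusion_prob=0.04,
        ),
        "other_mental": ClassProfile(
            weight=0.29,
            category_probs={
                "MBD002": 0.70, "MBD003": 0.08, "MBD004": 0.30,
                "MBD005": 0.65, "MBD007": 0.30, "MBD008": 0.15,
                "MBD009": 0.08, "MBD012": 0.05, "MBD027": 0.03,
                "MBD017": 0.12, "MBD019": 0.08,
            },
            mean_encounters=8.0, emergency_frac=0.20, inpatient_frac=0.06,
            female_prob=0.60, age_range=(18.0, 65.0),
            physical_prob=0.60, psychotic_prob=0.02,
        ),
        "healthy": ClassProfile(
            weight=0.22,
            category_probs={"MBD005": 0.03},
            mean_encounters=3.0, emergency_frac=0.10, inpatient_frac=0.03,
            female_prob=0.52, age_range=(18.0, 70.0),
            physical_prob=0.80, psychotic_prob=0.0,
        ),
    }


@dataclass
class SimConfig:
    """Study conditions for the synthetic-EHR generator.

    Defaults are chosen so that, after rule-based selection, the potential
    cohort's latent composition resembles the chart-review category mix
    (roughly 29% most-likely-BoPD) and the diagnosed cohort supplies a
    rule-selected silver-positive pool.
    """

    n_patients: int = 6000
    study_start: datetime.date = datetime.date(2015, 10, 1)
    study_end: datetime.date = datetime.date(2018, 7, 11)
    class_profiles: dict[str, ClassProfile] = field(default_factory=_default_profiles)
    diagnosed_bopd_prob: float = 0.35  # bopd_like fraction carrying F60.3
    historic_bopd_prob: float = 0.01   # stray BoPD codes in other classes
    rating_noise: float = 0.05
    unknown_gender_prob: float = 0.005
    pre_period_frac: float = 0.15      # encounters before the study window
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_patients <= 0:
            bad.append("n_patients")
        if self.study_start >= self.study_end:
            bad.append("study_start/study_end")
        weights = [p.weight for p in self.class_profiles.values()]
        if not np.isclose(sum(weights), 1.0) or any(w < 0 for w in weights):
            bad.append("class_profiles.weight")
        for prob in (
            "diagnosed_bopd_prob", "historic_bopd_prob", "rating_noise",
            "unknown_gender_prob", "pre_period_frac",
        ):
            if not 0.0 <= getattr(self, prob) <= 1.0:
                bad.append(prob)
        for name, prof in self.class_profiles.items():
            if prof.mean_encounters <= 0:
                bad.append(f"class_profiles[{name}].mean_encounters")
            if any(not 0 <= p <= 1 for p in prof.category_probs.values()):
                bad.append(f"class_profiles[{name}].category_probs")
        if bad:
            raise ValueError(f"invalid SimConfig fields: {', '.join(bad)}")

    def study_config(self, **overrides) -> StudyConfig:
        return StudyConfig(
            study_start=self.study_start, study_end=self.study_end, **overrides
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth: latent class per patient + class parameters."""

    classes: dict[str, str]
    class_profiles: dict[str, ClassProfile]


def _encounter_count(rng: np.random.Generator, mean: float) -> int:
    # negative-binomial-shaped counts create the low/median/high spread
    r = 3.0
    p = r / (r + mean - 1.0)
    return 1 + int(rng.negative_binomial(r, p))


def _random_date(
    rng: np.random.Generator, sim: SimConfig
) -> datetime.date:
    window = (sim.study_end - sim.study_start).days
    if rng.random() < sim.pre_period_frac:
        offset = -int(rng.integers(1, 540))
    else:
        offset = int(rng.integers(0, window + 1))
    return sim.study_start + datetime.timedelta(days=offset)


def _generate_patient(
    pid: str,
    cls: str,
    prof: ClassProfile,
    sim: SimConfig,
    rng: np.random.Generator,
) -> PatientRecord:
    if rng.random() < sim.unknown_gender_prob:
        gender = Gender.UNKNOWN_OTHER
    else:
        gender = Gender.FEMALE if rng.random() < prof.female_prob else Gender.MALE
    age0 = rng.uniform(*prof.age_range)
    birth_date = sim.study_start - datetime.timedelta(days=round(age0 * 365.25))

    n_enc = _encounter_count(rng, prof.mean_encounters)
    encounters = []
    for j in range(n_enc):
        u = rng.random()
        if u < prof.emergency_frac:
            etype = EncounterType.EMERGENCY
        elif u < prof.emergency_frac + prof.inpatient_frac:
            etype = EncounterType.INPATIENT
        else:
            etype = EncounterType.OUTPATIENT_OTHER
        encounters.append(
            Encounter(
                encounter_id=f"{pid}e{j}",
                patient_id=pid,
                encounter_type=etype,
                discharge_date=_random_date(rng, sim),
            )
        )

    enc_ids = [e.encounter_id for e in encounters]
    dx: list[DiagnosisEvent] = []

    def emit(code: str, n_events: int) -> None:
        for eid in rng.choice(enc_ids, size=min(n_events, len(enc_ids)), replace=False):
            dx.append(
                DiagnosisEvent(
                    patient_id=pid,
                    encounter_id=str(eid),
                    code_system=CodeSystem.ICD10CM,
                    code=code,
                )
            )

    for cat, p in prof.category_probs.items():
        if rng.random() < p:
            code = str(rng.choice(_CODES_BY_CATEGORY[cat]))
            emit(code, int(rng.integers(1, 4)))
    if rng.random() < prof.psychotic_prob:
        emit(str(rng.choice(_PSYCHOTIC_CODES)), int(rng.integers(1, 4)))
    if rng.random() < prof.physical_prob:
        for code in rng.choice(
            _PHYSICAL_CODES, size=int(rng.integers(1, 3)), replace=False
        ):
            emit(str(code), int(rng.integers(1, 3)))
    if rng.random() < prof.exclusion_prob:
        emit(str(rng.choice(_EXCLUSION_CODES)), 1)

    if cls == "bopd_like" and rng.random() < sim.diagnosed_bopd_prob:
        emit(BOPD_ICD10, int(rng.integers(1, 3)))
    elif cls != "bopd_like" and rng.random() < sim.historic_bopd_prob:
        # stray historic BoPD code exercises the "ever" exclusion
        eid = str(rng.choice(enc_ids))
        dx.append(
            DiagnosisEvent(
                patient_id=pid,
                encounter_id=eid,
                code_system=CodeSystem.ICD9CM,
                code="30183",
            )
        )

    # fill otherwise-empty encounters so most carry at least one code
    coded = {d.encounter_id for d in dx}
    for e in encounters:
        if e.encounter_id not in coded and rng.random() < prof.coded_encounter_frac:
            dx.append(
                DiagnosisEvent(
                    patient_id=pid,
                    encounter_id=e.encounter_id,
                    code_system=CodeSystem.ICD10CM,
                    code=str(rng.choice(_PHYSICAL_CODES)),
                )
            )

    # canonical ordering matches the flat-file reader's, so generated
    # records round-trip bit-identically through the interchange format
    encounters.sort(key=lambda e: (e.discharge_date, e.encounter_id))
    dx.sort(key=lambda d: (d.encounter_id, d.code_system.value, d.code))
    return PatientRecord(
        patient_id=pid,
        gender=gender,
        birth_date=birth_date,
        encounters=tuple(encounters),
        diagnoses=tuple(dx),
    )


def generate_cohort(
    sim: SimConfig,
) -> tuple[list[PatientRecord], SyntheticTruth, CcsrMap, AssociationRatings]:
    """Generate a synthetic cohort with its knowledge-table fixtures."""
    sim.validate()
    rng = np.random.default_rng(sim.seed)
    names = list(sim.class_profiles)
    weights = np.array([sim.class_profiles[n].weight for n in names])
    weights = weights / weights.sum()
    assignments = rng.choice(len(names), size=sim.n_patients, p=weights)

    width = len(str(sim.n_patients))
    records: list[PatientRecord] = []
    classes: dict[str, str] = {}
    for i, k in enumerate(assignments):
        pid = f"p{i:0{width}d}"
        cls = names[k]
        classes[pid] = cls
        records.append(
            _generate_patient(pid, cls, sim.class_profiles[cls], sim, rng)
        )
    truth = SyntheticTruth(classes=classes, class_profiles=dict(sim.class_profiles))
    return records, truth, fixture_ccsr_map(), fixture_association_ratings()


_CLASS_TO_CATEGORY = {
    "bopd_like": RatingCategory.E,
    "psychotic_substance": RatingCategory.B,
    "physical_primary": RatingCategory.A,
    "healthy": RatingCategory.A,
}


def generate_ratings(
    patients: Sequence[PatientRecord],
    truth: SyntheticTruth,
    sim: SimConfig,
    seed: int | None = None,
) -> list[RatingLabel]:
    """Expert-style chart-review labels derived from the latent classes.

    The deterministic map sends ``bopd_like`` to E (classic subflag when the
    generated profile shows self-harm plus at least four comorbidity
    groups), ``psychotic_substance`` to B, ``physical_primary`` and
    ``healthy`` to A, and ``other_mental`` to D (C when the record shows
    little to judge from). Each label is then flipped to a random *other*
    category with probability ``sim.rating_noise``.
    """
    rng = np.random.default_rng(sim.seed + 1 if seed is None else seed)
    config = sim.study_config()
    ccsr = fixture_ccsr_map()
    labels: list[RatingLabel] = []
    all_categories = list(RatingCategory)
    for p in patients:
        if p.patient_id not in truth.classes:
            raise ValueError(f"patient {p.patient_id!r} missing from truth")
        cls = truth.classes[p.patient_id]
        profile = mental_disorder_profile(p, ccsr, config, ignore_bopd_code=True)
        if cls == "other_mental":
            cat = (
                RatingCategory.D if profile.n_groups >= 2 else RatingCategory.C
            )
        else:
            cat = _CLASS_TO_CATEGORY[cls]
        classic = (
            cat is RatingCategory.E
            and profile.has_suicidal_selfharm
            and profile.n_groups >= 4
        )
        if rng.random() < sim.rating_noise:
            others = [c for c in all_categories if c is not cat]
            cat = others[int(rng.integers(0, len(others)))]
            classic = False
        labels.append(
            RatingLabel(patient_id=p.patient_id, category=cat, classic=classic)
        )
    return labels


def potential_fraction(sim: SimConfig, n: int, seed: int) -> float:
    """Monte-Carlo estimate of the potential-cohort fraction at size ``n``."""
    from .cohort import select_potential_cohort

    probe = dataclasses.replace(sim, n_patients=n, seed=seed)
    records, _, ccsr, _ = generate_cohort(probe)
    result = select_potential_cohort(records, ccsr, probe.study_config())
    return len(result.included_ids) / n


def planted_logistic_features(
    n: int,
    coef: Sequence[float],
    intercept: float,
    feature_prob: float | Sequence[float],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Boolean features with labels from a planted sparse logistic model."""
    coef = np.asarray(coef, dtype=float)
    X = rng.random((n, len(coef))) < np.broadcast_to(feature_prob, len(coef))
    z = X.astype(float) @ coef + intercept
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-z))).astype(int)
    return (
        pd.DataFrame(X, columns=[f"x{j}" for j in range(len(coef))]),
        y,
    )
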