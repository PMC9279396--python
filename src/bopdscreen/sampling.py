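"""Stratified chart-review sampling and expert rating labels.

Chart-review samples are drawn from the potential cohort by stratified
simple random sampling. Strata cross gender (female/male), age band
(18-39 / 40-59 / 60-65, at the last study-period encounter) and a
diagnostic-history class:

* ``N``  — no bipolar or suicidal/self-harm code, >= 3 associated groups;
* ``Y1`` — bipolar or suicidal/self-harm code and >= 3 associated groups;
* ``Y2`` — bipolar or suicidal/self-harm code and < 3 associated groups

(groups counted including the bipolar and suicidal/self-harm groups).
Patients of unknown/other gender are excluded from the sampling frame
before stratification.

Expert chart-review labels are the five mutually exclusive categories
A-E (A: primarily physical condition; B: severe psychotic/substance
abuse; C: unsure; D: possible BoPD; E: most likely BoPD, with a classic
subflag for E). The binary screening target is E vs. the rest.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import MentalDisorderProfile
from .ehr import FormatError, Gender, PatientRecord, RecordError, StudyConfig, age_at

logger = logging.getLogger(__name__)

__all__ = [
    "AgeBand",
    "HistoryClass",
    "Stratum",
    "RatingCategory",
    "RatingLabel",
    "assign_stratum",
    "stratified_sample",
    "stratified_train_test_pair",
    "read_ratings",
    "write_ratings",
]


class AgeBand(str, enum.Enum):
    YOUNG = "18-39"
    MIDDLE = "40-59"
    OLDER = "60-65"


class HistoryClass(str, enum.Enum):
    N = "N"
    Y1 = "Y1"
    Y2 = "Y2"


@dataclass(frozen=True, order=True)
class Stratum:
    gender: Gender
    age_band: AgeBand
    history_class: HistoryClass


class RatingCategory(str, enum.Enum):
    A = "A"  # not likely BoPD - primarily physical condition
    B = "B"  # not likely BoPD - severe psychotic/substance abuse
    C = "C"  # unsure - more information needed
    D = "D"  # possible BoPD
    E = "E"  # most likely BoPD


@dataclass(frozen=True)
class RatingLabel:
    patient_id: str
    category: RatingCategory
    classic: bool = False

    def __post_init__(self) -> None:
        if self.classic and self.category is not RatingCategory.E:
            raise RecordError(
                f"patient {self.patient_id!r}: classic flag requires category E"
            )

    @property
    def positive(self) -> bool:
        return self.category is RatingCategory.E


def _age_band(age: int) -> AgeBand:
    if age <= 39:
        return AgeBand.YOUNG
    if age <= 59:
        return AgeBand.MIDDLE
    return AgeBand.OLDER


def assign_stratum(
    patient: PatientRecord,
    profile: MentalDisorderProfile,
    config: StudyConfig,
) -> Stratum:
    """Deterministic stratum for a potential-cohort patient.

    The age band is taken at the last study-period encounter. Raises for
    unknown/other gender — callers must pre-filter the sampling frame.
    """
    if patient.gender is Gender.UNKNOWN_OTHER:
        raise ValueError(
            f"patient {patient.patient_id!r}: unknown/other gender is not "
            "part of the sampling frame"
        )
    period_dates = [
        e.discharge_date
        for e in patient.encounters
        if config.in_study_period(e.discharge_date)
    ]
    if not period_dates:
        raise ValueError(
            f"patient {patient.patient_id!r}: no study-period encounter"
        )
    age = age_at(patient, max(period_dates))
    flagged = profile.has_suicidal_selfharm or profile.has_bipolar
    if flagged:
        hist = (
            HistoryClass.Y1
            if profile.n_groups >= config.min_other_categories
            else HistoryClass.Y2
        )
    else:
        hist = HistoryClass.N
    return Stratum(gender=patient.gender, age_band=_age_band(age), history_class=hist)


def _largest_remainder_allocation(
    sizes: Mapping[Stratum, int], n: int
) -> dict[Stratum, int]:
    """Proportional allocation rounded by largest remainder, summing to n."""
    total = sum(sizes.values())
    strata = sorted(sizes)  # deterministic tie-break order
    shares = {s: n * sizes[s] / total for s in strata}
    alloc = {s: int(np.floor(shares[s])) for s in strata}
    short = n - sum(alloc.values())
    by_remainder = sorted(
        (s for s in strata if sizes[s] > 0),
        key=lambda s: (-(shares[s] - alloc[s]), s),
    )
    for s in by_remainder[:short]:
        alloc[s] += 1
    return alloc


def _cap_allocation(
    alloc: dict[Stratum, int], sizes: Mapping[Stratum, int], cap_factor: int = 1
) -> dict[Stratum, int]:
    """Cap per-stratum allocation at stratum capacity, spilling the excess
    to the largest strata with spare room."""
    alloc = dict(alloc)
    caps = {s: sizes[s] // cap_factor for s in alloc}
    spill = 0
    for s in alloc:
        if alloc[s] > caps[s]:
            spill += alloc[s] - caps[s]
            logger.warning(
                "stratum %s cannot absorb its allocation; reallocating", s
            )
            alloc[s] = caps[s]
    while spill > 0:
        candidates = [s for s in sorted(alloc) if alloc[s] < caps[s]]
        if not candidates:
            raise ValueError("sample size exceeds eligible cohort capacity")
        s = max(candidates, key=lambda s: (caps[s] - alloc[s], s))
        alloc[s] += 1
        spill -= 1
    return alloc


def stratified_sample(
    strata: Mapping[str, Stratum],
    n: int,
    seed: int | np.random.Generator,
) -> set[str]:
    """Draw ``n`` patients from the frame by proportional stratified SRS.

    ``strata`` maps patient id -> stratum. Allocation is proportional to
    stratum prevalence, rounded by largest remainder so it sums to ``n``;
    within strata the draw is simple random sampling without replacement.
    """
    if n > len(strata):
        raise ValueError(f"sample size {n} exceeds cohort size {len(strata)}")
    rng = np.random.default_rng(seed)
    members: dict[Stratum, list[str]] = {}
    for pid, s in strata.items():
        members.setdefault(s, []).append(pid)
    sizes = {s: len(v) for s, v in members.items()}
    alloc = _cap_allocation(_largest_remainder_allocation(sizes, n), sizes)
    out: set[str] = set()
    for s in sorted(members):
        take = alloc.get(s, 0)
        if take:
            pool = sorted(members[s])
            out.update(rng.choice(pool, size=take, replace=False).tolist())
    return out


def stratified_train_test_pair(
    strata: Mapping[str, Stratum],
    n: int,
    seed: int | np.random.Generator,
) -> tuple[set[str], set[str]]:
    """Two disjoint stratified samples of size ``n`` with identical margins.

    One joint stratified draw of size 2n (with an even per-stratum
    allocation) is split uniformly in half within each stratum, so the two
    samples share identical gender/age/history margins by construction.
    """
    if 2 * n > len(strata):
        raise ValueError(
            f"paired samples of size {n} exceed cohort size {len(strata)}"
        )
    rng = np.random.default_rng(seed)
    members: dict[Stratum, list[str]] = {}
    for pid, s in strata.items():
        members.setdefault(s, []).append(pid)
    sizes = {s: len(v) for s, v in members.items()}
    alloc = _cap_allocation(
        _largest_remainder_allocation(sizes, n), sizes, cap_factor=2
    )
    train: set[str] = set()
    test: set[str] = set()
    for s in sorted(members):
        take = alloc.get(s, 0)
        if take:
            pool = sorted(members[s])
            drawn = rng.choice(pool, size=2 * take, replace=False)
            train.update(drawn[:take].tolist())
            test.update(drawn[take:].tolist())
    return train, test


_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f", ""}


def read_ratings(path: str | Path) -> list[RatingLabel]:
    """Read expert chart-review labels from ``ratings.csv``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("patient_id", "category", "classic"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    labels = []
    for _, row in df.iterrows():
        try:
            cat = RatingCategory(row["category"].strip().upper())
        except ValueError as exc:
            raise FormatError(
                f"{path}: unknown rating category {row['category']!r}"
            ) from exc
        flag = row["classic"].strip().lower()
        if flag in _TRUTHY:
            classic = True
        elif flag in _FALSY:
            classic = False
        else:
            raise FormatError(f"{path}: unparseable classic flag {row['classic']!r}")
        labels.append(
            RatingLabel(patient_id=row["patient_id"], category=cat, classic=classic)
        )
    return labels


def write_ratings(labels: Iterable[RatingLabel], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": l.patient_id,
                "category": l.category.value,
                "classic": str(l.classic).lower(),
            }
            for l in labels
        ],
        columns=["patient_id", "category", "classic"],
    ).to_csv(path, index=False)
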