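"""Shared test utilities: terse record builders, an adversarial random
cohort generator, and an independent brute-force re-evaluation of the
cohort selection criteria (kept deliberately separate from the package's
rule engine)."""

from __future__ import annotations

import datetime
from datetime import date, timedelta

import numpy as np
from dateutil.relativedelta import relativedelta

from bopdscreen.ehr import (
    CodeSystem,
    DiagnosisEvent,
    Encounter,
    EncounterType,
    Gender,
    PatientRecord,
)
from bopdscreen.synthetic import CODE_TABLE


def build_patient(
    pid="p1",
    gender=Gender.FEMALE,
    birth=date(1985, 1, 1),
    encounters=(),
):
    """Build a PatientRecord from (date, type, codes) encounter triples.

    Codes are ICD-10-CM strings, or ("ICD9CM", code) tuples.
    """
    encs, dxs = [], []
    for j, (d, etype, codes) in enumerate(encounters):
        eid = f"{pid}e{j}"
        encs.append(
            Encounter(
                encounter_id=eid,
                patient_id=pid,
                encounter_type=EncounterType(etype),
                discharge_date=d,
            )
        )
        for code in codes:
            if isinstance(code, tuple):
                system, code = CodeSystem(code[0]), code[1]
            else:
                system = CodeSystem.ICD10CM
            dxs.append(
                DiagnosisEvent(
                    patient_id=pid,
                    encounter_id=eid,
                    code_system=system,
                    code=code.replace(".", "").upper(),
                )
            )
    return PatientRecord(
        patient_id=pid,
        gender=gender,
        birth_date=birth,
        encounters=tuple(encs),
        diagnoses=tuple(dxs),
    )


_RANDOM_CODES = sorted(CODE_TABLE) + ["Z0000", "Z123", "K5900"]  # incl. unmapped
_ETYPES = [e.value for e in EncounterType]


def random_cohort(rng: np.random.Generator, n: int) -> list[PatientRecord]:
    """Adversarial random records: stray ICD-9 BoPD codes, excluded-range
    codes, pre-period encounters, out-of-age-window diagnoses, codeless
    encounters."""
    records = []
    for i in range(n):
        pid = f"r{i}"
        birth = date(1950, 1, 1) + timedelta(days=int(rng.integers(0, 52 * 365)))
        encounters = []
        for j in range(int(rng.integers(1, 12))):
            d = date(2014, 1, 1) + timedelta(days=int(rng.integers(0, 5 * 365)))
            if d <= birth:
                d = birth + timedelta(days=int(rng.integers(1, 2000)))
            codes = []
            for _ in range(int(rng.integers(0, 4))):
                if rng.random() < 0.03:
                    codes.append(("ICD9CM", "30183"))
                else:
                    codes.append(str(rng.choice(_RANDOM_CODES)))
            encounters.append((d, str(rng.choice(_ETYPES)), codes))
        records.append(
            build_patient(
                pid=pid,
                gender=Gender(str(rng.choice([g.value for g in Gender]))),
                birth=birth,
                encounters=encounters,
            )
        )
    return records


# -- independent re-evaluation of the selection criteria --------------------

_SUIC = {"MBD012", "MBD027"}
_SUBST = {"MBD017", "MBD018", "MBD019", "MBD020", "MBD021", "MBD022",
          "MBD023", "MBD025"}
_TABLE = {"MBD002", "MBD003", "MBD004", "MBD005", "MBD007", "MBD008",
          "MBD009"} | _SUIC | _SUBST
_EXCL_PREFIXES = {f"F0{i}" for i in range(1, 10)} | {f"F7{i}" for i in range(10)}


def _patient_facts(p: PatientRecord, ccsr_entries, cfg):
    enc = {e.encounter_id: e for e in p.encounters}

    def in_period(d):
        return cfg.study_start <= d <= cfg.study_end

    coded = {d.encounter_id for d in p.diagnoses}
    dates = {
        e.discharge_date
        for e in p.encounters
        if e.encounter_id in coded and in_period(e.discharge_date)
    }
    er_dates = {
        e.discharge_date
        for e in p.encounters
        if e.encounter_id in coded
        and in_period(e.discharge_date)
        and e.encounter_type is EncounterType.EMERGENCY
    }
    crit_i = len(dates) >= cfg.min_encounter_dates or len(er_dates) >= cfg.min_emergency_dates

    cats = set()
    for d in p.diagnoses:
        if d.code_system is not CodeSystem.ICD10CM:
            continue
        when = enc[d.encounter_id].discharge_date
        if not in_period(when):
            continue
        age = relativedelta(when, p.birth_date).years
        if age < cfg.age_low or age > cfg.age_high:
            continue
        cat = ccsr_entries.get(d.code)
        if cat in _TABLE:
            cats.add(cat)
    return crit_i, cats, enc, in_period


def _group_count(cats):
    groups = set()
    for c in cats:
        if c in _SUBST:
            groups.add("SUBSTANCE")
        elif c in _SUIC:
            groups.add("SUICIDAL")
        else:
            groups.add(c)
    return len(groups)


def oracle_potential_ids(records, ccsr, cfg) -> set[str]:
    """Brute-force per-patient evaluation of inclusion i-iv and both
    exclusions, written directly from the criteria text."""
    out = set()
    for p in records:
        crit_i, cats, enc, in_period = _patient_facts(p, ccsr.entries, cfg)
        crit_ii = len(cats) > 0
        suicidal = bool(cats & _SUIC)
        bipolar = "MBD003" in cats
        crit_iii_iv = suicidal or bipolar or _group_count(cats) >= cfg.min_other_categories
        bopd_ever = any(
            (d.code_system is CodeSystem.ICD10CM and d.code == "F603")
            or (d.code_system is CodeSystem.ICD9CM and d.code == "30183")
            for d in p.diagnoses
        )
        range_excl = any(
            d.code_system is CodeSystem.ICD10CM
            and d.code[:3] in _EXCL_PREFIXES
            and in_period(enc[d.encounter_id].discharge_date)
            for d in p.diagnoses
        )
        if crit_i and crit_ii and crit_iii_iv and not bopd_ever and not range_excl:
            out.add(p.patient_id)
    return out


def oracle_diagnosed_ids(records, ccsr, cfg) -> set[str]:
    out = set()
    for p in records:
        crit_i, cats, enc, in_period = _patient_facts(p, ccsr.entries, cfg)
        has_bopd = any(
            d.code_system is CodeSystem.ICD10CM
            and d.code == "F603"
            and in_period(enc[d.encounter_id].discharge_date)
            for d in p.diagnoses
        )
        range_excl = any(
            d.code_system is CodeSystem.ICD10CM
            and d.code[:3] in _EXCL_PREFIXES
            and in_period(enc[d.encounter_id].discharge_date)
            for d in p.diagnoses
        )
        if has_bopd and crit_i and len(cats) > 0 and not range_excl:
            out.add(p.patient_id)
    return out


def brute_force_auroc(scores, labels) -> float:
    """Pairwise positive-vs-negative comparison with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
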