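"""Rule engine: inclusion criteria, exclusions, cohort funnels."""

from datetime import date

import numpy as np
import pytest

from bopdscreen.cohort import (
    MentalDisorderProfile,
    encounter_criterion,
    exclusion_criterion,
    mental_disorder_profile,
    select_diagnosed_cohort,
    select_potential_cohort,
    select_silver_positives,
)
from bopdscreen.ehr import Gender
from bopdscreen.synthetic import fixture_ccsr_map
from helpers import build_patient, oracle_potential_ids, random_cohort

CCSR = fixture_ccsr_map()

D = date  # brevity in tables below


def _days(start, n, etype="outpatient_other", codes=("F329",)):
    return [
        (date(2016, 1, 1 + i) if start is None else start[i], etype, list(codes))
        for i in range(n)
    ]


class TestEncounterCriterion:
    def test_five_outpatient_dates_pass(self, config):
        p = build_patient(encounters=_days(None, 5))
        assert encounter_criterion(p, config)

    def test_two_emergency_same_date_fail(self, config):
        p = build_patient(
            encounters=[
                (D(2016, 3, 1), "emergency", ["F329"]),
                (D(2016, 3, 1), "emergency", ["F419"]),
            ]
        )
        assert not encounter_criterion(p, config)

    def test_four_dates_with_one_emergency_fail(self, config):
        p = build_patient(
            encounters=_days(None, 3) + [(D(2016, 2, 1), "emergency", ["F329"])]
        )
        assert not encounter_criterion(p, config)

    def test_two_emergency_distinct_dates_pass(self, config):
        p = build_patient(
            encounters=[
                (D(2016, 3, 1), "emergency", ["F329"]),
                (D(2016, 3, 2), "emergency", ["F419"]),
            ]
        )
        assert encounter_criterion(p, config)

    def test_codeless_encounters_do_not_count(self, config):
        p = build_patient(
            encounters=[(D(2016, 1, 1 + i), "outpatient_other", []) for i in range(6)]
        )
        assert not encounter_criterion(p, config)

    def test_out_of_period_encounters_do_not_count(self, config):
        p = build_patient(
            encounters=[(D(2014, 1, 1 + i), "outpatient_other", ["F329"]) for i in range(6)]
        )
        assert not encounter_criterion(p, config)


class TestMentalDisorderProfile:
    def test_single_mapping(self, config):
        p = build_patient(
            birth=D(1986, 1, 1),
            encounters=[(D(2016, 5, 1), "outpatient_other", ["F32.9"])],
        )
        prof = mental_disorder_profile(p, CCSR, config)
        assert prof.categories_present == frozenset({"MBD002"})
        assert not prof.has_bipolar and not prof.has_suicidal_selfharm

    def test_diagnosis_outside_age_window_ignored(self, config):
        p = build_patient(
            birth=D(1999, 6, 1),  # age 16-17 during events
            encounters=[(D(2016, 5, 1), "outpatient_other", ["F329"])],
        )
        prof = mental_disorder_profile(p, CCSR, config)
        assert prof.categories_present == frozenset()

    def test_substance_categories_collapse_to_one_group(self, config):
        p = build_patient(
            encounters=[(D(2016, 5, 1), "outpatient_other", ["F1010", "F1210"])]
        )
        prof = mental_disorder_profile(p, CCSR, config)
        assert prof.categories_present == frozenset({"MBD017", "MBD019"})
        assert prof.n_groups == 1

    def test_suicidal_flags_set_by_either_category(self, config):
        p = build_patient(
            encounters=[(D(2016, 5, 1), "outpatient_other", ["T360X2A"])]
        )
        prof = mental_disorder_profile(p, CCSR, config)
        assert prof.has_suicidal_selfharm

    def test_unmapped_code_silently_ignored(self, config):
        p = build_patient(
            encounters=[(D(2016, 5, 1), "outpatient_other", ["Z9999"])]
        )
        prof = mental_disorder_profile(p, CCSR, config)
        assert prof.categories_present == frozenset()


class TestExclusions:
    def test_bopd_code_before_study_period_still_excludes(self, config):
        p = build_patient(
            encounters=[(D(2012, 5, 1), "outpatient_other", ["F60.3"])]
        )
        excluded, reason = exclusion_criterion(p, config)
        assert excluded and reason == "prior BoPD code"

    def test_icd9_bopd_code_excludes(self, config):
        p = build_patient(
            encounters=[(D(2016, 5, 1), "outpatient_other", [("ICD9CM", "30183")])]
        )
        assert exclusion_criterion(p, config)[0]

    def test_f05_in_period_excludes(self, config):
        p = build_patient(
            encounters=[(D(2016, 5, 1), "outpatient_other", ["F059"])]
        )
        assert exclusion_criterion(p, config)[0]

    def test_f05_outside_period_does_not_exclude(self, config):
        p = build_patient(
            encounters=[(D(2013, 5, 1), "outpatient_other", ["F059"])]
        )
        assert not exclusion_criterion(p, config)[0]

    def test_f10_is_not_in_the_excluded_prefix_range(self, config):
        p = build_patient(
            encounters=[(D(2016, 5, 1), "outpatient_other", ["F1020"])]
        )
        assert not exclusion_criterion(p, config)[0]


def _bipolar_patient(pid="p1", extra=()):
    encs = [
        (D(2016, 1, 1 + i), "outpatient_other", ["F319"]) for i in range(5)
    ] + list(extra)
    return build_patient(pid=pid, birth=D(1986, 1, 1), encounters=encs)


class TestPotentialCohort:
    def test_bipolar_with_history_included(self, config):
        res = select_potential_cohort([_bipolar_patient()], CCSR, config)
        assert res.included_ids == {"p1"}

    def test_two_categories_without_flags_not_included(self, config):
        p = build_patient(
            encounters=[
                (D(2016, 1, 1 + i), "outpatient_other", ["F329", "F419"])
                for i in range(5)
            ]
        )
        res = select_potential_cohort([p], CCSR, config)
        assert res.included_ids == set()

    def test_three_categories_without_flags_included(self, config):
        p = build_patient(
            encounters=[
                (D(2016, 1, 1 + i), "outpatient_other", ["F329", "F419", "F4310"])
                for i in range(5)
            ]
        )
        res = select_potential_cohort([p], CCSR, config)
        assert res.included_ids == {"p1"}

    def test_bopd_code_dominates(self, config):
        p = _bipolar_patient(extra=[(D(2016, 6, 1), "outpatient_other", ["F603"])])
        res = select_potential_cohort([p], CCSR, config)
        assert res.included_ids == set()

    def test_funnel_counts_are_monotone(self, config):
        rng = np.random.default_rng(17)
        records = random_cohort(rng, 150)
        res = select_potential_cohort(records, CCSR, config)
        counts = list(res.counts_per_stage.values())
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == len(res.included_ids)

    def test_determinism(self, config):
        rng = np.random.default_rng(3)
        records = random_cohort(rng, 80)
        a = select_potential_cohort(records, CCSR, config)
        b = select_potential_cohort(records, CCSR, config)
        assert a.included_ids == b.included_ids
        assert a.counts_per_stage == b.counts_per_stage
        assert a.per_patient_trace == b.per_patient_trace


class TestDiagnosedCohort:
    def test_bopd_with_history_and_comorbidity_included(self, config):
        p = _bipolar_patient(extra=[(D(2016, 6, 1), "outpatient_other", ["F603"])])
        res = select_diagnosed_cohort([p], CCSR, config)
        assert res.included_ids == {"p1"}

    def test_insufficient_history_not_included(self, config):
        p = build_patient(
            encounters=[
                (D(2016, 1, 1 + i), "outpatient_other", ["F603", "F329"])
                for i in range(3)
            ]
        )
        res = select_diagnosed_cohort([p], CCSR, config)
        assert res.included_ids == set()

    def test_intellectual_disability_code_excludes(self, config):
        p = _bipolar_patient(
            extra=[(D(2016, 6, 1), "outpatient_other", ["F603", "F75"])]
        )
        res = select_diagnosed_cohort([p], CCSR, config)
        assert res.included_ids == set()

    def test_disjoint_from_potential_cohort(self, config):
        rng = np.random.default_rng(11)
        records = random_cohort(rng, 200)
        pot = select_potential_cohort(records, CCSR, config)
        dia = select_diagnosed_cohort(records, CCSR, config)
        assert pot.included_ids.isdisjoint(dia.included_ids)


class TestSilverPositives:
    def test_bipolar_diagnosed_patient_retained(self, config):
        p = _bipolar_patient(extra=[(D(2016, 6, 1), "outpatient_other", ["F603"])])
        assert select_silver_positives([p], CCSR, config) == {"p1"}

    def test_two_other_categories_dropped(self, config):
        p = build_patient(
            encounters=[
                (D(2016, 1, 1 + i), "outpatient_other", ["F603", "F329", "F419"])
                for i in range(5)
            ]
        )
        assert select_silver_positives([p], CCSR, config) == set()

    def test_only_bopd_code_dropped(self, config):
        p = build_patient(
            encounters=[
                (D(2016, 1, 1 + i), "outpatient_other", ["F603"]) for i in range(5)
            ]
        )
        assert select_silver_positives([p], CCSR, config) == set()

    def test_personality_disorder_via_f603_not_counted_but_f609_is(self, config):
        # F60.9 maps to the same personality-disorder category; only the
        # BoPD code itself is masked
        p = build_patient(
            encounters=[
                (D(2016, 1, 1 + i), "outpatient_other", ["F603", "F609", "F329", "F419"])
                for i in range(5)
            ]
        )
        assert select_silver_positives([p], CCSR, config) == {"p1"}


def test_rule_engine_matches_brute_force_oracle_on_random_cohorts(config):
    """Independent per-patient re-evaluation of the criteria text."""
    rng = np.random.default_rng(2024)
    for _ in range(25):
        records = random_cohort(rng, 60)
        res = select_potential_cohort(records, CCSR, config)
        assert res.included_ids == oracle_potential_ids(records, CCSR, config)
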