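"""Draw paired stratified chart-review samples with identical margins.

Strata cross gender, age band and bipolar/suicidal diagnostic history
(N/Y1/Y2); one joint draw split evenly within each stratum makes the two
228-patient samples share gender/age margins exactly.
"""

import collections

from bopdscreen import (
    Gender,
    SimConfig,
    assign_stratum,
    generate_cohort,
    mental_disorder_profile,
    select_potential_cohort,
    stratified_train_test_pair,
)

sim = SimConfig(n_patients=4000, seed=11)
records, truth, ccsr, _ = generate_cohort(sim)
config = sim.study_config()
by_id = {r.patient_id: r for r in records}

cohort = select_potential_cohort(records, ccsr, config)
strata = {}
for pid in sorted(cohort.included_ids):
    p = by_id[pid]
    if p.gender is Gender.UNKNOWN_OTHER:
        continue  # unknown/other gender is outside the sampling frame
    strata[pid] = assign_stratum(p, mental_disorder_profile(p, ccsr, config), config)

train, test = stratified_train_test_pair(strata, n=228, seed=3)
print(f"frame {len(strata)} -> train {len(train)}, test {len(test)}, "
      f"overlap {len(train & test)}")
for name, ids in (("train", train), ("test", test)):
    margins = collections.Counter(
        (strata[i].gender.value, strata[i].age_band.value) for i in ids
    )
    print(name, dict(sorted(margins.items())))
# Both samples print identical gender x age counts: the stratified pair is
# drawn jointly and split within strata.
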