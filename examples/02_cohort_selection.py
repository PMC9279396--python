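"""Apply the rule-based selection funnel to a synthetic cohort.

Shows the staged inclusion/exclusion counts for the potential-BoPD cohort
(patients without the F60.3 code whose history suggests undiagnosed BoPD),
the EHR-diagnosed cohort, and the rule-selected silver-positive subset.
"""

from bopdscreen import (
    SimConfig,
    generate_cohort,
    select_diagnosed_cohort,
    select_potential_cohort,
    select_silver_positives,
)

sim = SimConfig(n_patients=2000, seed=7)
records, truth, ccsr, _ = generate_cohort(sim)
config = sim.study_config()

potential = select_potential_cohort(records, ccsr, config)
print("potential-cohort funnel (survivors per stage):")
for stage, count in potential.counts_per_stage.items():
    print(f"  {stage:<22} {count}")

diagnosed = select_diagnosed_cohort(records, ccsr, config)
by_id = {r.patient_id: r for r in records}
silver = select_silver_positives(
    [by_id[i] for i in sorted(diagnosed.included_ids)], ccsr, config
)
print(f"potential cohort: {len(potential.included_ids)}")
print(f"diagnosed cohort: {len(diagnosed.included_ids)}")
print(f"silver positives: {len(silver)} "
      "(diagnosed patients re-passing the comorbidity rule without F60.3)")
# The two cohorts are disjoint by construction: F60.3 excludes a patient
# from the potential cohort and defines the diagnosed one.
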