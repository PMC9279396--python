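# bopdscreen

Screening structured electronic health records (EHRs) for patients who may
have **undiagnosed borderline personality disorder (BoPD)**. BoPD is common,
frequently misdiagnosed (often as bipolar disorder), and its diagnosis code
is underused; automated screening of routinely collected EHR data — 
demographics, encounter types and dates, ICD-10-CM diagnosis codes — can
flag patients worth a formal clinical assessment.

The package implements a two-step algorithm:

1. **Rule-based selection** of a *potential BoPD cohort*: patients with
   sufficient encounter history (≥ 5 encounters on distinct discharge dates,
   or ≥ 2 emergency visits on distinct dates), diagnoses in BoPD-associated
   CCSR mental-disorder categories at age 18–65, and either a
   bipolar (MBD003) or suicidal/self-harm (MBD012/MBD027) code or diagnoses
   in ≥ 3 associated comorbidity groups — excluding anyone who ever carried
   a BoPD code (ICD-10-CM F60.3 / ICD-9-CM 301.83) and anyone with codes in
   F01–F09 or F70–F79 during the study period.
2. **Semi-supervised classification** over Boolean features (demographic
   bins, encounter frequency/type, and CCSR-category × expert-association
   diagnosis groups), all L1-regularized logistic regressions:
   - *Model 1* (seed) is fit on a small expert-rated **gold-label** sample
     (chart-review categories A–E; positive = "E: most likely BoPD");
   - a much larger **silver-label** set is assembled: silver *positives* are
     rule-selected from the EHR-diagnosed BoPD cohort, silver *negatives*
     are randomly drawn from potential-cohort patients Model 1 predicts
     negative, sized to preserve the gold positive:negative ratio
     (66 : 162, so 5,961 positives call for ⌊5961·162/66⌋ = 14,631
     negatives);
   - *Model 2* (main) is fit on the silver set; *Model 3* (adjustment) on
     the gold subset of categories E and B (severe psychotic/substance
     abuse) to suppress psychotic/substance false positives.

   The combined score is

   ```
   p_final = p2        if p3 > 0.5
           = p2 · p3   otherwise
   ```

   so the adjustment can only lower a score. A patient screens positive
   when `p_final > 0.5`.

Evaluation reports AUROC (Mann–Whitney, ties ½), accuracy, PPV,
sensitivity, specificity and classic-BoPD recall with 1,000-replicate
percentile-bootstrap 95% confidence intervals; chart-review samples are
drawn by proportional stratified sampling over gender × age band ×
bipolar/suicidal history (N/Y1/Y2).

Because real EHR databases of this kind are proprietary, the package ships
a **synthetic-EHR generator** that plants latent patient classes aligned
with the chart-review categories, so every stage — rules, sampling,
features, models, evaluation — is exercised end to end without any data
download.

## Worked example

```sh
python examples/04_train_and_evaluate.py
```

runs the full study on a 6,000-patient synthetic cohort and prints:

```
cohort counts: {'patients': 6000, 'potential_cohort': 1518,
 'diagnosed_cohort': 291, 'silver_positives': 263,
 'gold_train': 228, 'gold_test': 228}

held-out gold test set (n=228):
  auroc                0.848  [0.796, 0.898]
  accuracy             0.776  [0.724, 0.829]
  ppv                  0.723  [0.591, 0.850]
  sensitivity          0.472  [0.361, 0.591]
  specificity          0.917  [0.869, 0.956]
  classic_sensitivity  0.727  [0.567, 0.875]

seed-model AUROC 0.817 -> main-model AUROC 0.872 (benefit of the ~6x
larger silver-label training set)
```

Read: of 6,000 simulated patients, 1,518 enter the potential cohort and
291 already carry the BoPD code; two stratified 228-patient gold samples
are rated by the simulated expert. On the held-out sample the combined
model ranks a random most-likely-BoPD patient above a random other patient
84.8% of the time, and 72.3% of screen-positives are most-likely-BoPD.
The main model trained on the silver-label set outperforms the seed model
trained on gold labels alone.

The other examples show the generator (`01`), the selection funnel (`02`)
and the identical-margin paired sampling (`03`). The same steps are
available as a CLI: `bopd-screen simulate|select-cohort|sample|featurize|
train|predict|evaluate|reproduce`.

## Layout

- `src/bopdscreen/ehr.py` — domain types, flat-file readers/writers
- `src/bopdscreen/cohort.py` — rule engine (inclusion/exclusion funnel)
- `src/bopdscreen/sampling.py` — stratified chart-review sampling, ratings
- `src/bopdscreen/features.py` — Boolean feature engineering
- `src/bopdscreen/model.py` — the three-model semi-supervised pipeline
- `src/bopdscreen/evaluation.py` — metrics and bootstrap intervals
- `src/bopdscreen/synthetic.py` — synthetic-EHR generator
- `src/bopdscreen/pipeline.py`, `cli.py` — end-to-end driver and CLI
- `docs/methods.md` — modelling assumptions, parameters, limitations
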