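# Methods

## Problem and model

The package screens structured EHR extracts for patients likely to have
undiagnosed borderline personality disorder (BoPD). Input is three flat
tables — patients (id, gender, birth date), encounters (type, discharge
date) and diagnoses (code system, code) — plus two knowledge tables: a
CCSR-style map from ICD-10-CM codes to clinical categories, and an expert
rating of each code's association with BoPD (positive / negative /
unrelated / unsure).

Step 1 is a deterministic rule engine. A patient enters the *potential
cohort* iff, within the study period (inclusive of both boundary dates):

- ≥ 5 diagnosis-bearing encounters on distinct discharge dates, or ≥ 2
  emergency visits on distinct dates;
- ≥ 1 diagnosis in a BoPD-associated CCSR category at age 18–65 (age is
  evaluated at each event's discharge date, since the criteria anchor
  diagnoses, not patients, to the age window);
- a bipolar (MBD003) or suicidal/self-harm (MBD012/MBD027) code, or
  diagnoses in ≥ 3 associated groups — the eight substance categories
  count as one combined group and MBD012+MBD027 as one group;

and is excluded by any BoPD code (ICD-10-CM F60.3, ICD-9-CM 301.83)
anywhere in the record, or any F01–F09 / F70–F79 code (matched on the
3-character category prefix of the normalized code) in the study period.
The *diagnosed cohort* replaces the BoPD exclusion with an F60.3-in-period
requirement and keeps the history/age/range-exclusion rules.

Step 2 is a semi-supervised classifier over Boolean features. The three
models are L1-regularized logistic regressions sharing one feature space;
scores combine as `p_final = p2 if p3 > 0.5 else p2·p3` (p3 = 0.5 exactly
falls to the multiplicative branch; the comparison is strict). A patient
screens positive iff `p_final > 0.5`, again strict.

## Features

Diagnosis-history features are built in three steps: (1) keep ICD-10-CM
codes with patient-level prevalence ≥ 0.05 (inclusive) in either the
potential or the diagnosed cohort — the two per-cohort sets are combined by
**union**, read off the fact that combining enlarges the per-cohort lists;
(2) map each code to its default CCSR category (codes missing from the map
go to a reserved UNMAPPED category; unrated codes default to "unsure");
(3) one Boolean feature per non-empty (category × rating) cell, true iff
the patient has any member code in the study period. F60.3 itself is
removed from the candidate codes before feature construction: it is the
screening target and is universally present in the diagnosed cohort, so
keeping it would let the silver-positive labels leak into the main model
through a feature that is identically false on the potential cohort where
the model is deployed.

Demographics enter as age-band bins (18–39 / 40–59 / 60–65, at the last
study-period encounter), a female indicator, encounter-type presence
flags, and encounter-frequency bins (low/median/high). The frequency
cutoffs are the tertiles of distinct-discharge-date counts in the training
cohort, frozen into the serialized feature spec; a count exactly on a
cutoff falls to the lower bin. Frequency counts use diagnosis-bearing
encounters, consistent with the encounter criterion.

## Training pipeline

Model 1 trains on the gold-label chart-review sample (E vs A∪B∪C∪D).
Silver positives are diagnosed-cohort patients re-passing the
bipolar/suicidal-or-3-groups rule with all F60.3 events masked; silver
negatives are a seeded uniform draw without replacement from
potential-cohort patients (gold patients removed) with Model-1 probability
strictly below 0.5, of size ⌊n_pos · 162/66⌋ so the silver class ratio
matches the gold one up to integer truncation. Model 2 trains on the
silver set; Model 3 on the gold rows rated E or B, positive = E.

Regularization strength is selected from a fixed grid of 13 log-spaced
values spanning six orders of magnitude by mean validation-fold AUROC
under stratified 10-fold cross-validation (folds shuffled under the run
seed); ties prefer the strongest penalty, i.e. the sparser model. The
penalty is applied to the **mean** log-loss (the solver's C is divided by
the number of rows), which makes the fit invariant to replicating the
data set — the selected strength has the same meaning at n = 228 and
n = 20,000. Folds where the validation split is single-class are skipped
in the selection average. All-constant feature columns are dropped with a
warning before fitting. The final model is refit on all rows at the
selected strength.

## Chart-review sampling

The sampling frame is the potential cohort minus unknown/other-gender
patients. Strata cross gender × age band × history class (N: no
bipolar/suicidal code and ≥ 3 groups; Y1: bipolar/suicidal and ≥ 3 groups;
Y2: bipolar/suicidal and < 3 groups, groups counted including those
flags). Allocation is proportional with largest-remainder rounding (the
allocation rule is otherwise unconstrained by the study design; largest
remainder keeps every stratum within one unit of its exact share), and
the paired train/test samples are drawn as **one** joint stratified draw
split evenly within each stratum — this reproduces exactly the property
that the two gold samples share identical demographic margins. Strata
whose capacity cannot absorb their allocation spill the excess to the
largest strata with room, with a warning.

## Evaluation

AUROC is the Mann–Whitney rank statistic (ties ½). Confusion metrics are
computed at the strict 0.5 threshold; classic-BoPD recall is the
screen-positive fraction among classic-flagged positives only. Intervals
are percentile bootstrap over 1,000 patient-level resamples at the 95%
level — percentile rather than BCa, as nothing in the study design pins
down the variant and the percentile interval is the simplest seed-stable
choice. Replicates on which a metric is undefined (single-class resample,
no predicted positives, no classic cases drawn) are skipped for that
metric and counted; a metric undefined in more than half the replicates
is reported without an interval.

## Synthetic-EHR generator

The generator emulates the data structure the pipeline assumes, not any
real database's marginals. Five latent classes are planted with these
default mixture weights: BoPD-like 0.16, psychotic/substance 0.08,
primarily-physical 0.25, other-mental 0.29, healthy 0.22. Per class, the
generator draws encounter counts from a negative-binomial-shaped
distribution (class means 3–11, producing the low/median/high frequency
spread the features bin), encounter types (class-specific emergency and
inpatient fractions), demographics (class-specific female probability and
age range; 0.5% unknown/other gender), and per-category Bernoulli
indicators over a miniature in-repo table of ~60 ICD-10-CM-shaped codes
covering all the associated mental-disorder categories plus psychotic,
physical-illness and exclusion-range codes. 35% of BoPD-like patients
receive F60.3 and form the diagnosed cohort; 15% of encounters fall before
the study window and small rates of stray ICD-9 BoPD codes (1%) and
exclusion-range codes (1–4%) exercise the exclusion rules.

The class weights and comorbidity probabilities were calibrated once, by
Monte-Carlo on the generator itself, so that after rule-based selection
the BoPD-like share of the potential cohort sits near the ~29% positive
rate observed in expert-rated screening samples of this kind; they are
fixed defaults, not tuning knobs. Expert ratings derive deterministically
from the latent class (BoPD-like→E, psychotic/substance→B,
physical/healthy→A, other-mental→C or D depending on recorded comorbidity,
classic subflag for E patients with self-harm codes and ≥ 4 groups), then
flip to a random other category with probability 0.05.

What the generator does **not** emulate: real marginal code frequencies,
coding practice drift, inter-provider fragmentation, free-text notes, or
the multi-million-patient scale of production EHR databases. Passing
end-to-end tests therefore demonstrates that the pipeline's logic and
statistics behave as specified under the planted generative model — not
that the classifier would achieve any particular performance on real
records.

## Problem sizes and numerical choices

The end-to-end study runs at 6,000 synthetic patients with paired
228-patient gold samples — large enough for a four-figure potential
cohort, a few-hundred-patient silver-positive pool and stable bootstrap
intervals, while a full run stays under a minute. The logistic solver is
liblinear at tolerance 1e-6 (coefficients are stable to ~1e-3, well below
any decision that depends on them); probabilities compare to thresholds
strictly, so boundary cases (p = 0.5) are always negative/multiplicative;
dates are ISO-8601 and study-period membership is inclusive on both ends;
ages are completed years.

## Known limitations

- The encounter criterion counts any diagnosis-bearing encounter; if a
  deployment wants mental-disorder-coded encounters only, the rule engine
  needs a variant predicate.
- Silver-set quality depends on the seed model: a poorly calibrated
  Model 1 biases the silver negatives. The pipeline reports the seed and
  main model AUROCs side by side so this is visible.
- The adjustment model trains on ~90 rows; its regularization selection is
  noisy at that size, which is tolerable because the combination rule only
  lets it lower scores.
- ICD-9 codes participate only in the BoPD-ever exclusion; no
  ICD-9→ICD-10 cross-walk is attempted.
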