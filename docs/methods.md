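# Methods

## Scope and model

`dkaval` validates a deterministic claims-based case definition of
incident diabetic ketoacidosis (DKA) against a chart-review gold
standard, reporting the positive predictive value (PPV) with Wilson 95%
confidence intervals. The package estimates PPV only: sensitivity is not
estimable from a design that abstracts charts solely for flagged cases,
and no attempt is made to model it. Human abstraction and two-reviewer
adjudication are modeled as a single deterministic rule application (the
design this emulates recorded zero adjudicator disagreements), with
incomplete abstraction (chart not located, facility refused) a distinct
non-adjudicable state excluded from PPV denominators.

## Code matching

ICD codes are canonicalized to uppercase dotted form; families are
expressed as truncated prefixes on the dotless form, with a wildcard `x`
matching any single digit (or a literal `X`, so a pattern always matches
itself). `250.1` therefore accepts 250.1, 250.10–250.13; `E1x.1` accepts
the E10.1–E14.1 families; `250x` accepts all of 250.*. ICD-9
external-cause codes (E800–E999) split after four characters, everything
else after three. The code-set supports both ICD-9 and ICD-10 without
asserting which occur in any given database era; the ER index-date reset
matches ICD-9 250.xx by default, with ICD-10 E10–E14 behind an opt-in
flag.

## Cohort construction choices

Several rules required operational definitions where the design brief is
qualitative; each is configurable on `CohortConfig`:

- **Washout.** A fill qualifies iff no study-drug fill of *any* study
  class occurred in the 365 days strictly before it (control fills reset
  antipsychotic qualification and vice versa). A stricter literal
  "no prescription filled more than 90 days prior" clause is available
  as `require_90day_free` but off by default.
- **Current use** is fill date through fill date + days_supply − 1;
  refills starting within grace (default 0) + 1 day of the covered
  period extend the episode. Follow-up may run 365 days past the last
  covered day.
- **Baseline adequacy** = one enrollment span covering the full 365-day
  baseline plus ≥ 1 outpatient encounter in baseline
  (`require_baseline_outpatient`).
- **Follow-up termination** takes the minimum over study end, the day
  *before* the 25th birthday (the last day aged 24; inclusivity was
  unspecified), disenrollment, death, exclusion-diagnosis onset, and use
  lapse; same-day ties resolve death > disenrollment > age_25 >
  criteria_failure > use_lapse > study_end. Criteria are re-evaluated
  only at claim dates, since they can only change when claims appear.
- **Outcome vs censoring.** The diabetes code family is excluded from
  during-follow-up criteria re-evaluation. Censoring on it would end
  follow-up at a prior-day ER diabetes visit and make the index-date
  reset rule unreachable; a diabetes-coded claim during follow-up is the
  outcome pathway, terminating follow-up implicitly at the event.
  Baseline diabetes remains an exclusion, and incidence additionally
  requires no DKA-coded claim of any setting in baseline.

Eligibility checks collect **all** failed criteria (no short-circuit),
so exclusion tallies are interpretable. Members whose follow-up would end
before it begins are dropped.

## Adjudication

Confirmation requires glucose > 250 mg/dL (strict inequality; the
maximum recorded random glucose is used, the reading most favorable to
detection) plus any-of laboratory acidosis: any pH below its
specimen-specific threshold (venous 7.25; arterial/capillary 7.30) or
bicarbonate < 15 mmol/L, all strict. When venous and arterial values
conflict, any below-threshold value counts (any-of semantics; specimen
precedence was unspecified). The discharge-diagnosis criterion is
recorded in `criteria_met` but is never decisive under `strict`; the
`dx_fallback` policy lets it confirm only when no pH and no bicarbonate
were recorded at all. No ketone or anion-gap criterion is modeled.

## Wilson interval

Closed form with the exact normal quantile (≈ 1.959964 at 95%) rather
than 1.96 — both reproduce every one-decimal published value — no
continuity correction, and exact endpoints 0/1 at x = 0 / x = n (where
the algebra collapses but floating point would not). Clopper–Pearson is
available for comparison only. Displayed percentages round half-up to
one decimal, matching printed-table conventions; full precision is kept
internally. Tests cross-check the implementation against numeric
inversion of the score test (to 1e-9 over all 0 ≤ x ≤ n ≤ 50) and
against statsmodels.

Note: a 19/21 stratum is sometimes quoted as "90.0%" in print; 19/21 =
90.5% and the accompanying CI (71.1–97.3) matches 19/21 exactly, so the
package reports 90.5.

## Synthetic data

The generator emulates the *structure* of Medicaid-like claims for
validation studies, not their epidemiology:

- Defaults: ages uniform on 6–24; 47% female; race 70/20/10
  Caucasian/African-American/other; 63% urban; 53% ADHD; 20%
  antipsychotic initiators — roughly the validation-sample margins,
  which are descriptive context and not asserted in tests.
- Each person gets one enrollment span, a qualifying fill with
  Poisson-distributed refills, and a baseline outpatient visit. A
  designated ineligible fraction (default 0.15) violates exactly one
  criterion each (prior fill in washout, age outside 6–24, recent
  hospitalization, baseline diabetes, enrollment gap), tagged in the
  truth output.
- Eligible members receive a DKA-coded admission with probability
  `flag_rate` (default 0.30). This is a testability choice, not
  incidence realism — real DKA incidence (tens of cases per hundreds of
  thousands of person-years) would make pipeline tests vacuous. Flagged
  admissions carry the DKA code in primary or secondary position and,
  with probability 0.3, a prior-day ER diabetes claim exercising the
  index-date reset.
- Each flagged case is truly DKA with probability `true_ppv`; false
  positives follow the dominant observed error mode (severe
  hyperglycemia without acidosis, default weight 1.0) or a coding-error
  mode (glucose ≤ 250).
- Lab distributions only need correct ordering against the adjudication
  thresholds; defaults are clinically plausible: true cases glucose
  LogNormal(median 450 mg/dL) floored above 251, venous pH
  Normal(7.10, 0.08) truncated below threshold, bicarbonate
  Normal(8, 3) capped at 14.5; hyperglycemia-mode false positives
  glucose LogNormal(median 350) floored above 251 with pH/bicarbonate
  floored on the normal side (some carrying a DKA discharge diagnosis
  the rule must refuse). At these defaults true/false distributions do
  not overlap across the thresholds, so adjudication recovers the truth
  labels exactly (the separation property tested in the suite); real
  charts have measurement noise, borderline labs, and missing values
  far messier than this, so passing tests demonstrate pipeline
  correctness, not real-world PPV.
- Everything derives from one `numpy` Generator seeded by
  `SimulationConfig.seed`; identical configs give byte-identical CSV
  output. Abstraction generation derives a sub-seed (seed + 1000003).

The packaged fixture is a hand-constructed, RNG-free 30-person database
and abstraction set reproducing a published validation sample: 30
flagged, 3 unabstractable (2 charts not located, 1 facility refusal), 27
adjudicated, 24 confirmed, the 3 non-confirmed all hyperglycemic without
acidosis. Published margins constrain but do not determine the joint
strata table; the fixture fixes one feasible joint assignment (the three
non-confirmed cases are age ≤ 10, female, ADHD-positive; one
antipsychotic and two control initiators) and the tests verify all four
margins simultaneously. Whether unabstracted cases differed
systematically is unknowable; the generator marks unabstractable records
at random.

## Problem sizes in the test suite

The suite favors many small generated populations over few large ones:
the cohort-rule brute-force re-scan uses 20 seeds × 250 persons;
parameter recovery uses one 4,500-person population (≥ 1,000 flagged
cases, giving a ±0.04 Monte-Carlo band at 3 standard errors) plus 100
replicates of 320 persons for interval coverage; Wilson coverage uses
10,000 binomial draws at n = 27. These sizes make the checks sharp while
keeping the whole suite fast.

## Known limitations

- No procedure/revenue codes, no real Medicaid extract formats, no
  hospital-transfer chains, no death-certificate linkage modeling.
- Exclusion code sets are compact family-level stand-ins, not curated
  operational code lists.
- The generator does not model enrollment churn, seasonality, or
  correlated comorbidity; demographic margins are approximate.
- PPV transportability (adults, established diabetes, other payers) is
  outside what any synthetic experiment here can address.
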