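# dkaval

Validation pipeline for a **claims-based (computer) case definition of
diabetic ketoacidosis (DKA)** in children and youth, as used in
pharmacoepidemiologic studies of antipsychotic drug safety.

DKA is a life-threatening but rare complication, so drug-safety studies of
it rely on large administrative claims databases (e.g., Medicaid) rather
than trials. That only works if a deterministic rule over coded claims —
the computer case definition — flags mostly true cases. `dkaval`
implements such a definition together with everything needed to validate
it: new-user cohort construction, inpatient case finding, a gold-standard
chart-adjudication rule, and positive-predictive-value (PPV) estimation
with Wilson 95% confidence intervals, overall and by stratum. A synthetic
claims generator with known ground truth makes every stage testable, and a
packaged deterministic fixture reproduces a published 30-case validation
sample exactly.

## The method

1. **New-user cohort.** Persons aged 6–24 who fill an antipsychotic or a
   control psychotropic (mood stabilizer, ADHD drug, antidepressant,
   benzodiazepine) after a 365-day washout with no study-drug fill, with
   365 days of continuous baseline enrollment and utilization, no
   exclusion diagnosis (schizophrenia/psychosis, diabetes, pregnancy,
   PCOS, life-threatening illness) in baseline, and no hospital stay in
   the prior 30 days. Follow-up runs from the day after the fill to the
   earliest of study end, the 25th birthday, disenrollment, death, an
   exclusion diagnosis, or 365 days past the end of current drug use.
2. **Computer case definition.** An inpatient encounter during follow-up
   with any diagnosis (any position) in the DKA code set — ICD-9 250.1x,
   ICD-10 E10.1–E14.1. Outpatient/ER-only claims never trigger. The index
   date is the admission date, reset to the day prior when an ER claim
   with any diabetes diagnosis (ICD-9 250.xx) sits there. Only a person's
   first (incident) event counts.
3. **Adjudication (gold standard).** A flagged case is confirmed iff the
   abstracted chart shows random glucose > 250 mg/dL **and** laboratory
   acidosis: pH < 7.25 (venous) or < 7.30 (arterial/capillary), or
   bicarbonate < 15 mmol/L. A DKA discharge diagnosis alone never
   confirms under the default `strict` policy.
4. **PPV.** With x confirmed of n adjudicated, PPV = x/n, with the Wilson
   score interval

   PPV CI = (p̂ + z²/2n ± z·√(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n),

   z the exact normal quantile at (1+conf)/2, no continuity correction.

## Worked example

`python examples/reproduce_validation_table.py` runs the whole pipeline
on the packaged fixture and prints:

```
potential cases flagged by the case definition: 30
records abstracted and adjudicated:             27
confirmed incident DKA:                         24

Positive predictive value of the computer case definition
Stratum                                x/n  PPV (%)           95% CI
--------------------------------------------------------------------
overall                              24/27     88.9     71.9 to 96.1
by exposure
  antipsychotic                        5/6     83.3     43.6 to 97.0
  control                            19/21     90.5     71.1 to 97.3
by age
  lower (<=10 years)                  7/10     70.0     39.7 to 89.2
  upper (11-24 years)                17/17    100.0    81.6 to 100.0
by gender
  female                             10/13     76.9     49.7 to 91.8
  male                               14/14    100.0    78.5 to 100.0
by adhd
  no                                 12/12    100.0    75.8 to 100.0
  yes                                12/15     80.0     54.8 to 93.0
```

Reading it: of 30 admissions the claims rule flagged, 27 charts could be
abstracted; 24 of those met the clinical criteria, so roughly 9 in 10
flagged admissions are real DKA (88.9%, with a wide CI because n is
small). The three false positives presented with severe hyperglycemia but
no acidosis. The other examples generate synthetic claims with a planted
PPV and recover it end-to-end (`simulate_and_recover_ppv.py`), tally
cohort exclusions, and explore the Wilson interval.

A thin CLI mirrors the pipeline stages over CSV files
(`dkaval simulate | build-cohort | find-cases | adjudicate | validate`);
the CSV schemas are the columns of the five claims tables
(`persons.csv`: person_id, birth_date, gender, race, urban, adhd_dx;
`enrollment.csv`: person_id, start_date, end_date; `pharmacy.csv`:
person_id, fill_date, drug_class, days_supply; `encounters.csv`:
encounter_id, person_id, setting, start_date, end_date, dx_codes with
diagnosis lists serialized as `icd9:250.11;icd9:276.51`; `deaths.csv`:
person_id, death_date), all dates ISO-8601.

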