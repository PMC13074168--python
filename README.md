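# deprx

Rule-based classification of type 2 diabetes (T2D) medication deprescribing
from longitudinal primary-care prescription records.

## The problem

When patients improve — for example after intensive lifestyle change — their
glucose-lowering medications may be reduced or withdrawn. Research on this
kind of *deprescribing* (the planned, supervised dose reduction or
discontinuation of a medication that may no longer be beneficial) needs a
standardized way to decide which medication changes in a chart actually count
as deprescribing. `deprx` implements such a consensus framework as a
deterministic rules engine for pharmacoepidemiologists and clinical
informaticians working with EHR prescription exports.

## The framework

All T2D medications are grouped into three intensity tiers:
**insulin** (dosed in units) > **non-insulin/non-metformin agents**
(sulfonylureas, DPP-4 inhibitors, GLP-1 receptor agonists, SGLT-2 inhibitors,
thiazolidinediones, ...) > **metformin** (first prescribed, last withdrawn).
Every prescription is standardized to a daily dose
(dose per administration × administrations per day), and each patient is
summarized by the regimen in their first 12 months of diabetes prescribing
versus the last 12 months of the data period.

A patient is **DEPRESCRIBED** with one of eight subtypes:

1. insulin dose reduced (total daily units decreased)
2. insulin switched to a non-insulin medication
3. insulin discontinued
4. non-insulin agent stopped
5. same non-insulin agent's dose reduced
6. switch to metformin only (incl. multiple agents + metformin → metformin
   alone)
7. metformin stopped and not restarted at any point
8. total metformin dose reduced

**NOT_DEPRESCRIBED** covers lateral switches among non-insulin agents
(treated as equivalent in intensity), medication increases (higher doses, or
moves up the tier ordering: metformin → either higher tier, any oral agent →
insulin), and no change (identical endpoint regimens, even if doses wandered
in between). Trajectories with contradictory signals, or an empty final
window that cannot be explained, are **UNCLEAR** and flagged for human
review. Because the practices require at least an annual visit for refills, a
patient whose last prescription is more than a year old but who still
attends is treated as having had their medications discontinued
(inferred discontinuation).

## Worked example

The package ships a synthetic cohort generator that emits the exact export
shape the classifier consumes, with the intended label planted per patient:

```sh
deprx simulate --n 60 --seed 5 --out demo/sim
deprx classify --records demo/sim/records.csv \
               --encounters demo/sim/encounters.csv \
               --patients demo/sim/patients.csv --out demo/cls
```

which prints:

```
patients: 60 (eligible: 58)
  excluded (age): 1
  excluded (visits): 1
DEPRESCRIBED: 33
NOT_DEPRESCRIBED: 16
UNCLEAR: 9
  INSULIN_DISCONTINUED: 9
  INSULIN_DOSE_REDUCED: 4
  ...
unrecognized medication rows: 21 (4 distinct names)
wrote demo/cls/classifications.csv
```

Two patients fail the eligibility screen (age outside 18–89, or fewer than
two visits in the analysis window). Of the 58 classified, 33 are
deprescribed — the subtype lines always sum to the DEPRESCRIBED count — and 9
are flagged for review (planted mixed-signal and loss-to-follow-up cases).
The 21 unrecognized rows are non-diabetes medications (statins, vitamins)
that real exports contain; they are counted and set aside, never classified.
`demo/cls/classifications.csv` holds one row per patient with the matched
rules and a human-readable evidence trail; comparing it against
`demo/sim/truth.csv` shows every planted label recovered.

The same pipeline is available as a library:

```python
from datetime import date
from deprx import classify_patient, build_trajectory, generate_cohort

case = generate_cohort(1, mix={"metformin_dose_reduced": 1.0}, seed=0)[0]
cl = classify_patient(build_trajectory(case.history, date(2023, 3, 13)))
print(cl.top_level.value, cl.subtype)   # DEPRESCRIBED METFORMIN_DOSE_REDUCED
```

## Input formats

Comma-delimited tables with ISO-8601 dates:

- records: `patient_id,date,medication_name,strength_amount,strength_unit,frequency_per_day`
- encounters: `patient_id,date`
- patients (optional demographics): `patient_id,age`

Medication names are matched case-insensitively against an editable lexicon
(`canonical_name,category,synonyms,components,component_strengths`; a default
is bundled) covering generics, brands, abbreviations and fixed-dose
combinations, which are split into their components so a
metformin-containing combination counts as metformin exposure.
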