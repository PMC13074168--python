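# Methods

## Model of a medication trajectory

`deprx` treats a patient's chart as two tables: dated prescription rows
(name as written, strength per administration, unit, administrations per
day) and dated clinic encounters, optionally joined to an age. Every
medication name is resolved through an editable lexicon to a canonical
generic and one of three intensity tiers — insulin, non-insulin/non-metformin
agents, metformin — and every prescription is standardized to a daily dose,
the exact product `strength × frequency_per_day` with no rounding. Insulin
is compared in units, oral agents in mg (mcg is converted; no other unit
conversion exists because the rules never compare doses across different
drugs — the single exception being total daily insulin units, which are
deliberately summed across products, basal plus bolus, because the
clinically meaningful quantity for the insulin tier is total units).

The classification is an endpoint comparison. A patient's **baseline**
regimen is the set of medications prescribed in the half-open 12-month
window starting at their first diabetes-medication record; the **final**
regimen is the closed 12-month window ending at the extraction end date.
Within a window each medication's dose is its most recent record (same-date
duplicates keep the higher dose — conservative against over-calling a
reduction). Interim churn between the windows is summarized only as a
transition count: a regimen that wanders but returns to the same endpoint is
"no change" by construction. The window length (365 days) and analysis
period (defaults 2014-05-15 through 2023-03-13) are configuration, not
constants.

Eligibility mirrors the source cohort: age 18–89 with at least two
encounters inside the analysis window. The records/encounters dialects carry
no age column, so demographics ride in an optional third table; when it is
absent the age criterion is skipped rather than excluding everyone, and a
patient present in the table without an age is excluded as `missing_age`.

## The rules

Within each tier:

- **Insulin** — total daily units decreased → dose reduced; insulin absent
  from the final window → discontinued, reported as a *switch* when a new
  non-insulin medication started in its place.
- **Non-insulin tier** — these agents are laterally equivalent, so a switch
  (some stopped *and* some started) is lateral, a net loss of agents is a
  stop, and dose changes are evaluated per drug, never summed across drugs.
  A regimen that collapses to metformin only is the switch-to-metformin
  subtype.
- **Metformin** — compared at category level ("total metformin dosing", so a
  plain↔extended-release product switch at equal dose is no change). A stop
  requires no restart at any point: a restart is detected as a metformin
  record following a gap of more than a year since the previous one — the
  same annual-refill coverage logic that underlies inferred discontinuation.

Escalation is the mirror image: higher total insulin units, a per-drug or
total-metformin dose increase, a move up the tier ordering (new insulin in a
patient not previously on it; a net addition of non-insulin agents; any
addition with nothing stopped, including initiation from an empty baseline).
A stop that is part of an up-switch (e.g. glipizide → insulin) is escalation
only, not a mixed signal: moving up the ordering is defined as a medication
increase regardless of what it replaced. An insulin product switch at equal
total units is no change at category level.

Resolution order: whole-regimen inferred discontinuation; clean
deprescribing (no escalation signal); escalation only; both → UNCLEAR
(mixed signals are never netted across categories — that judgment belongs to
a human reviewer); lateral only; no change; more interim transitions than
`max_transitions` (default 4, configurable; a judgment call with no
published value) without a net tier change → UNCLEAR; anything else →
UNCLEAR. Subtype precedence follows the tier ordering with the more specific
switch rules outranking the stops they imply (insulin switch over insulin
discontinued; switch-to-metformin over the non-insulin stop), so the
reported subtype is the most informative matched rule; all matched rules are
retained in the output.

Two structural guarantees follow: every trajectory receives exactly one
(top level, subtype), and the DEPRESCRIBED count of any cohort equals the
sum over the eight deprescribing subtypes.

## Inferred discontinuation and its limits

The flag is true iff the last prescription predates the extraction end by
more than `window_days` **and** at least one encounter postdates that
prescription. Without such an encounter an empty final window is
undecidable — the patient may simply have left the practice — so those cases
are UNCLEAR, never deprescribed. The flag is monotone: adding a later
prescription can only clear it.

## Synthetic cohorts

The generator emits the exact table dialects the pipeline consumes, one
scenario per patient with the intended label planted: the eight
deprescribing subtypes, lateral switch chains, dose and category escalation,
stable regimens (half with an interim dose excursion that the endpoint
comparison must ignore), inferred discontinuation, loss to follow-up (truth
UNCLEAR), a mixed-signal case (truth UNCLEAR), and a planted-ineligible
patient. Dose menus are small fixed grids (insulin 10/20/40 units/day,
metformin 500–2000 mg/day, one menu per non-insulin agent) and change points
are drawn uniformly with wide margins so each planted event falls cleanly in
the baseline window, the interim, or the final window; refills recur every
140–200 days, inside annual-refill coverage. Names are written the way
exports write them (case variants, strength suffixes, brands) and ~40% of
patients carry a non-diabetes prescription row that must be set aside as
unrecognized. Generation is seeded and byte-reproducible.

What the generator does *not* emulate: overlapping days-supply, pharmacy
dispensing vs prescribing, free-text dose instructions, titration schedules,
comorbidities, or any correlation between scenarios and demographics.
Passing the round-trip tests therefore shows the engine implements the rules
faithfully on clean, well-separated trajectories; it does not certify
performance on messy real-world exports, where the UNCLEAR route and the
audit trail (matched rules, evidence lines, suppressed-comparison counts)
are the intended safety valve.

## Verification strategy and problem sizes

The rule engine is checked against an independently written flat
transcription of the framework's predicates by exhaustive enumeration of all
(baseline, final) pairs over a 4-medication grid with three dose levels plus
absence per medication (256 regimens, 65,536 pairs, exact agreement
required). Round-trip recovery of planted labels is tested on a 600-patient
cohort plus smaller cohorts in unit tests; the discontinuation rule and the
dose formula are property-tested with randomized inputs; determinism is
checked at the byte level on written tables. These sizes run the whole suite
in well under a minute while covering the full rule lattice exhaustively at
the grid level.

## Numerical and degenerate-input choices

Dose comparisons are exact float comparisons on values that arrive as
tabulated decimals multiplied by small frequencies; no tolerance is applied,
so any strict decrease counts as a reduction (the framework defines no
minimum clinically important difference). Records dated outside the analysis
window and encounters outside it are dropped with counts. A combination
product whose component split is not encoded in the lexicon is kept whole
under its lexicon tier and flagged, never silently dropped. Patients with
encounters but no resolvable medication records flow through as empty
regimens (no change). A category whose doses mix units across windows has
its dose-change rules suppressed — presence/absence rules still apply — and
the suppression is recorded in the evidence trail.

## Known limitations

- The bundled lexicon is a curated stand-in covering the common U.S.
  glucose-lowering products, not a complete terminology; sites should extend
  the table rather than rely on fuzzy matching, which is deliberately absent.
- Endpoint comparison cannot see a reduction that is initiated and fully
  reversed between the windows; this is by design (the "no change"
  definition) but means the subtype counts are about net trajectories, not
  events.
- The non-insulin tier is treated as flat; no finer intensity ranking among
  those agents is modeled.
- Inferred discontinuation leans on the annual-refill practice policy; in a
  setting without that policy the rule should be disabled by setting a
  longer `window_days` or ignored.
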