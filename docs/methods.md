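# Methods

## The screening model

`depscreen` implements a staged triage algorithm for depression and
suicide risk designed for general medical practices (GMPs), and the
cohort-level analysis built on top of it.

Stage 1 is the four-item short form of the Beck Hopelessness Scale
(BHS-4): four items scored 0–3, total 0–12. Hopelessness is an
independent and strong predictor of suicide risk, so it is assessed
first. Three zones of the total partition the scale:

| BHS-4 total | meaning | next step |
|---|---|---|
| 0 … `bhs_stop_max` | no further evaluation | stop |
| `bhs_stop_max`+1 … 5 | intermediate | complete BDI-9 |
| ≥ 6 | acute suicide risk | immediate psychiatric referral |

Totals of 9+ within the referral zone carry a "very high risk"
annotation (`TriageOutcome.very_high_risk`); both sub-ranges lead to
psychiatrist contact, so they are one category.

Stage 2 is the Hungarian nine-item short form of the Beck Depression
Inventory (BDI-9): nine items scored 1–4, total 9–36, severity bands
9–13 none / 14–18 mild / 19–24 moderate / ≥25 severe. The raw 1–4 item
coding is deliberately kept (not rebased to 0–3) so these published
band boundaries apply verbatim. Totals < 19 end screening; 19–24
trigger a DSM-5 major-depressive-episode (MDE) assessment; ≥ 25 mean
immediate referral.

Stage 3 is the MDE rule: MDE is present iff at least one of the two
core symptoms (depressed mood, loss of interest) and at least four
additional DSM-5 symptoms are present. Among MDE cases, a suicidality
qualifier — current ideation, a plan, or a previous attempt — routes to
psychiatrist treatment; without it, treatment can start in the GMP.
Non-MDE cases are flagged for considered referral or re-screening after
three months; the three-month follow-up is an action label only, no
longitudinal state is modelled.

Respondents with a previously identified psychiatric condition are
excluded *before* screening (they are already in specialist care), but
they remain in every denominator. Any missing item voids the whole
instrument — no prorating or imputation — because the survey analysis
this package reproduces accounts for missingness at the instrument
level. Records in the BDI-indicated zone whose BDI-9 is incomplete form
their own terminal category (`BDI_MISSING`) rather than being dropped.

Three protocols are shipped, differing only in the stop cutoff:
P1 stops at BHS 0–1 (the original algorithm), P2 at 0–2, P3 at 0–3.
All cutoff comparisons use closed intervals exactly as published.

## Cohort tabulation and extrapolation

`tabulate` assigns every record of a cohort to exactly one terminal
category and keeps the **full** cohort size N as the denominator, so
prevalences (count/N × 100) are fractions of the whole sample including
excluded and missing records. Derived aggregates:

* *definitive care* = BHS referrals + BDI referrals,
* *potential care* = the BDI 19–24 group (counted whether or not DSM-5
  flags were collected; when flags exist the MDE sub-split is reported
  additionally, never instead).

Rounding of prevalences (2 decimals, half away from zero) happens only
at presentation; all aggregation uses raw counts.

`extrapolate_count(c, N, T)` returns round-half-away-from-zero(c·T/N),
computed in exact integer arithmetic (`divmod`, remainder comparison),
so results are bit-reproducible for any operand sizes and the bound
|estimate − c·T/N| ≤ ½ holds exactly. The two shipped targets are an
average Hungarian GMP (1,600 registered adults) and the Hungarian
population aged 25+ in 2018 (7,288,433); both are plain config values,
so other targets can be supplied. Aggregates are extrapolated from
their raw summed counts (aggregate-then-round); the component-wise
(round-then-sum) convention is recorded alongside, because at least one
published practice-level figure appears to arise from it.

## The synthetic cohort

The survey behind the published analysis (Hungarostudy 2002,
N = 12,668) is not publicly deposited, but the published branch counts
of all three protocols pin down most of the joint distribution of
(prior diagnosis, BHS zone, BDI band, missingness). The default
blueprint stores exact counts for 16 calibration cells, derived from
the published marginals by subtraction:

* BHS zones 0–1 / 2 / 3 / 4–5 / ≥6: 6,992 / 1,177 / 827 / 1,112 / 1,097;
  prior diagnosis 805; BHS missing 658.
* BDI bands inside zones 3 and 4–5 follow from the published 3–5 and
  4–5 zone band counts (19–24: 45 and 190; ≥25: 41 and 137).

Two allocations are *not* published and are fixed by a documented rule
(proportional allocation, remainders by largest remainder), with the
affected cells flagged `free` in the blueprint metadata:

* the 491 BDI-incomplete respondents are placed inside the BHS 2–5
  zone and split 186 / 130 / 175 across zones 2 / 3 / 4–5;
* the BDI band split inside zone 2 (740 / 143 / 108) follows the
  BDI-complete band distribution of zones 3–5.

Only protocol 1's unprinted BDI-stage sub-counts depend on these free
cells, which is why they are documented (see the reconciliation note
below) rather than asserted.

`generate` materialises exactly cell-many records per cell, sampling
item vectors uniformly from all compositions consistent with the cell's
total-score range (enumerated: 4⁴ BHS, 4⁹ BDI compositions). Cell
counts are therefore blueprint-determined — *every* seed reproduces the
published census exactly; the seed changes only item values and record
order. Exact-count generation is the default because the published
analysis is a census of the sample, not a sampling experiment;
`sample_stochastic` draws cell sizes multinomially for robustness
experiments and property tests.

What the generator does **not** emulate: the survey's cluster-randomised
sampling design, refusal mechanism, interviewer effects, item-level
response correlations within an instrument, and demographic structure
(sex/age are uniform placeholders, marked non-calibrated). DSM-5
symptom flags are generated only on request (`mde_rate`), since the
published cohort accounting does not use them. Passing tests therefore
show that the *algorithmic pipeline* reproduces the published
tabulations from a cohort with the published margins — not that the
generator mimics individual-level survey responses.

## Numerical and design choices

* Missing values: `None` at the record level, nullable `Int64` in
  DataFrames/CSV (empty cells).
* Percentages: `Decimal` quantisation, ROUND_HALF_UP on non-negative
  values (half away from zero).
* Extrapolation: integer `divmod`, never floating point.
* Largest-remainder ties break toward the earlier cell (deterministic).
* Evaluation order in triage is fixed (exclusion → BHS missing → BHS
  zone → BDI missing → BDI zone → MDE) so each record has exactly one
  category; an exhaustive truth-table oracle in the test suite checks
  agreement on all enumerable inputs.
* The test suite's stochastic check uses 200 multinomial cohorts at
  n = 12,668 and requires the mean referral count to sit within three
  standard errors of the census value.

## Reconciliation of non-reproducible published figures

A handful of published headline figures cannot be asserted exactly and
are instead recomputed and explained in `reconciliation_note.txt`
(emitted by every all-protocol pipeline run):

* Protocol-1 aggregate care-need figures (165 / 747,944 definitive,
  35 / 159,370 potential, 1,211 / 5,517,531 unaffected) depend on the
  unpublished BDI band split of the whole BHS 2–5 zone. Inverting the
  national estimates implies ≈203 BDI-referral and ≈277 assessment-band
  respondents; the blueprint's free-cell allocation carries 286 and 378.
  The practice-level 165 is additionally consistent with component-wise
  rounding.
* The published "15.39%" for protocol-2 BDI indication conflicts with
  its own published count (1,939/12,668 = 15.31%); the count is trusted.
* The protocol-2 potential-care national estimate (135,205) *does*
  reproduce exactly under the integer rounding rule and is stated as
  such in the note.

## Limitations

* Unweighted proportions: no survey weights, design effects or
  uncertainty intervals (the reproduced analysis reports point
  estimates only).
* Psychometric properties of the scales (reliability,
  sensitivity/specificity) are context, not computed here.
* The MDE stage is exercised only on synthetic flags; the reproduced
  cohort accounting treats the whole BDI 19–24 group as potential need.
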