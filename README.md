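# depscreen

Staged depression / suicide-risk screening for general medical
practices, applied at cohort scale.

Primary-care practices are well placed to catch depression and acute
suicide risk early, but they need instruments that are quick to
administer and an explicit decision rule. `depscreen` implements such a
two-stage triage algorithm and the population analysis built on it:

1. **BHS-4** (four-item Beck Hopelessness Scale, items 0–3, total
   0–12): totals ≤ 1 end screening, totals ≥ 6 mean immediate
   psychiatric referral, the zone in between triggers stage 2.
2. **BDI-9** (nine-item Beck Depression Inventory, items 1–4, total
   9–36): totals < 19 end screening, 19–24 indicate a DSM-5
   major-depressive-episode (MDE) assessment, ≥ 25 mean immediate
   referral.
3. **MDE check**: MDE iff ≥ 1 core symptom (depressed mood, loss of
   interest) and ≥ 4 additional DSM-5 symptoms; a suicidality qualifier
   (ideation, plan, previous attempt) routes MDE cases to a
   psychiatrist, otherwise treatment can start in the practice.

Two cutoff variants (stopping at BHS 0–2 or 0–3 instead of 0–1) are
shipped as protocols P2 and P3. The package triages whole cohorts
(CSV, one row per respondent), tabulates terminal categories against
the full-sample denominator N, and extrapolates
round-half-away-from-zero(count · T / N) to target populations — by
default an average Hungarian practice (T = 1,600 adults) and the
Hungarian 25+ population (T = 7,288,433, 2018).

Because the survey that motivates the analysis (Hungarostudy 2002,
N = 12,668) is not publicly deposited, the package includes a seedable
synthetic-cohort generator calibrated to the survey's published
screening margins; tabulating the generated cohort reproduces every
published branch count exactly, for every seed. See `docs/methods.md`
for the model, the calibration and its limits.

## Worked example

```python
import depscreen as ds

cohort = ds.generate(ds.default_blueprint(), seed=42)   # N = 12,668
table = ds.tabulate(cohort, ds.get_protocol("P1"))
print(table.count(ds.Category.IMMEDIATE_REFERRAL_BHS),
      table.prevalence_pct(ds.Category.IMMEDIATE_REFERRAL_BHS))
# 1097 8.66

gmp = ds.extrapolate_table(table, ds.GMP_TARGET)
nat = ds.extrapolate_table(table, ds.NATIONAL_25PLUS_TARGET)
print(gmp.estimate(ds.Category.IMMEDIATE_REFERRAL_BHS),
      nat.estimate(ds.Category.IMMEDIATE_REFERRAL_BHS))
# 139 631150
```

1,097 of 12,668 respondents (8.66%) hit the BHS referral cutoff: in an
average 1,600-adult practice that is 139 people needing immediate
psychiatric referral, and 631,150 nationwide. The full category table
for the same run:

```text
>>> from depscreen.reporting import render_cohort_table
>>> print(render_cohort_table(table))
Screening categories, protocol P1 (N = 12,668)
==================================================
                   category  count  prevalence_pct
 EXCLUDED_PRIOR_PSYCHIATRIC    805            6.35
                MISSING_BHS    658            5.19
      NO_FURTHER_EVALUATION   6992           55.19
     IMMEDIATE_REFERRAL_BHS   1097            8.66
                BDI_MISSING    491            3.88
           BDI_BELOW_ASSESS   1961           15.48
   MDE_ASSESSMENT_INDICATED    378            2.98
     IMMEDIATE_REFERRAL_BDI    286            2.26
  BDI_INDICATED (aggregate)   3116           24.60
DEFINITIVE_CARE (aggregate)   1383           10.92
 POTENTIAL_CARE (aggregate)    378            2.98
```

The top six published counts (805 excluded, 658 BHS-missing, 6,992
stop, 1,097 referral, 3,116 BDI-indicated, 491 BDI-missing) are fixed
by the calibration; the BDI sub-split of protocol 1 (1,961 / 378 / 286)
depends on cells the survey never published and is a documented free
allocation (`docs/methods.md`).

The same pipeline from the shell:

```sh
screen run --synthetic --seed 42 --protocol all \
    --targets gmp:1600,national:7288433 --outdir out/
```

writes per-protocol category/estimate tables, a cross-protocol summary
of definitive care need by BHS cutoff (161 / 733,561 for P2 and
156 / 709,972 for P3 at practice/national scale), and a reconciliation
note for the few published figures that rest on unpublished cells.
`screen synth` writes a synthetic cohort CSV; `screen table3` prints
the cross-protocol summary.

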