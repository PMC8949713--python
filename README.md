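# boutscan

Minute-epoch accelerometry analysis for two-arm rehabilitation trials:
wear-time validation, MET-based intensity classification, MVPA
bout-accumulation spectra, per-participant activity summaries, and the
trial statistics layer (paired/independent *t* tests, two-way mixed-design
ANOVA, Spearman rank correlation), plus a synthetic minute-epoch cohort
generator with a planted-truth ledger for end-to-end testing.

## The problem

Pulmonary rehabilitation reliably improves exercise capacity in people
with COPD, but whether it changes free-living physical activity — and in
what *pattern* — is much less clear. Two interventions can produce the
same step count through very different behaviours: many short (~2-minute)
bursts of moderate activity, or fewer but prolonged (≥20-minute) bouts.
Distinguishing these requires going beyond steps/day to the
**bout-accumulation spectrum**: how many maximal runs of
moderate-to-vigorous activity reach each duration floor.

`boutscan` implements that derivation pipeline for minute-epoch armband
data and the statistics used to compare two trial arms (e.g. web-based vs
centre-based rehabilitation) at baseline and discharge.

## The derivation in brief

Given one-minute epochs with MET values (multiples of resting oxygen
consumption, ≈3.5 mL O₂/kg/min):

* **Intensity classes** — vigorous: METs > 6; moderate: 3 ≤ METs ≤ 6;
  light: 1.5 < METs < 3; sedentary-or-below otherwise.
* **Wear validity** — a day is valid with ≥ 480 worn minutes (8 h); a
  participant-timepoint enters the analysis with ≥ 4 valid days.
* **Bouts** — maximal runs of consecutive worn epochs at MVPA intensity
  (≥ 3 METs; vigorous minutes never break a run). A recording gap, a
  non-worn epoch, or (by default) a single sub-moderate minute ends a
  bout; an interruption tolerance is available via `max_break_min`.
* **Spectrum** — for duration floors d ∈ {2, 5, 10, 20} minutes,
  counts/day(d) = (# bouts with length ≥ d over valid days) / (# valid
  days); plus the pooled mean bout length and total MVPA min/day.
* **Participant summary** — steps/day, wear-weighted daily MET mean,
  % of wear time in the moderate class, and the spectrum fields.
* **Statistics** — within-arm paired *t*; between-arm independent *t*
  (pooled variance); two-way mixed ANOVA with arm as the between-subjects
  factor and timepoint as the within-subjects factor (for two timepoints
  the interaction F equals the squared pooled *t* on change scores);
  Spearman ρ of clinical covariates (age, BMI, FEV₁ %predicted) against
  activity, arms pooled. No multiplicity adjustment is applied; the run
  log records the number of tests next to α.

## Input formats

Epoch CSV (one row per participant-minute, ISO-8601 timestamps):

```
participant_id,timepoint,timestamp,mets,steps[,worn]
P1,baseline,2014-01-06T08:00:00,3.4,55,1
```

`timepoint` is `baseline` or `discharge`. `worn` (0/1) is optional: when
absent, an epoch is non-worn iff its `mets` cell is blank.

Manifest CSV (one row per participant):

```
participant_id,arm,age,bmi,fev1_pct_pred,sex[,iswt_m,eswt_s]
```

with `arm` in `{web, conventional}`.

## Worked example

Simulate a default two-arm cohort (20 web / 34 conventional participants,
7 days at each timepoint) and run the pipeline:

```bash
boutscan simulate --seed 5763 --out sim/
boutscan run --epochs sim/epochs.csv --manifest sim/manifest.csv --out results/
```

`results/group_summary.csv` (display-rounded excerpt):

```
              metric          arm  baseline_mean  baseline_sd  discharge_mean  discharge_sd  pct_change
       steps_per_day          web         5226.0        437.0          5896.0         441.0          13
       steps_per_day conventional         5316.0        432.0          6464.0         483.0          22
mean_bout_length_min          web            2.8          0.2             2.8           0.1           0
mean_bout_length_min conventional            2.7          0.2             4.5           0.3          64
             bouts_2          web           17.6          1.6            20.5           2.3          17
             bouts_2 conventional           18.1          1.8            17.5           1.7          -3
```

The two planted intervention phenotypes are visible directly: the web arm
gains ~3 two-minute bouts/day (its 13% step increase accrues through short
bouts, mean bout length unchanged), while the conventional arm lengthens
its bouts (mean length 2.7 → 4.5 min) at a stable ≥2-minute bout count.

`results/stats.csv` for steps/day (excerpt):

```
                 family                 scope    estimate  statistic  df1  df2 p_display
               paired_t                   web  669.765238   4.070814 19.0  NaN     <.001
          independent_t baseline_between_arms  -89.226611  -0.730100 52.0  NaN      .469
mixed_anova_interaction     anova_interaction    7.132188   7.132188  1.0 52.0      .010
```

i.e. arms were comparable at baseline (p=.469), the web arm increased
steps within-group (mean +670 steps/day, p<.001), and the arms' changes
differed (interaction F(1,52)=7.13, p=.010).

Published group means can be fed straight through the same reporting
layer: steps/day cells of 5464.6 → 6111.7 render as a 12% (+647 steps)
change, and 5300.1 → 5409.4 as 2%.

## Configuration

Every cut-point is a flag or YAML key: `--min-wear-hours` (8),
`--min-valid-days` (4), `--met-moderate` (3), `--met-vigorous` (6),
`--bout-thresholds` (2,5,10,20), `--max-break-min` (0). See
`docs/methods.md` for the full model description, defaults and
limitations.
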