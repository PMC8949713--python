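# Methods

## Scope and units of analysis

`boutscan` starts from minute epochs (the conventional granularity of
armband energy-expenditure exports; all bout duration floors are whole
minutes) carrying a MET estimate, a step count and an on-body flag. The
unit of wear accounting is the midnight-to-midnight calendar day — the
simplest defensible convention, and the reason bouts never span a day
boundary. Raw-sensor-to-MET conversion is out of scope: the package
consumes MET-per-epoch input.

## Intensity classification

Cut-points follow the common armband convention: vigorous strictly above
6 METs, moderate on the closed band [3, 6] (so 6.0 METs is moderate, not
vigorous), light on the open band (1.5, 3), sedentary-or-below otherwise.
The boundary placement matters at exactly the band edges and is
configurable (`IntensityThresholds`); the defaults implement the closed
moderate interval because the vigorous bound is stated as a strict
inequality.

## Wear-time validity

A day is valid with ≥ 480 *worn* minutes; "data" is read as worn time,
the conservative choice when recorded-vs-worn is not distinguished. A
participant-timepoint enters the analysis set with ≥ 4 valid days,
assessed per timepoint: a participant can qualify at baseline only, and
paired analyses then drop them (complete-case). Whether the original
criterion was per timepoint or pooled is not derivable from the trial
description; per timepoint is the stricter reading and is what the
package implements. Non-wear periods are never imputed. Inclusion is
monotone in both criterion components and invariant to non-worn epochs'
MET values — both are property-tested.

When the input lacks an on-body column, an epoch counts as non-worn iff
its MET cell is blank: the device only emits an energy estimate while
worn, so missing data is the only defensible proxy.

## Bout detection

A bout is a maximal run of consecutive worn epochs at MVPA intensity
(moderate *or* vigorous — a vigorous minute must not break a "moderate"
bout). Default behaviour is strict: a recording gap, a non-worn epoch, or
one worn sub-moderate minute ends the run. This is the only rule under
which a "2-minute bout" floor is meaningful; some armband pipelines
instead use an 80%-of-epochs-above-threshold rule, so absolute bout
counts from other software may differ. An interruption tolerance
(`max_break_min`, default 0) merges runs separated by at most that many
worn sub-moderate, gap-free minutes; merged durations still count MVPA
minutes only. Length-1 runs are retained as 1-minute bouts: they meet no
≥2-minute floor but contribute to mean bout length and total MVPA.

The detector is run-length based and is tested for exact equivalence
against a quadratic brute-force oracle (every interval checked for
run-ness and maximality) on random sequences, alongside two invariants:
the spectrum is non-increasing in the duration floor, and the sum of bout
durations equals total MVPA minutes.

## Participant summaries

* steps/day — mean over valid days;
* daily METs — worn-epoch MET mean pooled (wear-weighted) across valid
  days, so non-wear cannot dilute it and short days do not get equal
  weight with long ones;
* % moderate time — 100 × moderate minutes / wear minutes, pooled; the
  moderate class only, since it is reported separately from total MVPA;
* bouts/day at each floor, mean bout length, total MVPA min/day — from
  the pooled spectrum.

Percent change between timepoints is computed on group means
(`100·(m₂−m₁)/m₁`, undefined for non-positive baselines), matching how
trial tables print "from 5465 to 6112 (12%)"; the mean of individual
percent changes is available via `change_on="participants"`. Display
rounding (steps to integers, METs to 2 decimals, bout metrics to 1)
lives only in the rendering layer; CSVs keep full precision.

## Statistics

The test statistics are computed from their definitions; scipy supplies
only the t and F reference distributions.

* Independent *t*: pooled-variance Student (the generic "independent
  samples t test"); Welch is exposed as an option.
* Paired *t*: one-sample t on differences.
* Mixed ANOVA: classical weighted sums-of-squares partition with one
  between-subjects factor (arm) and one within-subjects factor (time):
  between-subjects SS splits into {group, subjects-within-group},
  within-subjects SS into {time, group×time, time×subjects-within-group};
  F(group) = MS(group)/MS(subjects), F(time) and F(interaction) against
  MS(time×subjects). With two time levels sphericity holds trivially and
  the interaction F equals the squared pooled t on change scores — an
  identity asserted to 1e-10 on random data, including unbalanced arms.
  (An SPSS-style Type III analysis differs only in the time main effect
  under imbalance; the interaction and group effects coincide.)
* Spearman: Pearson correlation of mid-ranks (tie-aware), two-sided p
  from t = ρ√((n−2)/(1−ρ²)). Undefined for constant inputs; the
  correlation screen converts that to a flagged NA row rather than
  aborting.

Degenerate zero-variance inputs produce flagged conventional results
(t = 0, p = 1 for identical samples; p = 0 for a nonzero shift with no
spread), never NaNs. p values display to three decimals with the "<.001"
convention. No multiple-testing adjustment is applied anywhere; the run
log records the number of tests performed next to α = 0.05. Calibration
is verified empirically: under a null two-arm simulation the paired t,
independent t and interaction each reject at a rate within [0.035, 0.065]
at α = .05 over 2,000 replicates.

## Synthetic cohort generator

The generator emulates a two-arm (20 web / 34 conventional),
two-timepoint trial of sedentary COPD patients, with per-arm covariates
(age, BMI, FEV₁ %predicted, shuttle-walk distances, sex) drawn from
normals matched to the cohort's baseline characteristics.

Each participant-day is 1440 epochs with a 07:00–22:00 wear window
(900 min). MVPA bouts number Poisson(28)/day with geometric lengths
(p = 0.36, mean 2.78 min), placed uniformly at random with ≥1 non-MVPA
minute between bouts and at the window edges, so every planted bout is
recoverable as exactly one maximal run and planted MVPA minutes equal
detected MVPA minutes exactly. Light activity occupies ~120 random worn
minutes; the sedentary background is N(1.1, 0.15) clipped to ≤1.5 METs.
Steps are Poisson per epoch at 50/min (MVPA) and 12/min (light). These
defaults put the expected phenotype at ≈5,300 steps/day, daily METs ≈1.5,
≈8.6% moderate time and ≈18 ≥2-minute bouts/day — the scale of a COPD
rehabilitation cohort. With probability 0.15 a day's window is truncated
below 480 min (an invalid day). A master seed fans out through
`SeedSequence.spawn` to per-participant streams, so identical seeds give
byte-identical CSVs and single participants can be regenerated.

Geometric bout lengths are a modelling choice for tractability — the
memoryless tail gives closed-form expected spectra
E[counts/day ≥ d] = rate·(1−p)^(d−1) for oracle tests — not a claim about
COPD physiology. Real bout-length distributions are heavier-tailed: no
geometric parameter can simultaneously match a 2.8-minute mean bout
length and the ≥20-minute bout counts seen in real cohorts. Consequently
the planted intervention effects are *qualitative* phenotypes, not
calibrated effect sizes:

* web arm: +5 bouts/day, lengths unchanged — steps rise ≈13% purely
  through added short bouts;
* conventional arm: p×0.61 with −5 bouts/day, chosen so the expected
  ≥2-minute count is unchanged while the ≥20-minute count rises ~30-fold
  (and, as a side effect, total MVPA and steps rise too — the generator
  does not pin steps under the long-bout effect).

What passing tests therefore show about real data: the *derivation* is
exact (bout detection, wear filtering, summarisation recover planted
truth to machine precision or within Monte-Carlo error), and the
statistics are calibrated. What they do not show: that real armband data
follow geometric bout lengths, fixed wear windows, or class-constant step
rates; there is no circadian or seasonal structure, no autocorrelated
MET noise, and no measurement error model.

## Numerical and degenerate-input choices

* Wear/intensity boundaries are closed as documented above; ties at a
  cut-point are deterministic, not random.
* CSV round-tripping uses `float_precision="round_trip"` so
  write→read→write is byte-stable.
* Zero valid days → an explicit undefined-spectrum error; no bouts → a
  flagged zero mean bout length; empty day → a zero summary marked
  invalid.
* Bout placement sheds the longest drawn bouts when a truncated
  (invalid-day) window cannot hold them, recording the shed count in the
  truth ledger.

## Problem sizes used in the checked runs

The shipped verification runs use the full 54-participant cohort at
7 days per timepoint (≈1.1 M epochs), 2,000 null replicates for
calibration, 1,000 random sequences for detector equivalence, and 200
days for planted-parameter recovery (within 3 Monte-Carlo standard
errors) — sizes at which the Monte-Carlo error of every checked quantity
is far smaller than the assertion margins.

## Known limitations

* The mixed ANOVA is univariate and complete-case; no mixed-effects or
  nonparametric alternatives.
* Categorical baseline comparisons (sex, smoking status) are out of
  scope.
* No sedentary-bout, intensity-gradient or MX metrics.
* The strict-run bout rule may undercount bouts relative to
  80%-tolerance pipelines on noisy data (see Bout detection).
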