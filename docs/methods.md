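# Methods

## Scope and data model

The package analyzes long-format questionnaire data from a small
longitudinal cohort: 11 participants by default, five visits (pre, post,
1, 3 and 6 months), ten instruments yielding 21 score names (eight
instrument totals without subscales, the CAPS-5 total plus its B/C/D/E
cluster and dissociation subtotals, and the DERS-18 total plus its six
subscales). Two instruments have schedule gaps: the CAPS-5 interview was
not administered at the 1-month visit and the DERS-18 not at the 6-month
visit. Input is either an item-level CSV
(`participant_id,timepoint,instrument,item_index,value`) or a pre-computed
score CSV.

## Instrument constants

Instrument definitions live in a built-in catalog
(`trajperm.instruments.default_catalog`) and can be overridden from a YAML
file. Noteworthy choices:

* **PCL-5** is defined as the standard 20-item DSM-5 form (items 0–4,
  total 0–80). The trial's report describes it as "17-item" while also
  giving the 0–80 range; these are mutually inconsistent, and the 0–80
  range identifies the standard 20-item instrument. The item count is
  overridable for users who want the 17-item variant.
* **DERS-18** has six 3-item subscales (Awareness, Clarity, Goals,
  Impulse, Nonacceptance, Strategies) on a 1–5 scale, so each subscale
  ranges 3–15 and the total 18–90. The three Awareness items are
  reverse-keyed. (An 18-item form cannot have 3–18 subscale ranges; 3–15
  is forced by 18 items / 6 subscales.)
* **CAPS-5** is ingested as 22 severity items on 0–4: 20 symptom items
  partitioned B=5, C=2, D=7, E=6 (their sum is the total symptom score,
  0–80) plus 2 dissociation items scored separately. Interview logic and
  diagnostic criterion counting are not modeled.
* **MISS-M-SF** is modeled as 10 items on 1–10 (total 10–100); only the
  total range is published, so the item split is an assumption.
* **AUDIT** is modeled as 10 uniform 0–4 items (total 0–40); the
  irregular response sets of its last two items are not modeled since only
  totals feed the analysis (per-item bounds are overridable).
* Interpretive bands (PHQ-9/GAD-7 severity bands, PDEQ > 15, AUDIT ≥ 8,
  OQ-45 ≥ 63) are presentation-only and never feed inference. Fractional
  scores are classified by the band whose closed integer interval contains
  `floor(score)`.

## Scoring and the 75% rule

Every score is the sum of its items after reverse-keying. "At least 75%
answered" is read literally as `frac_answered >= 0.75`, applied
independently per score (per subscale for subscale scores, over the full
item set for totals): a 9-item score needs 7 answers (6/9 < 0.75 ≤ 7/9), a
3-item subscale needs all 3, so one missing DERS-18 item makes its
subscale missing while leaving the 17/18-answered total imputable.
Imputation fills each missing item with the mean of the answered items *on
the scored (post-reversal) scale* — means on the raw scale would pull
reverse-keyed sums the wrong way. Imputed scores are carried at full
precision (no rounding). Each score carries a provenance tag: `full`
(all items answered), `imputed` (≥ 75%), or `missing` (< 75%, value NaN).

## Trend model

For one score, the model is `y_pt = a_p + b·x_t + e_pt` with one offset
per participant and a shared slope, fit by least squares over observed
cells only (cell-level listwise deletion). Time codes default to ordinal
consecutive integers over the visits actually collected for that
instrument (0..4, or 0..3 for CAPS-5 and DERS-18) — the published slopes
are only consistent with unit-spaced coding — with a months-since-baseline
calendar coding (0, 1.5, 3, 5, 8) available as an option. For the CAPS-5
the ordinal default codes its four collected visits 0,1,2,3; coding the
gap as 0,1,3,4 can be expressed through the calendar scheme.

The design has one indicator column per participant (participants with a
single observation keep their column; their residual is forced to zero and
they contribute nothing to the slope) and no global intercept. The solver
is `numpy.linalg.lstsq` (minimum-norm on rank deficiency, e.g. a
participant with zero observations). The slope is identifiable iff at
least one participant is observed at two distinct time codes; otherwise
the fit raises. By Frisch–Waugh–Lovell the slope equals the
within-participant estimator
`b = Σ_p Σ_t (x_t − x̄_p) y_pt / Σ_p Σ_t (x_t − x̄_p)²`; `within_slope`
exposes this closed form, the test suite asserts its equality with the
`lstsq` route to 1e-10, and the permutation engine uses it for speed.

## Permutation test

Under the null of no time trend, each participant's observed values are
exchangeable across their own observed visits. Each replicate shuffles
every participant's observed values among their observed time codes
independently and uniformly; missing cells never move, so the design —
and hence the within-estimator denominator — is constant across
replicates, and each replicate slope is a dot product of participant-wise
centered codes with shuffled values (vectorized over all replicates).
The empirical distribution comprises `n_perm` replicates (default 99,999)
plus the observed slope as one more sample; the p-value is the fraction of
the `n_perm + 1` samples at least as extreme as the observed statistic,
so p-values live on the lattice `k/(n_perm+1)` with floor `1/100000` at
defaults. Extremity is `|slope|` (two-sided) by default — the published
family contains a significant positive slope under the same procedure as
negative ones — with one-sided modes available. Ties count as extreme
(conservative), with a 1e-9 relative tolerance so exact ties (constant
data) are counted. An exhaustive enumerator over the full within-
participant arrangement group (≤ 10^6 combinations) provides exact
p-values on small series and is the oracle for the Monte Carlo path.

Randomness: per-score integer child seeds are derived from the master
seed via `numpy.random.SeedSequence`, recorded in the output, so any
single score's p-value can be reproduced in isolation.

## Multiplicity

Benjamini–Hochberg step-up across the family of 21 p-values: sort
ascending, `k* = max{k : p(k) ≤ k·q/m}`, threshold `p(k*)` (0 if none),
reject all p ≤ threshold; ties at the threshold are rejected together and
flags are returned in input order. The trial never states its q level;
q = 0.05 is the default and is validated by an acceptance test that feeds
the 21 published p-values through `bh_correct` and recovers the published
threshold of .031 with exactly the 16 published survivors.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with defaults
equal to the published study conditions: 11 participants, the published
per-score baseline means/SDs and slopes, the two schedule gaps. Latent
scores follow `L_pt = μ0 + b_p + β·x_t + ε_pt` with
`b_p ~ N(0, icc·sd²)`, `ε ~ N(0, (1−icc)·sd²)`; the intraclass correlation
defaults to 0.6, a typical value for repeated questionnaire
administration (the true within-subject correlation of the study is
unknowable from its report). For CAPS-5 and DERS-18 the *subscales* are
the generated units and totals emerge as their sums, which reproduces the
published total means exactly and total slopes up to printed rounding
(the published subscale slopes sum to the totals). Total variances are
consequently somewhat below the published total SDs (subscale latents are
independent); this is a known simplification.

Item disaggregation splits the clamped, rounded latent total evenly
across the score's items with a randomized remainder, on the scored scale,
then un-reverses reverse-keyed items — totals hit the latent target
exactly (within rounding) and items respect bounds. Correlated item
structure is out of scope.

Missingness has two mechanisms: each item answer is independently blanked
with `item_missing_rate`, and whole participant-visits are dropped (rows
absent, emulating pandemic-style collection gaps) with
`visit_missing_rate = 0.03`. The item rate default 0.0047 was calibrated
(by exact binomial computation over the catalog's item counts and
schedules) so that scoring default cohorts yields a provenance mix near
the published 95.2% full / 4.5% imputed / 0.3% missing; the achieved mix
is ≈ 95.2% / 4.4% / 0.5% — a single uniform item rate cannot hit both the
imputed and missing fractions exactly, since small (2–3 item) scores jump
straight from full to missing. All draws derive from a master seed
through named child streams (latent, items, missingness), so cohorts are
byte-reproducible and stages independently regenerable.

`generate_score_table` is a fast path that emits the latent scores
directly (continuous, no clamping, rounding or missingness). Calibration
and estimator-recovery studies use it: the estimator's unbiasedness is a
property of the latent linear model, and item rounding/clamping would
bias recovery for scores whose published means sit near a bound (e.g.
CAPS-5 dissociation at 1.2 ± 1.5 just above 0).

## What the simulations show — and don't

Passing calibration and recovery tests show the pipeline's inference is
valid *under the generator's assumptions*: normal latents, linear mean
trajectories, exchangeable within-participant noise, missingness
independent of severity (MCAR). Real trial data may violate any of these
(e.g. dropout related to symptom severity); the tests say nothing about
robustness to such violations, and the trial's own per-score slopes and
p-values are not reproducible without its individual-level data.

## Problem sizes and tolerances

* Monte Carlo vs exhaustive agreement: 50 random series (≤ 3 participants
  × ≤ 4 visits), n_perm = 9,999, within 3 binomial SDs of the exact p.
* Type-I error: 2,000 null cohorts × 21 scores at n_perm = 999, pooled
  rejection rate at α = 0.05 required in [0.035, 0.065] (observed ≈ 0.045
  — the lattice at n_perm = 999 makes 0.05 exactly attainable, and tie
  counting is conservative).
* Slope recovery: 500 cohorts at the published (μ0, sd, β); per-score mean
  estimate within 3 Monte-Carlo SEs of the generating slope.
* The acceptance script uses scaled-down replicate counts (60 cohorts for
  provenance, 400 for type-I error, 300 for recovery), chosen to keep the
  whole run under a minute while leaving Monte-Carlo error well inside
  the quantities' tolerances.
* Numerical: lstsq/within-estimator agreement asserted at 1e-10 relative;
  permutation tie tolerance 1e-9 relative; balanced-grid equivalence with
  the OLS-of-means closed form at 1e-10 relative.
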