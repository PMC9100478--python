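# Methods

## Model and estimation

### Dichotomous core

Each cut of the rating scale is fit with the dichotomous Rasch model,
`P(x_ni = 1) = σ(θ_n − b_i)`, by joint maximum likelihood (JMLE):
alternating damped Newton–Raphson steps on the item and person score
equations, starting from logits of the observed proportions. Steps are
capped at 1 logit, parameters are clamped to ±20 logits (quasi-extreme
patterns otherwise diverge), and iteration stops when the largest
parameter change in a sweep falls below 1e−5 logit (cap 1000 sweeps).
Unanchored fits are identified by centering the estimable item
difficulties to mean zero each sweep, with person abilities expressed on
the same origin.

Persons or items whose observed responses are all 0 or all 1 have no
finite MLE. They are excluded from estimation — iteratively, since
removing an extreme person can render an item extreme — but retained in
the output arrays as `NaN`, keeping indices stable for the cut-averaging
above them. The classical `(L−1)/L` JMLE shrinkage is available
(`bias_correction=True`) but off by default: the polytomous measures are
averages across cuts and the uncorrected estimates keep that average on
one consistent scale. JMLE's small multiplicative bias (order `L/(L−1)`
for `L` items) is visible in simulation as a ~3–4% inflation of the item
spread and is part of the reported recovery error.

### Successive dichotomizations

For categories `0..M` there are `M` cuts and `M` thresholds (five
categories give four thresholds, matching the packaged banks). Item
measures are the per-cut estimates averaged over the cuts in which the
item was estimable, then re-centered to mean zero. Averages over a
subset of cuts are unbiased for items (each cut's centered fit estimates
the same `b_i`) but not for persons: a cut-`k` fit expresses abilities
relative to that cut's threshold (`θ̂^(k) ≈ θ − τ_k`), so a person
estimable in only some cuts would inherit the mean threshold of those
cuts as an offset.

Person measures and thresholds are therefore iterated to a
self-consistent pair: each threshold `τ_k` is the anchored
single-parameter MLE of the cut-`k` dichotomized likelihood given the
current measures (Newton on one parameter, tolerance 1e−8; standard
error from the scalar Fisher information), and person measures solve the
composite score equation `Σ_i Σ_k σ(θ − b_i − τ_k) = raw score` — the
same equation the anchored scorer uses, so re-scoring the calibration
sample against its own exported calibration reproduces its person
measures to numerical precision. The iteration is seeded with the plain
per-cut averages and stops when thresholds change by less than 1e−7
logit (in practice 3–5 rounds). If a cut is degenerate (an unused
category leaves its dichotomization all-0 or all-1), its threshold is
`NaN` with a warning and the per-cut averaged person measures are kept.

Ordering of the thresholds follows from the construction: the anchored
score equations for successive cuts share one monotone expected-score
curve evaluated at strictly decreasing observed counts, so estimates are
strictly increasing whenever every category is used at least once (exact
ties can occur for categories never observed).

**Gauge freedom.** Adding a constant to every threshold and every person
measure leaves all response probabilities unchanged, so the threshold
origin is a convention, not an estimable quantity. This package inherits
the origin of the per-cut averages, which makes calibrated thresholds
come out approximately mean-centered. Consequently, simulated-data
recovery of generating thresholds through a full unanchored calibration
is only defined up to this shift (bounded by the magnitude of the
generating thresholds' mean); the threshold estimator itself is
validated by anchoring at the generating measures, where recovery is
well-posed and accurate to a few hundredths of a logit.

### Standard errors

Item and person standard errors are inverse square roots of the
composite-dichotomization information: every answered response
contributes `p(1−p)` at `θ_n − b_i − τ_k` for each cut `k`. Errors
therefore shrink as `1/√n`; with thousands of persons rating 30 items,
item errors are an order of magnitude below person errors. Caveat: the
composite information treats the `M` dichotomized responses of one
rating as independent, which overstates the information in a single
polytomous response; simulation shows the realized sampling error of
item measures is larger than these nominal errors (variance ratio near 3
at a few hundred persons). They are reported as the method's
conventional errors; the pooling diagnostic below deliberately does not
rely on them.

## Scoring, bounds, MCID

Person scoring against an anchored bank maximizes the composite
pseudo-likelihood (Newton with a bracketed bisection fallback on
[−20, 20], tolerance 1e−6). Missing items drop out of the score
equation: the measure stays on the bank's scale and only the standard
error grows. Estimable bounds are operationalized as the score-equation
solutions one raw-score unit inside each extreme (raw score 1 and
maximum − 1); for the full 25C bank the ceiling is 6.61 logit. The
minimum clinically important difference is `z(confidence) × SE`
(1.96 × 0.4 ≈ 0.78 logit at the instrument's typical person error).
Note that scoring a *uniform* mid-scale pattern (e.g. all ratings 2) is
well-defined here even though every single dichotomization of such a
pattern is extreme — one reason the scorer solves the composite equation
rather than averaging per-cut estimates.

## Instruments

The 25C roster drops the two general health/vision items, keeps the
remaining 24 plus the six appendix items, and collapses the driving
block (15/15a/15b/15c) into one converted item 30 — 30 items on a shared
five-category scale. The VF/SE split (20/10 items, pain items 4 and 19
assigned to VF and SE respectively) and the three driving items follow
the published rosters.

Recoding conventions shipped as reviewable data (`data/recode_tables.json`):

* Higher category = greater function, so more positive item measures mean
  harder items. Native difficulty scales (1 = no difficulty) are
  reverse-coded; "stopped doing this because of your eyesight" is the
  bottom category, which is what gives difficulty items five substantive
  levels; "stopped for other reasons / not interested" is missing.
* Driving items are wholly missing for respondents who never drove or who
  gave up driving for reasons other than eyesight alone (gating item 15b
  response 2 or 3). Respondents who stopped mainly because of eyesight
  (15b = 1) contribute category 0 on all three driving items — an
  assumption for items 16/16A, which such respondents skip on paper.
* The questionnaire's option lists are standard instrument content
  reproduced as configuration, not measured data; sites using variant
  printings can swap the tables.

The legacy 0–100 composite score is retained only for comparison; its
item→subscale assignment and 0–100 value tables are configuration
(`data/subscales.json`) with the standard assignment as default.

Packaged banks are verified against SHA-256 digests at load and fail
closed on mismatch.

## Pooling diagnostics (DIF)

Deviations `d_{i,g} = b_i^(g) − b_i^(pooled)` are formed from free,
mean-item-centered calibrations of each dataset and of the pooled data.
Two statistics are reported:

* the one-way ANOVA of deviations grouped by dataset — the classical
  reported analysis. Because every calibration is mean-centered, each
  group's mean deviation is identically zero whenever all items are
  estimable everywhere, so this test is conservative by construction and
  is reported for comparability, not detection.
* a split-half item-by-dataset interaction F test: each dataset is split
  into two random halves (seeded), each half calibrated, and the
  dataset×item interaction mean square compared to the within-cell
  (between-half) mean square in the balanced two-way layout. A uniform
  shift of all items in one group is absorbed by that group's persons
  (the gauge freedom again), so item-level contrasts are the only
  identifiable DIF signal; this F targets exactly those, with a noise
  scale estimated from the data rather than from the (understated)
  nominal standard errors. In simulation at 250 persons per dataset its
  null size is at or below nominal and a one-logit shift on half the
  items is detected essentially always.

## Synthetic data

The generator draws person measures from a normal distribution and
responses from the cumulative model `P(X ≥ k) = σ(θ − b_i − τ_k)` — the
model the estimator assumes, by design: the recovery loop then tests the
estimator, not the generator. Defaults mirror the calibration cohort the
packaged banks describe: 3342 persons, the 30-item 25C roster with five
categories, person measures Normal(1.26, 1.99) logits, and the packaged
item measures and thresholds as generating values. Missing-at-random
masking, opt-out injection, driving-ineligible respondents and a
per-item threshold-jitter misspecification mode (off by default) are
available. A raw-format generator inverse-codes categories into native
option numbering so the recoder can be tested end to end; respondents
whose collapsed driving item lands in category 0 are represented as
having stopped driving for eyesight reasons, which also places their
other driving items in category 0 (the only native encoding of that
state).

What the generator does **not** emulate: multidimensionality (a single
latent trait generates all items), item-specific discrimination, misfit,
informative missingness, and covariate structure (age, acuity,
diagnosis). Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the model's own assumptions, not
robustness of the instrument on real clinical data.

## Problem sizes and numerical conventions in the test suite

Tests run at the cohort's structure but mostly reduced person counts
chosen as the package's own validation sizes: recovery at 500 and 3342
persons (item-measure correlation > 0.97, RMSE < 0.15 logit at 500;
anchored threshold recovery within 0.1 logit), a 50-seed ordered-
threshold battery at 500×30, and 100-replicate DIF size/power runs at
250 persons per dataset. Brute-force oracles (multi-resolution
coordinate grid search of the joint likelihood; dense score-equation
scans at 1e−4–1e−5 steps) validate the Newton machinery on all complete
3×3 designs with non-extreme margins and on small anchored-scoring
fixtures. All stochastic fixtures are seeded; calibration itself is
deterministic.

## Known limitations

* JMLE bias is not corrected by default; item spreads are inflated by a
  few percent at 30 items.
* Nominal standard errors understate realized sampling error of item
  measures (composite-information convention; see above).
* The threshold origin is conventional (gauge freedom); compare
  thresholds across calibrations only after a common centering.
* Per-item (partial-credit-style) thresholds, conditional/marginal
  estimators, Bayesian scoring and test equating are out of scope.
* The packaged banks apply to English-language administration of the
  NEI VFQ-25 in populations comparable to the calibration cohorts
  (primarily adult retinal disease and low vision); the calibrations may
  not generalize to, e.g., primarily peripheral field loss.
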