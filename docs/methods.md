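# Methods

This note documents the statistical procedures `endopredict` implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not show about real data.

## Outcomes and cohort handling

A cohort table carries one outcome at a single 6-month follow-up horizon:
baseline and follow-up scores on the VAS pain scale (0–10) or the QoL
barometer (0–100), plus typed predictors described by a sidecar codebook
(YAML). Improvement is defined inclusively: a relative VAS reduction
`(baseline − followup)/baseline ≥ 0.30`, or a QoL gain
`followup − baseline ≥ 10`. "A minimum of 30%" reads naturally as inclusive,
so a reduction of exactly 30% is improved; the same convention applies to the
10-point QoL rule.

A baseline VAS of exactly 0 makes the relative reduction undefined. Such
records are excluded from that outcome's analysis set with a logged count
rather than assigned a status; this is a package convention, since symptomatic
registries contain essentially no pain-free baselines.

Missing data follow the complete-case stance of the development workflow:
candidate predictors missing in **≥ 50%** of records are dropped before
modelling (boundary inclusive), and development then uses only rows complete
in the baseline score, follow-up score and the retained candidates. Both
filters log counts per reason. Multiple imputation is deliberately out of
scope. Eligibility (age 16–65, optional endometriosis flag) is an explicit,
logged filter that can be switched off.

## Fractional-polynomial logistic development

Continuous predictors may enter via a first-degree fractional polynomial
(FP1): `((x + a)/s)^p − c` with `p` from `{−2, −1, −0.5, 0, 0.5, 1, 2, 3}`
(0 = natural log). The shift `a` is the smallest round amount making values
strictly positive (+1 for 0-based scores), the scale `s` the power of ten
bringing them to order of magnitude 1 — e.g. `(baseline + 1)/10` for a 0–10
score — and the centering constant `c` is the development-sample mean of the
transformed values, so the intercept refers to an average patient.

Transform choice uses the closed test: (i) best FP1 power versus the null
model at α on 2 df — failure excludes the predictor; (ii) best FP1 versus the
linear term at α on 1 df — failure keeps linear. For mandatory covariates
(the baseline score), stage (i) is skipped, since a mandatory term cannot
leave the model. When the linear form wins, it is reported unscaled and
centered at the raw mean (an affine reparameterisation of the same model),
matching how linear age/BMI terms are conventionally printed.

Fitting is maximum-likelihood logistic regression via a Newton/IRLS solver
written for the many small refits this pipeline performs (backward
elimination and bootstrap replay run tens of thousands of fits). Standard
errors come from the inverse observed information; convergence is a relative
log-likelihood change below 1e-8 within 100 iterations with step-halving.
Exact collinearity raises an error naming the aliased columns; complete
separation is detected (diverging coefficients with fitted probabilities at
the class labels) and raised, never returned silently. The solver agrees with
statsmodels GLM to ~1e-9 on test fixtures, and the suite keeps statsmodels as
an independent oracle.

Backward elimination works on whole term blocks (a 3-level categorical's two
dummies leave or stay together) using likelihood-ratio tests: at each step the
non-mandatory block with the largest p ≥ α is removed and the model refitted,
until all remaining non-mandatory blocks have p < α. The default
**α = 0.157** corresponds to the AIC-as-selection interpretation of a 1-df
deviance change of 2. Transform selection runs once, before elimination, and
transforms are frozen during it; a `cycle` flag repeats
selection-then-elimination to stability for users who want mfp-style cycling.

## Internal validation, optimism and shrinkage

Bootstrap internal validation (default **B = 200**) replays the *entire*
development procedure — FP selection and backward elimination — inside each
resample (`replay_selection=True`), because the object under validation is
the selection procedure, not one fixed covariate set; a fast mode refits only
the final terms for comparison. Each resample's model is scored on the
resample (apparent) and on the original data (test); optimism is the mean
apparent-minus-test gap, and adjusted performance is apparent performance of
the original model minus optimism, for the C-statistic, calibration slope
(apparent value 1 on a model's own development data by construction) and CITL
(apparent 0). Resamples that draw a single outcome class are redrawn so B
stays fixed (logged); resamples whose fit separates or fails to converge are
skipped and the effective B reported.

The optimism-adjusted calibration slope is used directly as the uniform
shrinkage factor S — no heuristic alternatives. Shrinkage multiplies all
slope coefficients by S and re-estimates the intercept by maximum likelihood
with the shrunken linear predictor as a fixed offset, which restores equality
of the mean predicted probability and the observed event fraction.

## Performance metrics

* **C-statistic** via the Mann–Whitney rank formulation with midranks for
  ties (O(n log n)); identical to all-pairs concordance and invariant under
  strictly increasing transforms of the predictions.
* **Calibration slope**: logistic refit of the outcome on the linear
  predictor, intercept free.
* **CITL**: intercept-only logistic fit with the linear predictor as an
  offset (slope fixed at 1). These are the standard two separate fits.
* **Calibration curves**: ten equal-size groups by ranked prediction (stable
  sort for ties); a constant-prediction input collapses the grouping and is
  flagged degenerate. An optional smoother takes a windowed local mean on the
  logit scale (window 0.3 of the observed range) purely for plotting; the
  published plots' exact smoother is unstated, so no numerical claims rest
  on it.

## Decision curves

Net benefit at threshold `p_t` classifies "treat" when prediction ≥ `p_t`
(inclusive; ties against the grid are a documented convention) and equals
`TP/n − (FP/n)·p_t/(1−p_t)`. Treat-all follows the closed form
`φ − (1−φ)·p_t/(1−p_t)` with prevalence φ; treat-none is identically zero.
The default grid is 0 to 0.80 in steps of 0.01, inclusive, with no smoothing
of the raw values.

## Minimum sample size

Three criteria for a binary-outcome model with `p` candidate parameters,
anticipated Cox–Snell `R²_CS` and prevalence φ:

1. shrinkage ≥ S_target (default 0.9): `n ≥ p / ((S−1)·ln(1 − R²_CS/S))`;
2. apparent-vs-adjusted R² difference ≤ δ (default 0.05) of the maximum
   achievable `R²_CS(φ) = 1 − (φ^φ(1−φ)^(1−φ))²`, via the shrinkage it
   implies, `S₂ = R²_CS/(R²_CS + δ·max R²_CS)`, plugged into the same formula;
3. overall-risk precision: `n ≥ (1.96/margin)²·φ(1−φ)` (default margin 0.05).

Each is rounded up before taking the maximum. Note the shrinkage criterion
*decreases* in `R²_CS`: a stronger anticipated signal needs less data to
reach the same shrinkage target. For the published inputs (p = 12,
R²_CS = 0.11, S = 0.9) criterion 1 gives n = 921 and is binding.

## Shipped model cards

Eight published models are stored as JSON cards: terms with their transforms
and dummy encodings, coefficients (natural logs of the printed odds ratios,
which limits them to the printed 2-decimal precision), intercepts with SEs,
development counts, and the optimism-adjusted performance block. Event
percentages are always recomputed from the stored counts, never stored. Two
caveats are recorded in each card's notes rather than silently resolved:

* printed categorical contrast labels name the reference level first
  ("not trying to conceive vs trying < 18 months"); the odds ratio is read as
  belonging to the second-named level, the direction consistent with the
  source abstract;
* odds ratios for transformed continuous terms (e.g. 0.01 for an `(age/10)^−2`
  term) are per unit of the *transformed* variable, not per year/point.

## The synthetic-cohort generator

Real registry data are not publicly deposited, so cohorts are generated:
covariates are drawn independently (age ~ truncated normal(34.5, 7) on
[16, 65] years; BMI ~ truncated normal(26, 5) on [15, 50] kg/m²; baseline VAS
~ Beta(5, 2) scaled to [0, 10] and recorded as integers, skewed high because
development cohorts are symptomatic; baseline QoL ~ truncated normal(50, 18)
on [0, 90], bounded so a 10-point gain is always realisable; binary
treated-location flags with prevalences 0.10–0.45; three-level conceiving and
smoking variables with fixed probabilities). Age and BMI means follow the
development-sample means the published centering constants reveal; spreads
and prevalences are unpublished and are package defaults, all overridable.

Improvement status is drawn Bernoulli from the truth card's linear predictor,
optionally perturbed as `shift + factor·lp` to construct miscalibrated
external cohorts (at large n, validation recovers CITL ≈ shift and slope ≈
factor). Follow-up scores are back-constructed to be consistent with the
drawn status and then nudged by machine ulps so that re-applying the
dichotomization rule reproduces the drawn status *exactly* — naive clipping
to the 30%-reduction boundary loses the status for many baselines through
floating-point rounding, which measurably biases downstream refits.
Missingness is MCAR per predictor (the complete-case stance makes richer
mechanisms irrelevant here). All draws flow from one seeded generator, so an
identical spec yields a byte-identical cohort.

What passing tests show, and what they do not: the generator is structurally
faithful (variable types, score supports, outcome law, missingness) but not
distributionally faithful — real covariate spreads, correlations between
predictors, informative missingness and centre/surgeon clustering are absent.
Self-consistency results (slope ≈ 1, CITL ≈ 0 at n = 50,000; coefficient
recovery within 3 SE) validate the *pipeline's correctness*, not the
published models' real-data performance, which requires the original
registries.

## Problem sizes and numerical conventions

Test and acceptance runs use n = 50,000 for self-consistency checks,
n = 20,000 × 20 seeds for coefficient recovery, n = 5,000 × 20 seeds for
selection behaviour, and B = 200 bootstrap at n = 2,000 plus an overfit
regime of n = 200 with 20 noise candidates — sizes at which the Monte-Carlo
error is small relative to the tolerances asserted. Tie-breaks: equal
deviance among FP powers prefers the power closest to linear; equal p-values
in elimination drop the later term. Degenerate inputs (single-class outcomes,
constant linear predictors, empty tables, thresholds at 1) raise typed errors
rather than returning conventional values.

## Known limitations

* FP2 (two-term fractional polynomials), interactions and penalised
  estimation are out of scope, as is multiple imputation.
* Bootstrap confidence intervals for performance statistics are not provided,
  only optimism adjustment.
* The generator draws covariates independently; selection behaviour under
  strong predictor correlation is untested.
* The published minimum-sample-size figure (824–840) is not reproducible from
  the stated inputs with the standard formulas (which give 921); the
  implementation documents its formulas and treats the published figure as
  contextual.
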