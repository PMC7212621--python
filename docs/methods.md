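# Methods

This note documents the models behind `diarycal`, the choices made where
the design was genuinely open, and what the synthetic cohorts do and do
not establish about real diary data.

## Problem setting

Participants in an internet intervention for alcohol use disorder may
log standard drinks per day in an optional diary. At baseline and at a
follow-up roughly ten weeks later they complete a last-week timeline
followback (TLFB), giving a gold-standard total of drinks over the seven
days preceding each assessment. Diary use is sparse (most days have no
entry) and the missingness mechanism is unknown and plausibly related to
drinking itself. The pipeline asks whether adjusted diary data recover
group-level consumption at follow-up, and whether early diary data
predict individual treatment success.

## Preprocessing conventions

Day 0 is the baseline date; the intervention window is half-open,
`[baseline, followup)`. Week *w* (1-based) covers days `7(w−1)..7w−1`;
`total_weeks = ceil(duration/7)`, so a final partial week keeps a full
week index while `days_present` reflects only observed entry days.
Normalized treatment time is `week / total_weeks`, which aligns
participants with different real durations. Duplicate entries on one
(participant, day) keep the maximum reported drinks. Fully missing weeks
are not materialized; within-week missingness is carried by
`7 − days_present`. Sample SD (n−1) is used throughout.

## Missing-entry adjustment

The calibration set contains every participant with at least one diary
entry dated in `[followup−7, followup−1]` (one row per participant; the
window excludes the follow-up day itself). OLS of the TLFB total on
(calendar drinks in window, days missing from the window) with an
intercept gives the two scaling coefficients; the intercept is estimated
for diagnostics but never applied, and weekly scaled values are floored
at zero. Stability is assessed with a case (row) bootstrap — the
assumption-light choice — with rank-deficient resamples redrawn. The
homogeneity assumption (one coefficient pair for the whole treatment
period) is exactly what the downstream CI-overlap check tests.

Known property: because the intercept is excluded from scaling, its
*sampling noise* propagates into every adjusted value. With an overlap
subset of ~100 participants this contributes an end-point uncertainty of
roughly ±1 drink/week that the GEE's plug-in standard errors do not
see. The test suite documents the consequence (see "Validation check"
below).

## Trajectory model

Weekly drinks (raw or adjusted) are modeled with a gaussian-family GEE,
participants as clusters, exchangeable working correlation, robust
sandwich covariance. Time enters as *reversed* normalized time
t′ = 1 − week/total_weeks, a pure re-parameterization of the forward
coding (verified numerically to 1e-8) whose intercept is the end-point
estimate B at normalized time 1 with a directly available robust SE.
The reversal was chosen over 1/t because 1/t is undefined at t = 0 and
incompatible with a linear time effect. 95% CIs are B ± 1.96·SE. The
follow-up TLFB mean gets a normal-approximation CI. Good estimation =
the two intervals overlap; otherwise the sign of the point difference
classifies over- vs under-estimation.

## Features and outcomes

Eighteen predictors per participant are computed from entries in the
first half of treatment (normalized day position < 0.5, strict), after
excluding participants whose follow-up came more than 35 days after the
intended 70: sixteen order/summary statistics of entry-level drinks
(first/last ordered by date; the first-to-last difference is signed;
quantiles use linear interpolation so results are bit-reproducible) and
the per-participant random intercept and slope of a Poisson mixed model
`log E[drinks] = (b0+u0) + (b1+u1)·t` with correlated random effects.
Entry categories: women — light ≤ 3, heavy 4–6, binge ≥ 7 drinks; men —
light ≤ 4, heavy 5–8, binge ≥ 9. Non-integer amounts in the category
gaps resolve with precedence binge > heavy > light (logged). The
relative first-last difference is `(last − first)/first`, 0 when the
first entry is 0 — one isolated function, since several algebraically
inequivalent definitions exist in the wild.

The Poisson mixed model is fitted by Laplace-approximate EM:
per-participant Newton iterations find the conditional modes (u0, u1),
the 2×2 random-effect covariance updates by the moment rule
`D ← mean(û û' + H⁻¹)`, and fixed effects update by IRLS with the modes
as offsets. Conditional modes are shrinkage estimates: a participant
with one entry gets a finite, heavily shrunk slope. On non-convergence
the last iterate is returned flagged, which is equivalent to
ridge-penalized per-participant fits at the final covariance.

Outcomes: `non_hazardous` = follow-up TLFB ≤ 14 (men) / ≤ 9 (women);
`audit_improved` = follow-up AUDIT in a strictly lower risk zone than
baseline, zones 0–7 / 8–15 / 16–19 / 20–40 (standard AUDIT bands; the
instrument defines no canonical partition).

## Prediction

Random forests with the positive class "improved". Repeated CV (10-fold,
3 repeats by default) grid-searches mtry over 1–17 by out-of-fold ROC;
sensitivity/specificity at the 0.5 cutoff and fixed-width decile
calibration curves come from pooled out-of-fold predictions, importances
from the final full-data refit, scaled so the top variable is 100.
Nested CV (10 outer, 10 inner) keeps outer folds untouched while inner
folds select mtry; scaling/centering is fitted inside each training fold
only — a deliberate tightening of the full-data scaling a literal
reproduction would use, to keep the generalization estimates leak-free.
Folds are stratified.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, with a
fully observed latent truth retained for oracle tests.

*Latent drinking*: each participant has a baseline weekly rate
(gamma, mean 28.1, SD 18.66 drinks/week), drops at enrollment toward a
common week-one level of 16 drinks/week (lognormal heterogeneity, SD
0.10 on the log scale; an optional coupling exponent lets the drop stay
proportional to baseline instead), then declines linearly by 1.5
drinks/week over the normalized duration. Daily counts are negative
binomial (size 1.5) around the weekly rate / 7. Intended duration 70
days plus a uniform 0–39-day follow-up delay, which reproduces a ~10%
">35 extra days" exclusion rate. TLFB totals are exact latent sums over
the seven days before each assessment — the follow-up TLFB is a gold
standard by construction. AUDIT scores are ordinal-plausible only:
baseline truncated-normal respecting the ≥6 (women) / ≥8 (men) inclusion
floors, follow-up = baseline − a change score correlated with true
drinking reduction.

*Diary sampling*: weekly sessions. A week-level logistic presence
process (per-participant propensity SD 1.2; participant-specific decay
slope ~ N(−7, 9.5) clipped at 0 per unit normalized time; a first-week
boost of +3.2 logits capturing the novelty effect) decides whether the
diary is used that week; within a session week each day is logged
independently (logit −0.5 + 0.05·drinks under MNAR_amount, plus a
day-level share of the propensity). The menu also offers MCAR (constant
probabilities), MNAR_time (decay only) and `full` (probability 1 — the
oracle mechanism under which the diary equals the latent truth). A
session structure is required: the cohort the defaults target logs ~3.8
days in each diary week but only ~3.9 diary weeks out of ~10–16, which
no iid per-day mechanism can produce.

Calibration of the defaults (607 participants): ~90% of participants
make ≥1 entry; 3.7–4.0 diary-weeks (target 3.91) and 13–16 entries
(target 15.0) per active participant, range 1–16 weeks; ~20% of users
have entries in the follow-up TLFB window; follow-up TLFB mean ~14.4
drinks.

*Planted outcomes* (`plant_outcome_signal`) grade prediction tests: the
score is the standardized negative first-half latent daily mean
(participants reaching low consumption early are "improvers"),
labels are Bernoulli(sigmoid(effect·score)); effect 0 gives coin-flip
labels, effect ∞ the deterministic below-median rule, which first-half
summaries recover exactly under full observation.

What passing tests show — and don't: the generator provides exact
conservation (diary ⊂ latent), known calibration-regression truth under
MCAR, and tunable outcome signals, so correctness of every pipeline
stage is verifiable. It does not model real diary idiosyncrasies
(situational covariates, reporting error in TLFB or diary amounts,
informative enrollment dates), so passing tests demonstrate procedure
correctness, not real-world validity of the adjustment.

## Validation check under the default mechanism

Under MNAR_amount defaults the raw end-point always lands far below the
TLFB interval (underestimation, 100% of cohorts), and the adjusted
end-point is unbiased to about +0.3 drinks/week. The *interval-overlap*
verdict for the adjusted fit, however, succeeds in only ~55–75% of
cohort replicates (configuration-dependent): the tolerance implied by
the two plug-in CIs (≈1.1 drinks/week) is smaller than the sampling
noise the calibration regression injects through the excluded intercept
(SD ≈ 1.0–1.4 at ~100 overlap rows). Substituting the generating
coefficients for the fitted ones raises the success rate to ~99%,
isolating the cause in the plug-in procedure rather than the pipeline.
The acceptance suite states the check at its nominal 80% level and the
test is expected to fail at study scale; the per-seed artifacts let a
user inspect every component of the verdict.

## Numerical choices

Logistic inputs are clipped at ±500 (probabilities) and linear
predictors at ±30 (Poisson means). GEE fits with a constant response
short-circuit to a degenerate zero-slope fit with epsilon SEs. Bootstrap
resamples with a constant predictor are redrawn with a retry cap.
Negative adjusted weekly values are floored at zero and logged. The
pipeline derives per-stage seeds by hashing stage names into the master
seed, so stages are reproducible independently; rerunning any stage with
the same configuration is byte-identical.

## Evaluation sizes

Simulation-based tests use reduced problem sizes chosen to keep the
whole suite fast while leaving Monte-Carlo error well inside the asserted
margins: coverage checks use 40–100 replicates, the end-to-end verdict
check 50 cohorts, prediction checks forests of 60–100 trees with coarse
mtry grids, and the acceptance script uses 120-tree forests with a
9-point mtry grid, 2 repeated-CV repeats and 5 inner folds. The
full-size settings (500 trees, grid 1–17, 10×10 nested CV, 5000
bootstrap resamples) are the library defaults.

## Known limitations

- AUDIT follow-up scores are simulated only to ordinal plausibility;
  AUDIT-derived prevalences are not calibrated targets.
- The adjustment's homogeneity assumption is tested only via the
  end-point check, mirroring the analysis design it implements.
- Sensitivity/specificity patterns depend on outcome prevalence, which
  the generator does not pin down (~40% improvers for both outcomes).
- Between-participant spread at follow-up is narrower than real cohorts
  show; see the validation-check section for the consequence.
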