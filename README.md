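# diarycal

Validation and predictive modeling of **non-mandatory alcohol
consumption diary data** from internet interventions for alcohol use
disorder (AUD), together with a synthetic cohort generator for method
evaluation.

Internet interventions for AUD often include an optional drinking diary
("calendar"). Because use is voluntary, the data are mostly missing and
the missingness mechanism is unknown — yet the diary is the only
continuous record of drinking during treatment. This package implements
a complete pipeline for asking, on such data:

1. **Validation** — does diary data, after adjusting for missing
   entries, approximate the gold-standard last-week timeline followback
   (TLFB) total reported at follow-up?
2. **Prediction** — do summary features of first-half-of-treatment diary
   data predict treatment success at follow-up?

It is aimed at biostatisticians and intervention researchers who want to
evaluate these procedures without access to participant-level data: a
configurable generator produces cohorts with realistic diary structure
and a fully observed latent truth, so every step can be verified against
an exact oracle.

## The methods

**Missing-entry adjustment.** For participants whose diary use overlaps
the 7-day TLFB recall window at follow-up, both the diary-reported
drinks and the TLFB total are observed. An OLS calibration regression

    TLFB_total ~ β_d · calendar_drinks + β_m · days_missing + α

yields β_d (predicted drinks per reported drink) and β_m (drinks per
missing day per week); the intercept α is estimated but never applied.
Every participant-week (with `days_present` of 1–7 entry days) is then
scaled to `adjusted = β_d·raw + β_m·(7 − days_present)`. Coefficient
stability is assessed by case bootstrap (5000 resamples by default).

**Trajectory end-point.** A gaussian-family GEE with exchangeable
working correlation and robust (sandwich) errors is fitted to weekly
drinks on reversed normalized time t′ = 1 − week/total_weeks, so the
model intercept is the predicted drinks/week at the end of treatment, B
(SE). *Good estimation* means the 95% CI of B overlaps the 95% CI of the
TLFB-derived follow-up mean; disjoint intervals are classified as over-
or under-estimation.

**Outcome prediction.** Eighteen per-participant features are built from
first-half diary entries (summary statistics, drinking-category counts
and percentages, and the random intercept/slope of a Poisson mixed model
of drinks on time). Random forests (500 trees, mtry grid 1–17) are
evaluated by repeated cross-validation (model selection by ROC,
sensitivity/specificity, calibration, scaled importances) and by nested
cross-validation (10 outer × 10 inner folds) for honest accuracy and
ROC, for two binary outcomes: non-hazardous drinking at follow-up
(≤ 14 drinks for men, ≤ 9 for women) and a drop in AUDIT risk zone.

## Worked example

```python
from diarycal import (GeneratorConfig, generate_cohort, deduplicate,
                      window_entries, collapse_weeks, find_overlap_subset,
                      fit_adjustment, apply_adjustment, validate)

cfg = GeneratorConfig(seed=3)                      # 607 participants, MNAR_amount
participants, diary, latent = generate_cohort(cfg)
entries = window_entries(deduplicate(diary), participants)
weeks = collapse_weeks(entries, participants)
model = fit_adjustment(find_overlap_subset(entries, participants))
report = validate(apply_adjustment(weeks, model), participants, model)
print(f"betas: {model.beta_missing:.2f} per missing day, "
      f"{model.beta_drinks:.3f} per reported drink")
print(report.to_text())
```

```
betas: 2.12 per missing day, 0.999 per reported drink
Trajectory validation
=====================
     raw: end-point B = 7.07 (SE = 0.35, 95% CI 6.40..7.75), time effect = -1.61 drinks over duration (SE = 0.45) -> underestimation
adjusted: end-point B = 15.08 (SE = 0.23, 95% CI 14.64..15.53), time effect = -0.73 drinks over duration (SE = 0.33) -> good_estimation
follow-up TLFB mean = 14.60 (95% CI 14.12..15.07)
```

Raw diary weeks under-count true weekly consumption (end-point ~7
drinks/week against a follow-up TLFB mean of ~14.6), because unlogged days
still contain drinking. After the empirically derived adjustment the
end-point interval overlaps the TLFB interval: adjusted diary data
recover group-level consumption.

The same pipeline is available from the shell:

```bash
diarycal run-all --seed 3 --outdir out/        # all stages, all artifacts
diarycal validate --seed 3 --outdir out/       # stop after the CI-overlap check
```

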