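# Methods

## Scope and model

`spectrisk` treats three-year MACE as a binary outcome and a risk model as a
logistic linear predictor over named covariates with optional per-covariate
transforms. The packaged default model uses diabetes (0/1), age (years, as
supplied — no rounding), the summed stress score mapped to its severity
category (0–3 → 0, 4–8 → 1, 9–13 → 2, ≥ 14 → 3; the coefficient multiplies
the *category index*, not the raw score), and LVEF (%). Probabilities are
carried internally on the fraction scale everywhere; percent is applied only
at presentation. Time-to-event structure, competing risks and penalized
estimation are out of scope: the outcome is a fixed-horizon binary label.

## Validation statistics and their conventions

Several printed values depend on conventions the literature leaves open;
the choices here are fixed and surfaced in the outputs:

- **C-statistic** — midrank (Mann–Whitney) form; tied predictions earn half
  credit. Identical to the explicit all-pairs count.
- **Residual deviance** — −2 × binomial log-likelihood; df = n minus the
  number of parameters estimated *on this cohort* (0 external, 1
  in-the-large, 2 slope, 1 + #covariates refit). An externally fixed model
  therefore has df = n.
- **Risk binning** — deciles of predicted probability on sorted order,
  left-closed/right-open, tied values kept together in the *lower* bin, so
  bin sizes may be unequal and ties can collapse bins (collapses are
  warned, never silent).
- **Hosmer–Lemeshow** — Σ (O−E)²/(E(1−E/n_bin)) over the bins, df =
  bins − 2. The df convention for externally fixed models is debatable; the
  df used is always reported alongside the statistic so alternates can be
  compared.
- **Decile calibration** — OLS of observed on mean predicted probability
  across the 10 bin points; R² and the regression F-test p quantify
  linearity.
- **Loess calibration** — degree-1 locally weighted regression of the
  outcome on predicted probability, tricube kernel, no robustness
  iterations, default span 0.75 (a configuration knob; the span used is
  recorded in the curve object). The smoother interpolates within
  `delta = 0.01 × range(p)` for speed, the same shortcut R's `lowess`
  uses; the curve is clipped to [0, 1]. d_max and d_mean are the max and
  mean |predicted − smoothed| over patients.
- **Bootstrap** — patient-level percentile bootstrap, default 1000
  resamples, seeded and bit-reproducible. C, Brier, d_max and d_mean are
  evaluated jointly on each resample. A resample on which a statistic is
  undefined (e.g. no events) is redrawn, at most 100 times, and redraws are
  an exception, never a silent skip.
- **Group comparison** — Student t (pooled variance) for continuous
  variables, 2×2 χ² without continuity correction for indicators.

## Recalibration and update

All three corrections run through one binomial-GLM maximizer (IRLS,
deviance tolerance 1e−12, max 100 iterations) with an offset facility:
in-the-large is an intercept-only fit with the original logit as offset,
the slope model regresses the outcome on the original logit, and the refit
re-estimates everything. Using a single maximizer guarantees the deviance
nesting external ≥ in-the-large ≥ slope ≥ refit numerically. After every
fit the score vector X′(y−μ) is checked against a scale-aware tolerance
(1e−6 × max(1, max|X|)); non-convergence, rank deficiency and separation
raise errors. A practical consequence of the intercept's score equation —
mean recalibrated probability = observed event rate — holds to 1e−8 and is
asserted in the test suite.

Inference is Wald throughout, matching the estimate/SE presentation of
updated-model coefficient tables: p-values from z = estimate/SE, odds
ratios e^estimate with CI e^(estimate ± 1.96·SE). No profile likelihood.
The 95% quantile is fixed at 1.96. When an external model's own standard
errors are unavailable (the usual case for published models), comparisons
between refit and external coefficients should use the refit's SEs only.

Temporal subgrouping is plain cohort filtering on the `year` column plus
two ladder runs; no bespoke machinery. Extended updates (extra risk-factor
covariates) append columns to the same design matrix.

## The synthetic cohort generator

The generator claims **marginal** fidelity only. It emulates a contemporary
European stress-SPECT referral population: age ~ N(63.3, 11²) truncated at
the 20-year inclusion bound; diabetes prevalence 33.6%; SSS severity mix
60/19/9/12% across categories 0–III with the raw score uniform on each
category's integer range (top category capped at 40); LVEF drawn
conditionally on SSS category with means 58/54/50/45% (SD 12, truncated to
5–90%), reflecting the lower ejection fractions seen with larger perfusion
defects. Other covariate correlations (e.g. age–diabetes) default to
independence. Outcomes are Bernoulli draws from
`expit(shift + scale · logit_model)`, so a known calibration-in-the-large
offset and slope distortion can be injected.

`expected_event_rate` computes the analytic mean outcome probability by
enumerating diabetes and every raw SSS value exactly and integrating age
and LVEF by 48-node Gauss–Legendre quadrature against their truncated
normal densities. The packaged scenarios solve (Brent's method on the
shift) for target event rates of 8.2% (full cohort), 5.5% / 10.8% (earlier
and later temporal halves, the later period carrying a 70% vs 51% abnormal
scan fraction) and 4.3% (a lower-risk derivation-like population). Tuning
touches only the baseline shift, never the covariate structure.

What passing tests on these cohorts demonstrate: the statistics, fits and
their inferential guarantees (recovery, coverage, nesting, score equations)
are implemented correctly. What they do not demonstrate: performance of any
particular published model on real patients — synthetic outcomes are
generated *from* a logistic model on these covariates, so discrimination is
higher and residual miscalibration lower than real cohorts exhibit, and no
claim about unmodelled heterogeneity, measurement error or case-mix drift
is supported.

## Numerical choices and degenerate inputs

- Cohort validation is strict: missing values, ages below 20, out-of-range
  LVEF, non-binary indicators and negative scores are rejected at load with
  the offending row named; there is no imputation.
- Predicted probabilities must lie strictly in (0, 1); a boundary
  probability with a discordant outcome would make the deviance infinite
  and is rejected at construction.
- LRT statistics that come out within 1e−8 below zero (float noise on
  identical fits) are clamped to 0; anything more negative is a nesting
  violation and raises.
- Reports serialize with sorted keys and fixed float formats; cohort CSVs
  round age and LVEF to 2 decimals at generation. Fixed seed ⇒ byte-identical
  files. Every output embeds package version, seed and a config hash.

## Problem sizes

The test suite exercises recovery at the sizes the guarantees are stated
for: single-fit recovery at n = 50 000, repeated-fit recovery (50
replicates) at n = 20 000, Wald coverage (200 replicates) at n = 5000,
deviance nesting across 50 random n = 400 cohorts, and oracle equivalence
on instances up to n = 200. The acceptance script runs the full ladder at
the reference cohort size n = 3623 with 1000 bootstrap resamples.

## Known limitations

- The loess span default (0.75) is a convention, not an estimate; d_max is
  sensitive to it at the sparse tails of the risk distribution.
- The Hosmer–Lemeshow df convention (bins − 2) is applied to all rungs,
  including the externally fixed model.
- Synthetic cohorts cannot validate joint-distribution claims (see above).
- Separation is an error, not a Firth fallback; cohorts small or
  imbalanced enough to separate need different tooling.
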