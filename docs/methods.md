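# Methods

This note documents the models, the synthetic data-generating process, the
numerical conventions, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The emulated design

The unit of analysis is the **person-trial**: one participant's entry into
one of K = 5 emulated trials run at the quarterly assessment waves December
2020, March, June, September and December 2021 (a sixth wave, March 2022,
serves only as an outcome assessment). Entry rules:

* A participant is eligible for a trial if they completed that wave's
  assessment and reported vaccination status. Status-missing waves are
  skipped without barring later entry; re-entry after a missed wave is
  allowed.
* Unvaccinated participants contribute one unvaccinated person-trial per
  eligible wave until vaccinated; time zero is the assessment month.
* A participant first reporting vaccination at a trial wave contributes
  exactly one vaccinated person-trial there, with time zero the month of
  the first dose, and never re-enters. A participant already vaccinated at
  their first eligible wave is a vaccinated entry at trial 1, provided the
  dose month is not before their first assessment (otherwise no covariate
  history exists at time zero and the build fails with a data error).
  A vaccinated report without a dose date cannot be assigned a time zero
  or era and is skipped with a logged warning; earlier unvaccinated
  entries are kept.
* Exposure is ≥ 1 dose (ITT analog); per-protocol, dose-response and
  censoring-weighted estimators are out of scope.

**Era.** First doses on or after 2021-04-19 are *universal*-era, earlier
ones *preuniversal*. Era assignment uses the exact reported dose date when
available; month-only values resolve to the month's mid-point (day 15).
Unvaccinated person-trials take the era of their time-zero month, resolved
the same way. All other date logic is at calendar-month resolution, with
months encoded as the first of the month.

**Outcome.** The GAD-7 (anxiety, 0–21) or PHQ-8 (depression, 0–24) total
at the first completed assessment 2–5 months after time zero, earliest
match first; the dichotomous outcome is total ≥ 10 (moderate-to-severe).
The 2..5 window with earliest-match tie-break operationalizes "generally
~3 months of follow-up" while tolerating off-quarter dose months. Missing
items are never prorated: a partially answered instrument has a missing
total, handled by imputation at the score level.

**Covariate snapshot.** Baseline covariates are taken from the enrollment
(first) assessment; time-updated covariates (employment, food insecurity,
housing instability) and symptom severity come from the most recent
measure at or before time zero, falling back across waves when a wave's
value is missing.

## Estimators

* **Pooled logistic regression** per era stratum, fitted by IRLS
  (statsmodels GLM, tolerance 1e-8, at most 100 iterations).
  Non-convergence and quasi-separation (any |coefficient| > 30) raise
  errors naming the offending column. Stratified fits are used rather than
  an era×treatment interaction model; both parameterizations feed the same
  Wald test and the stratified form matches how results are reported.
* **Cluster-robust variance**: CR0 sandwich `A⁻¹BA⁻¹` with `A` the Fisher
  information and `B` the outer product of within-participant score sums;
  no small-sample factor by default, CR1 (`G/(G−1)`) by flag. With
  singleton clusters CR0 equals HC0. The implementation is independent of
  statsmodels' cluster covariance, which serves as a cross-check in the
  test suite, alongside a nonparametric cluster bootstrap.
* **Multiple imputation**: Bayesian linear regression of the outcome total
  on complete covariates; per imputation, the residual variance is drawn
  from its scaled inverse-χ² posterior, coefficients from their normal
  sampling distribution, and missing cells from the posterior predictive,
  rounded and clipped to the instrument range. Predictive-mean matching
  (5 donors) is available as an alternative. m = 20 by default — ample
  for ~7% missingness — with per-imputation seeds `seed + index`.
  Imputation models are separate per outcome (the anxiety model includes
  enrollment anxiety; depression, enrollment depression). The default
  predictor list mirrors the published models (demographics, socioeconomic
  covariates, enrollment severity); `run_full_analysis` additionally
  appends treatment and era so the imputation model nests the analysis
  model — omitting them makes the imputation uncongenial and attenuates
  the recovered effect. Covariates are never imputed: the analytic set is
  restricted to confounder-complete person-trials, mirroring the
  complete-confounder restriction of the emulated analysis.
* **Rubin pooling**: pooled point = mean, `T = W + (1 + 1/m)B`, 95%
  intervals from a t distribution with Barnard–Rubin degrees of freedom.
  When every per-imputation estimate coincides (e.g. nothing was missing)
  the pooled point is taken as the first value and B set to exactly 0, so
  a no-missing-data run is bitwise identical to the complete-data
  analysis; `np.mean` of m identical floats would not guarantee that.
* **Descriptives**: prevalence as a percentage with a Wald binomial 95%
  interval (the form that reproduces printed cohort tables); 2×2 odds
  ratios closed-form `ad/bc` with Woolf intervals and no continuity
  correction — zero cells raise. The printed odds ratios of the
  motivating analysis do not equal `ad/bc` on its printed counts, so the
  package exposes the closed-form and the model-based pooled OR as
  distinct quantities and never asserts their equality.
* **Subgroups**: person-trials with moderate-to-severe symptoms at time
  zero; the conditioning severity covariate is dropped from the adjustment
  set (constant within the subgroup). The continuous-score model is a
  REML linear mixed model with a participant random intercept; its
  treatment coefficient is in score points and its interval uses the
  model-based SE.
* **Heterogeneity**: Wald `W = (θ̂_pre − θ̂_uni)²/(v_pre + v_uni)` on
  robust variances, χ²₁ reference, two-sided p, no multiplicity
  adjustment.

## The synthetic cohort

The generator emulates the study conditions the pipeline assumes: ~4,800
eligible participants assessed quarterly December 2020 – March 2022.

* **Covariates.** Two generative confounders — binary susceptibility to
  severe COVID-19 (prevalence 0.21; outcome log-odds +0.8, uptake
  log-odds +0.5) and 3-level education (14/28/58%; outcome +0.3/+0.15/0,
  uptake −0.4/−0.2/0 vs. college graduates) — plus descriptive covariates
  (age band, gender, race/ethnicity, income, children, exposure risk,
  healthcare access; time-updated employment, food and housing insecurity
  evolving as a slow Markov chain) with marginals loosely modeled on a
  diverse U.S. online cohort. Descriptive covariates have no generative
  effect by default but populate the full adjustment set and imputation
  models; everything is overridable.
* **Uptake.** Per-wave first-dose log-odds (−2.1, −0.45, −2.0, −2.85,
  −3.15 at the five trial waves) plus covariate effects, calibrated a
  priori so that roughly 80% of vaccinated person-trials fall in the
  preuniversal era, matching the emulated cohort's structure. Vaccination
  is absorbing; the dose day defaults to the 15th.
* **Outcomes.** Severity is Bernoulli with
  `logit P = α + θ_era·treated + γ'x (+ u)`; α is calibrated by
  root-finding so the marginal untreated prevalence equals
  `baseline_prevalence` (default 0.25) over the exact confounder
  distribution (Gauss–Hermite quadrature over the optional person-level
  effect `u`, default off). Integer totals are then drawn uniformly
  within the severe (≥ 10) or non-severe class — the estimand lives on
  the dichotomized scale, so the continuous distribution only needs to
  respect the threshold and range. Default true effects are OR 0.79
  (preuniversal) and 1.23 (universal).
* **Crossover timing.** By default doses occur in assessment months and
  the symptom effect manifests from the *following* assessment onward.
  In a sequential-trial design an unvaccinated person-trial's outcome
  assessment can postdate a later first dose; if that outcome already
  carried the treatment effect, the control arm would be contaminated and
  the ITT-analog estimand would no longer equal the generating
  conditional log-odds ratio. With the default timing the two coincide,
  which is what makes exact parameter-recovery testing possible. The
  trial builder itself handles arbitrary dose dates.
* **Missingness.** Outcome totals (never covariates) are blanked at an
  overall rate of 7% by default, MCAR or MAR-on-covariates (default MAR
  on food insecurity, log-odds +0.8), with the intercept calibrated to
  the target rate; each instrument's score is blanked independently. The
  motivating analysis does not characterize its missingness mechanism, so
  both generators are provided rather than asserting either.
* **Reproducibility.** A fixed config (including seed) yields a
  byte-identical cohort; the full analysis report is bitwise reproducible
  under a fixed seed.

### What the generator does not emulate

Recruitment channels and survey weighting; construction of the composite
exposure/susceptibility/access scores from raw survey items (composites
enter as given binary covariates); attrition (per-wave retention is
configurable but defaults to 1); secular trends in symptom prevalence
(the baseline is calendar-constant, so era strata share one untreated
baseline); item-level instrument data (totals are generated directly);
and state-specific vaccine rollout. Passing tests therefore demonstrate
the estimators' correctness under the stated generative assumptions, not
robustness to violations such as informative dropout or
treatment-confounder feedback.

## Problem sizes in the verification suite

The simulation studies use sizes chosen to make Monte-Carlo error small at
desk scale: parameter recovery uses 200 cohorts of n = 2,000 with m = 10
imputations and one binary confounder (mean pooled log-OR within 3
Monte-Carlo SEs of truth per era; CI coverage within [92%, 98%]); Wald
calibration uses 500 cohorts of n = 600 under era-homogeneous effects;
the sandwich-vs-bootstrap check uses one 200-cluster cohort and 1,000
cluster resamples (agreement within 10% relative SE); builder-vs-oracle
equivalence uses 50 random toy cohorts of ≤ 20 participants against a
brute-force timeline enumerator. The acceptance script's synthetic run
uses 4,832 participants — the analytic cohort's scale — with m = 20.

## Known limitations

* The published adjusted odds ratios cannot be reproduced without the
  underlying individual-level cohort; only count-derived descriptives are
  checked exactly, and the synthetic run recovers the *generating*
  effects, which are set to the published point estimates by default.
* CR0 is mildly anticonservative with few clusters; use CR1 (or judge by
  the bootstrap) when the number of participants is small.
* The mixed model's interval uses the model-based SE; no sandwich is
  applied on the LMM scale.
* Imputation assumes MAR given the model covariates; MNAR outcomes would
  bias all estimators equally.
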