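# Methods

`bpevent` implements a two-step semiparametric event study for evaluating
referral programs — here, a remote blood-pressure monitoring (RPM) service —
from longitudinal EHR records, together with a calibrated synthetic-panel
generator used to validate every stage against known ground truth.

## The design

Patients are referred to the program at different calendar months; the
referral is the "event", and all time is measured in integer calendar months
relative to it (event time). There is no never-treated control group: the
counterfactual is each group's own pre-referral outcome process, extrapolated
forward.

**Cohort.** Raw readings are aligned to event time, averaged to one value per
patient per event month (the unweighted mean of that month's readings, with
the reading count kept as an optional weight), and filtered: the pre-referral
analysis window is event months −12 to −1, the post window +7 to +12
(skipping the first six months so the estimate reflects the program's settled
effect rather than onboarding transients), and a patient is retained only
with at least one patient-month in each window. Months 0 to +6 are kept in
the panel, flagged out-of-analysis, so the ramp-in can be displayed.

**Step 1 — residualization.** Within each condition group, observed SBP on
the baseline window (event months −12 to −2; month −1 is excluded as
potentially transitory) is regressed by OLS on an intercept, a linear
calendar-month trend, and fixed effects for integer year of age. The fitted
model is the counterfactual "as if never referred"; residuals are observed
minus predicted SBP for all analysis rows. Ages advance on whole-year
boundaries of elapsed event months; an age never seen in the baseline is
predicted with the nearest fitted age's coefficient (ties to the younger
age), since fixed effects carry no extrapolation slope. The reference age
(coefficient pinned at 0) is the most frequent age-year, ties to the younger.

**Step 2 — event-study estimate.** Residuals are regressed on a post-window
indicator with patient fixed effects, estimated by the within (patient
demeaning) transformation; the coefficient is the intention-to-treat (ITT)
effect of referral in mm Hg. Variance is the Liang–Zeger cluster-robust
sandwich with clusters at the patient level and small-sample factor
(G/(G−1))·((N−1)/(N−K)), K counting the regressors plus the G absorbed
intercepts — exactly the clustered covariance of the equivalent
dummy-variable regression, which the test suite verifies coefficient-for-SE.
P-values use a t distribution with G−1 degrees of freedom.

**Take-up and scaling.** Take-up is the share of referred patients with at
least one electronic BP reading. Its SE is the sample-variance binomial
formula `sqrt(p(1−p)/(n−1))`, identical to the HC1-robust SE of an
intercept-only regression on the take-up indicator; this is the formula that
reproduces published take-up SEs at small n, where the `1/n` variant differs
in the fourth decimal. The treatment-on-treated (TOT) effect is the Wald
ratio ITT / take-up; a delta-method SE
`sqrt((se_itt/p)² + (itt·se_p/p²)²)` is attached as supplementary output,
since published tables print the scaled point estimate alone. Between-group
ITT contrasts come from a pooled interaction regression (post +
post×group, patient fixed effects, patient-clustered SEs), whose interaction
coefficient is exactly the difference of the separate estimates; take-up
contrasts use the independent-proportions SE.

## The synthetic generator

Latent SBP for patient i of group g at calendar month t (event month e):

    y_it = m_g + a_i + s·(t − t0) + b·(age_it − A_g) + U_i · tau_g · r(e) + eps_it

with per-patient intercept `a_i ~ N(0, patient_sd)`, reading noise
`eps_it ~ N(0, noise_sd)`, take-up `U_i ~ Bernoulli(p_g)` and ramp
`r(e) = min(1, e/ramp_months)` for e ≥ 0. Referral months are uniform over a
22-month window; ages are drawn from each group's normal (truncated to
[18, 100]) and advance with the panel. Calendar time is centered at
t0 = E[referral] − 1 and age at the group mean so that `m_g` is the expected
observed SBP at event month −1 — the baseline as reported.

Defaults are the study conditions: group sizes 1318/745/143; take-up
probabilities 0.58/0.50/0.41; TOT effects −16.8/−13.2/−16.0 mm Hg with a
6-month ramp; group means 138.4/131.4/128.8 mm Hg; age means (SDs) 63.2
(15.2)/67.1 (12.8)/69.6 (11.5). Where the study conditions leave a parameter
free, one realistic value was fixed up front:

- `patient_sd = 13`, `noise_sd = 17` mm Hg. Between-person dispersion is
  compressed relative to the general hypertensive population because referral
  selects on a high-BP trend; within-person month-to-month office SBP
  variability is large. Together (with small age and trend terms) these give
  a cross-sectional SD at month −1 of ≈ 21.4 mm Hg, the reported baseline
  dispersion.
- `calendar_slope = 0.1` mm Hg/month (≈ 1.2 mm Hg/yr secular drift in
  poorly controlled hypertension) and `age_effect_per_year = 0.4` mm Hg/yr
  (cross-sectional adult SBP gradient).
- `obs_prob_per_month = 0.35` (roughly one office BP measurement per
  quarter), with `1 + Poisson(0.3)` readings in an observed month. With a
  6-month post window this leaves ~8% of patients without post-window data,
  exercising the cohort filter the way real attrition would.

Device readings are modelled as relabelled readings *within* the common
patient-month coverage process (takers' post-referral readings are labelled
"device" with probability 0.7) rather than as additional coverage for
takers. In real RPM data device transmission increases takers' observation
density; modelling that would overweight takers in the unbalanced within
estimator and bias the ITT toward the TOT, breaking the ITT = TOT × take-up
bookkeeping the recovery tests rely on. The source label still lets the
office-only sensitivity path be exercised. This is the main respect in which
the generator is more benign than real data; the others are strictly MCAR
observation (no informative missingness), no medication titration or
adherence decay, and a globally linear secular trend. Passing recovery tests
therefore show the estimator is correct under its own assumptions, not that
those assumptions hold in any particular EHR.

## Numerical choices

- Within estimator and sandwich are dense numpy linear algebra; the trend
  fit uses `numpy.linalg.lstsq` with explicit rank checks (a baseline window
  with a single calendar month is reported as collinear by name).
- OLS orthogonality (zero mean residual, zero calendar correlation on the
  fit window) is asserted to 1e-8 in the tests; within-vs-dummy-OLS
  equivalence to 1e-10.
- Rounding for display is round-half-even on the decimal representation,
  applied only at render time; internal values stay at full precision, and
  every rendered Part C cell is checked to equal Part A / Part B.
- Degenerate inputs: zero residual variance yields SE 0 (not an error); a
  single cluster, an empty group, a zero take-up rate, and overlapping
  windows raise typed errors naming the offending input.

## Calibration of inference, and a known limitation

Step-1 uncertainty is **not** propagated into Step-2 SEs (the two-step,
generated-regressand design matches how the analysis is reported). This is
not innocuous: the Step-1 calendar slope is estimated on an 11-month baseline
and extrapolated ~16 months forward into the post window, so its sampling
error shifts every patient's pre→post contrast together — a common shock that
patient-clustered SEs cannot register, with magnitude of the same order as
the clustered SE itself at any sample size (both shrink as 1/√n). In
simulation at the default conditions the full two-step pipeline rejects a
true null at |t| > 1.96 far above the nominal rate, while the identical
Step-2 machinery applied to residuals from the *known true* counterfactual is
correctly calibrated (~5%). The null-calibration test therefore validates the
Step-2 estimator and its clustered variance against the generator's true
trend model; mean (point-estimate) recovery of ITT and TOT is validated
through the full pipeline, which is unbiased. Users should read the reported
SEs as conditional on the fitted baseline trend.

Other limitations: nearest-age fallback makes out-of-range age predictions
flat; the per-group Step-1 fit (the default; a pooled fit is available via
`pooled_trend=True`) can be noisy for small groups; and with a 143-patient
group, single-study estimates of the smallest column swing by several mm Hg —
replicate means (see `examples/estimator_recovery.py`) are the meaningful
check at that size.

## Problem sizes used in validation

Monte-Carlo recovery runs 200 replicate single-group cohorts at n = 1318;
null calibration runs 500 replicates at n = 500; the acceptance script
averages 250 replicate three-group studies (n = 2206 each). These sizes give
Monte-Carlo standard errors a factor of several below the tolerances they
are checked against.
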