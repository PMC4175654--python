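# Methods

`rsrates` implements the statistical machinery behind publicly reported
hospital 30-day outcome measures — risk-standardized mortality rates (RSMR)
and risk-standardized unplanned readmission rates (RSRR) — as a tested
pipeline over claims-like tables, together with a synthetic claims generator
that provides known ground truth.

## The risk model and standardization

For patient *j* at hospital *i*, the outcome (death within 30 days of
admission, or unplanned readmission within 30 days of discharge) follows a
random-intercept logistic model

    logit Pr(y_ij = 1) = μ + α_i + x_ij′β,    α_i ~ N(0, τ²),

where x_ij collects age, sex and binary comorbidity indicators.  Parameters
(μ, β, τ) are estimated by marginal maximum likelihood with the hospital
effect integrated out; hospital effects are reported as posterior modes
(empirical Bayes), which shrink low-volume hospitals toward the national
average.

A hospital's standardized rate is

    RSR_i = (predicted_i / expected_i) × (national crude rate),

with `predicted_i = Σ_j expit(μ + α̂_i + x_ij′β)` and
`expected_i = Σ_j expit(μ + x_ij′β)`: the numerator is the hospital's
model-implied event count for its own case-mix, the denominator the count an
average (α = 0) hospital would produce on the same case-mix.  A hospital
identical to the national average therefore reproduces the national crude
rate exactly.

### Numerical estimation

* The per-cluster integral uses a **Laplace approximation** by default and
  **adaptive Gauss–Hermite quadrature** (`method="agq"`, default 9 nodes,
  15 in verification runs) centred and scaled at the posterior mode.  Tests
  verify the AGQ marginal log-likelihood against dense-grid trapezoid
  integration to 1e-4 on a 180-row fixture.
* The posterior mode per cluster is found by a vectorized 1-D Newton
  iteration (steps clipped at ±5, tolerance 1e-11).
* The outer optimization is L-BFGS-B over (μ, β, τ) with τ ∈ [0, 10],
  relative log-likelihood tolerance 1e-8 and projected-gradient tolerance
  1e-6, started from the pooled logistic MLE (IRLS) with τ₀ = 0.2.
  τ below 1e-6 is treated as exactly zero (pooled logistic), so a
  homogeneous population yields τ̂² = 0 and all α̂ = 0.
* Covariates are standardized internally for conditioning; coefficients are
  reported on the original scale.  Rank-deficient designs raise an error
  naming the offending columns; non-convergence is flagged on the fit,
  never silent.

## Cohort construction

Day counting uses integer day offsets from the start of the measurement
window; a measure year is 365 days (the July–June reporting convention).

* **Transfer chaining:** consecutive acute admissions of one patient with
  ≤1 day between discharge and the next admission form one episode of care.
  Mortality is attributed to the episode's first (admitting) hospital,
  readmission to its last (discharging) hospital.  The episode keeps the
  first record's principal condition, age and sex, and the union of
  secondary codes; overlapping acute stays drop the later record with a
  logged warning.
* **Inclusion:** principal condition matches the measure; age ≥ 65 at
  admission; continuous enrollment for the 365 days before admission; no
  hospice span overlapping the lookback period or admission day.
* **Mortality cohort:** one episode per patient per measure year, chosen by
  a seeded uniform draw (sorted before drawing, so the selection is
  invariant to input row order); outcome = death on days 0..30 inclusive
  from admission.
* **Readmission cohort:** index episodes must end alive; an episode
  admitted within 30 days after a prior index discharge cannot itself be an
  index; outcome = an unplanned acute episode admitted on days 1..30
  inclusive after discharge.  Observation and non-acute stays are neither
  indexes nor outcome events.  Same- or next-day admissions are transfer
  chains, not readmissions.
* **Planned readmissions** are classified from configurable code lists:
  planned iff a procedure is on the always-planned list, or on the
  potentially-planned list with a non-acute principal condition.  The
  production code tables are configuration, not shipped; the shipped
  defaults cover the synthetic vocabulary.
* **Covariates:** comorbidity indicators come from index secondary codes
  and any claim in the lookback year, except codes on a configurable
  possible-complication list, which count only when seen in lookback claims
  (a complication of the measured stay must not credit the hospital's
  case-mix).  An exclusion waterfall is emitted whose counts always sum to
  the candidate count.

## Bootstrap intervals and categories

Confidence intervals use a hospital-level (cluster) bootstrap: each
iteration samples hospitals with replacement, refits the model
(warm-started from the base fit), and recomputes sampled hospitals' rates
against that iteration's crude national rate.  A hospital drawn k times
contributes k copies to the refit — each treated as a distinct cluster —
but only one rate observation (its first sampled copy) to its own
distribution.  Percentile intervals and empirical variances are taken per
hospital across the iterations in which it appears (flagged unstable below
30 appearances); iterations that fail to converge are dropped and counted,
with an error above 10%.

**Posterior draws.** Within each iteration the copy's intercept is drawn
from its approximate posterior, N(α̂, 1/(Σ_j p̂_j(1−p̂_j) + 1/τ̂²)), rather
than fixed at the mode.  Hospital resampling alone never varies a
hospital's own cases, so a mode-only bootstrap reflects refit noise only
and undercovers badly (we measured ~85% coverage and 15% of homogeneous
hospitals flagged); with posterior draws the null simulation shows ≥95%
coverage and no false flags.  This matches standard practice in the
hospital-profiling literature.  5,000 iterations is the reporting-grade
setting; 200 is the desk default used in tests and the acceptance script.

Hospitals are categorized against the national rate: **better** if the rate
is below it and the 95% interval excludes it, **worse** symmetrically,
otherwise **no different**; hospitals under 25 cases are not reported.

## Trends

Annual rates rebuild the cohort and refit the model independently per
measure year.  The trend test is a Gaussian identity-link GEE of annual
hospital rates on categorical period indicators with an exchangeable
working correlation, robust (sandwich) standard errors, and Wald pairwise
period contrasts; raw p-values are reported without multiplicity
adjustment.  Unbalanced panels are allowed.  Degenerate panels (constant
within hospital) drive the exchangeable correlation to 1, where statsmodels
fails; the fit then falls back to an independence working correlation, and
to plain least squares when the residual variance is exactly zero, so a
constant panel returns exactly-zero contrasts.  Category-change tabulation
crosses two periods' categories into improved / no change / worsened cells,
excluding (and counting) hospitals under 25 cases or present in one period
only.

Note a small-sample caveat the tests make visible: the yearly national
crude rate is a common multiplier of all hospitals' rates, so at desk-scale
yearly cohorts its binomial noise appears as a genuine shift in period
means, and the GEE (correctly) flags it.  At the national scale this term
is negligible.

## Weighted summaries and the counterfactual

National distribution summaries weight hospitals by inverse bootstrap
variance.  Weighted percentiles use a lower-step dialect — the smallest
value whose normalized cumulative weight reaches the quantile — chosen so
outputs are reproducible bit-for-bit and integer weights coincide with
value replication; equal weights reduce exactly to the unweighted summary.
The averted-events counterfactual sums (rate − median)/100 × cases over
hospitals above the median, rounded to whole events; the median defaults to
the same weighted-median dialect but can be supplied explicitly.

## The synthetic generator

The generator emulates one condition-outcome measure of Medicare-FFS/VA
style inpatient claims.  Its defaults are the study conditions used
throughout: hospital volumes lognormal with quartiles 10/40/156 eligible
cases per 3 years, patient ages truncated-normal with quartiles 72/79/86
(plus 3% under-65 to exercise the age rule), four independent Bernoulli
comorbidities with prevalences 0.30/0.25/0.20/0.15 and log-odds
0.40/0.30/0.25/0.20, age effect 0.04/year, male effect 0.10, hospital
effect SD τ = 0.20, and national intercept μ = −2.25, which yields a crude
30-day mortality rate of ~15.2% (the readmission demo uses μ = −1.95 for a
~18.3% crude rate) — both matching the published national crude rates the
package emulates.  Around the measured outcome it emits transfer chains
(5%), planned readmissions (calibrated so ~10% of 30-day readmissions are
planned), observation stays, prior-history admissions, hospice spans (2%),
enrollment gaps (5%), under-age admissions, same-year repeat stays (12%)
and death dates, so every exclusion rule has work to do.  One global seed
feeds four named substreams (hospitals / patients / outcomes / furniture),
and identical configs produce byte-identical tables.

What it does **not** emulate: real ICD-9/CCS vocabularies, correlated
comorbidities, coding drift, hospital-level case-mix differences (case-mix
is i.i.d. across hospitals), seasonal admission patterns, or billing
fields.  Passing tests therefore demonstrate the correctness and
calibration of the measure machinery under the stated generative model, not
the clinical validity of risk adjustment on real claims.

## Problem sizes and defaults

Desk-scale defaults keep every analysis inside a laptop minute: 60–100
hospitals, ~5,000–25,000 index admissions, 200 bootstrap iterations,
20-replicate recovery studies at 100 hospitals × 200 cases with τ = 0.3.
At that size the replicate sampling SD of τ̂ is ≈0.03 and the Spearman
correlation between true hospital effects and estimated rates averages
≈0.79 — the calibrated thresholds in the acceptance tests come from those
replicate distributions.  Reporting-grade runs scale the same code by
raising `n_iterations` and the volume distribution.

## Known limitations

* The Laplace default slightly underestimates τ on very small clusters;
  AGQ with ≥9 nodes is the verification setting.
* Percentile bootstrap intervals with posterior draws are mildly
  conservative under the null (coverage above nominal).
* The GEE assumes Gaussian rates with identity link; rate panels are
  bounded below by zero, which matters only for tiny cohorts.
* `alpha_` covers only hospitals with ≥1 case in the fitted cohort; unseen
  hospitals predict at the national intercept.
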