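# Methods

This note records the statistical model behind each pipeline stage, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Outcome construction

Joint-level ultrasound synovitis is reduced to a scalar per visit. Two
conventions coexist in the development cohorts and both are supported:

* **composite22** — a combined PDUS grade per joint, defined as 0 when
  both GS and PD are 0 and otherwise `max(gs, pd)`, summed over 22
  joints (wrists, MCPs 2–3, PIPs 2–3, knees, MTPs 1–5, bilateral). The
  combination rule is exposed as a swappable function; `max` reproduces
  the published combined-grade table for the grade patterns that occur
  with GS-dominant synovitis, and PD signal without GS hypertrophy
  (atypical) is graded the same way and logged.
* **sum10** — GS and PD summed separately over bilateral MCPs 1–5 on
  0–4 scales. Raw grades are summed without rescaling: the derivation
  works with within-cohort coefficient *ratios*, which absorb any
  outcome scaling, so cross-cohort comparability of the raw totals is
  not required.

## Censored CRP

CRP reported only as "< 5 mg/L" is left-censored at a single threshold.
Robust regression on order statistics (ROS) fits `ln x` against normal
scores at Weibull plotting positions adjusted for the censored
fraction: with `m` detected among `n`, detected value `i` (ascending)
sits at `p = (1-m/n) + (m/n)·i/(m+1)` and censored value `i` at
`p = (1-m/n)·i/(c+1)`. Detected values are never altered; censored ones
are replaced by back-transformed predictions of the fitted line. A weak
fit can push the largest prediction marginally past the threshold; such
predictions are capped just below it and counted in the diagnostics.
The single substitute recommended for routine scoring is the median of
the imputed values rounded half-up to an integer, which gives 2 mg/L
under the calibration used here (lognormal with median 6 and upper
quartile 18 mg/L: `sigma = ln(18/6)/z_0.75 = 1.63`).

## Missing covariates

Chained equations with predictive mean matching (PMM, donor pool k = 5,
10 cycles, m = 20 independent chains by default; statsmodels'
`MICEData` supplies the engine). Imputation models run on the analysis
scales — sqrt joint counts, `ln(CRP+1)`, `ln(ESR)` — plus GHVAS,
HAQ-DI, age and sex; the GSPD outcome is excluded from the predictor
set and rows without an observed GSPD are dropped beforehand. Observed
cells are carried over verbatim. Censored CRP rows enter the imputation
carrying the threshold value; this slightly coarsens donors near the
limit and is accepted because scoring later replaces all censored
values by the single substitute anyway. Estimates across imputations
are pooled by Rubin's rules (total variance `Ubar + (1+1/m)B`), with a
t reference using the classic Rubin degrees of freedom, or the
Barnard–Rubin adjustment when complete-data degrees of freedom are
supplied. Multiple imputation is performed once on the full dataset,
not nested inside cross-validation folds.

## Mixed models and cross-validated evidence

GSPD is modelled as `y_ij = x_ij'β + b_i + e_ij` with a patient random
intercept, fitted by maximum likelihood (not REML, so log-likelihoods
are comparable across fixed-effect sets). The likelihood is profiled:
for fixed `λ = τ²/σ²` the GLS coefficients and `σ²` are closed-form,
leaving a one-dimensional bounded search over `λ` with the boundary
`λ = 0` checked explicitly. This fitter is exercised against
statsmodels' `MixedLM` (ML) as an independent oracle in the tests.

Model comparison uses 20-fold cross-validation with folds that
partition *patients*, because the evidence measure is per-patient:
each held-out patient contributes the log-density of their residual
vector under `N(0, σ²I + τ²J)` (the compound symmetry induced by the
random intercept), summed over all test folds. R² is the squared
Pearson correlation between observed and predicted values over the
concatenated test folds. With m completed datasets, both metrics are
computed per dataset on a shared fold assignment and averaged
arithmetically. Fold assignment is seeded and recorded; folds are not
stratified by cohort (models are fitted within cohort) — stratification
is available through the fold-assignment seed interface if wanted.

A test-log-likelihood difference of `0.5·χ²_{0.99,2} − 2 = 2.605 ≈ 2.6`
natural-log units between nested models two parameters apart is the
"P = 0.01-equivalent" evidence threshold, via the asymptotic
equivalence of leave-one-out CV and AIC. The same arithmetic fixes what
"the 2C model wins" can mean under a true null for the two extra
parameters: within a single cohort the preference probability is
`P(χ²₂ < 4) ≈ 0.87`, so the package defines preference by the
test-log-likelihood difference summed over the three development
cohorts (`P(χ²₆ < 12) ≈ 0.94` under the null), mirroring the fact that
the score is derived from all three cohorts jointly.

## Score derivation

For each cohort a two-component model (`sqrt(SJC28)` + acute-phase
term) is fitted to every completed dataset, coefficients are
Rubin-pooled, and the ratio `β_sjc / β_ap` is formed (a non-positive
acute-phase coefficient makes the ratio unusable for scoring and raises;
the pipeline drops such a cohort from that acute phase's combination
with a warning). Ratios are combined as the weighted mean with weights
equal to each cohort's count of observations with a non-missing
acute-phase measurement — observations, not patients. Ratios are
carried at full precision and rounding happens only when the equation
is emitted: the acute-phase weight is the reciprocal of the combined
ratio, rounded to 1 decimal for CRP and 2 decimals for ESR. The final
score is deliberately not rescaled onto the conventional DAS28 range
and no remission cut-offs are defined for it.

## Radiographic validation

Erosion presence is a longitudinal binary outcome, modelled by GEE with
logit link, exchangeable working correlation and robust (sandwich)
standard errors (statsmodels `GEE`; max 100 iterations, coefficient
tolerance 1e-8). Model fit is ranked by QIC, computed in-module per
Pan's definition: `−2·QL + 2·trace(Ω̂_I V̂_R)` with the binomial
quasi-likelihood evaluated at the GEE estimates and `Ω̂_I = X'vX` the
independence-model information. (statsmodels' built-in QIC uses a
different information matrix whose penalty does not approach the
parameter count; with the definition used here, QIC on singleton
clusters agrees with the logistic AIC to a fraction of a percent and
adding a pure-noise predictor increases QIC on average.)

Larsen damage totals are non-negative, right-skewed and repeated within
patient. They are modelled by a random-intercept generalized linear
mixed model with log link and Poisson kernel, fitted by maximum
likelihood with adaptive Gauss–Hermite quadrature (15 nodes; per-cluster
posterior modes by Newton iterations; predictors centred and scaled
internally and estimates mapped back). Age and disease duration are
always included as covariates. Because real damage scores are usually
overdispersed relative to Poisson, a quasi-Poisson dispersion is
estimated from conditional Pearson residuals and standard errors are
inflated by its square root when it exceeds 1; AIC/BIC come from the ML
log-likelihood. This is a declared proxy for the flexible latent-and-
mixed-model family sometimes used for such outcomes: its adequacy is
established here only by parameter recovery on the matching generator,
and the implementation agrees with lme4's `glmer` (Poisson, adaptive
quadrature) to ~1e-5 on a fixture.

## Synthetic cohorts

The generator emulates the development-study data structure, not any
patient-level real data:

* **Designs.** IACON-like: 434 patients, visits at weeks 0/26/52/104,
  composite22 on 0–3 scales. IDEA-like: 59 patients, weeks 0/52/78,
  composite22. PEAC-like: 117 patients, weeks 0/26, sum10 on 0–4
  scales. Validation register: 717 patients, years 0/3/5/10. A global
  `cohort_scale` shrinks patient counts proportionally for simulation
  studies.
* **Components.** Per-visit draws come from a Gaussian copula with a
  patient-level severity factor (40% of latent variance) so that
  components correlate within patients over time; latent cross-
  correlations default to 0.5 (TJC–SJC), 0.7 (CRP–ESR; acute-phase
  reactants track each other strongly in practice) and 0.3 otherwise,
  all configurable — the TJC–SJC correlation in particular is a config
  parameter, not a fixed constant. Marginals are lognormal (CRP, ESR),
  rounded-sqrt-normal clipped to 0–28 (joint counts) and clipped normal
  on 0–100 mm (GHVAS), each calibrated to the published baseline
  quartiles (when the lower quartile is reported only as below the
  censoring limit, the scale comes from the median-to-Q3 spread).
  Distributions are stationary across visits: the generator reproduces
  the baseline case mix at every visit and does not model treatment
  response, so visit-level censoring fractions match the IACON report
  (45.5% vs 431/889 = 48.5%) but understate cohorts whose CRP fell
  under treatment.
* **Outcome.** GSPD is linear in `sqrt(SJC28)` and `ln(CRP*+1)` with a
  patient random intercept and Gaussian noise (defaults: intercept 6,
  slopes 5 and 3, τ² = 4, σ² = 9, zero TJC/GHVAS effects; the implied
  SJC:CRP ratio 5/3 matches the magnitude of the published combined
  ratio). `CRP*` is the value an analyst would use — the observed value,
  or the single substitute 2 when censored — so the generative
  coefficients are recoverable by the downstream analysis without
  deconvolving the censoring. The latent outcome is rounded onto the
  joint grid; draws falling outside the representable range (possible
  only in the far Gaussian tails under the defaults) have their visit
  noise redrawn rather than being clamped, and the redraw count is
  reported. The integer total is then spread evenly across the joint
  set (respecting grade caps, with a randomized remainder and PD drawn
  below the GS grade) so that recombining the written joint-level table
  reproduces the visit's GSPD exactly. Totals that cannot be laid out
  on the grid raise; nothing is silently truncated.
* **Missingness** is MAR given age and HAQ-DI, with logistic intercepts
  solved so realized expected rates equal the published per-component
  rates.
* **Radiographic truth.** Larsen totals are cumulative Poisson
  increments with log-rate `ln(rate0) + γ_sjc·sqrt(SJC) +
  γ_crp·ln(CRP+1) + γ_tjc·sqrt(TJC) + u_i` and exposure equal to the
  inter-visit gap (the first visit's exposure adds the pre-entry
  disease duration), hence monotone non-decreasing within patient.
  Erosion is a per-visit Bernoulli with the same linear predictor and
  intercept −1; conditional independence across visits keeps the null
  model exact (prevalence = expit(intercept) when effects and
  heterogeneity vanish) at the cost of not modelling the irreversibility
  of erosions. Default effects (0.2, 0.3, −0.1) follow the published
  sign pattern — positive SJC/CRP, non-positive TJC; simulation studies
  use γ_tjc = −0.28 (erosion power setting) or γ_tjc = 0 (Larsen
  null-coverage setting), both admissible under the sign constraint.

What passing tests show: the pipeline recovers known coefficients,
ratios and signs under its own generative assumptions, and the
model-selection machinery behaves as the asymptotics predict. What they
do not show: performance under treatment-driven trajectories,
informative dropout, non-linear component-synovitis relationships, or
reader variability in ultrasound/radiograph scoring, none of which the
generator emulates.

## Numerical choices and problem sizes

* LMM profile search over `ln λ ∈ [−12, 8]` with xatol 1e-8; explicit
  λ = 0 comparison.
* GLMM: 15 adaptive Gauss–Hermite nodes, L-BFGS-B with `ln σ_u`
  bounded in [−8, 3]; numerical Hessian for standard errors.
* Scores carry full precision internally; files are written at 6
  significant digits; derived weights round only at equation emission.
* Simulation studies in the test suite use 100 seeds at the full
  cohort sizes for the model-selection and sign-recovery properties,
  and reduced register scales (0.15–0.42 of full size) for the heavier
  GLMM comparisons; the acceptance script uses 25 replicate cohorts of
  n = 889 for the censored-CRP substitute.

## Known limitations

* The ESR weight derived on synthetic data reflects the generator's
  truth (GSPD driven by CRP, ESR informative only through their
  correlation), so it is attenuated relative to the published 0.32;
  the published-coefficient path reproduces 0.32 exactly.
* PMM with small donor pools is only approximately proper; pooled CIs
  attain ~95% coverage in the suite's MAR scenario but can undercover
  at higher missingness fractions.
* The Larsen model is a Poisson-kernel proxy; with strongly
  overdispersed real damage scores its AIC/BIC comparisons remain
  meaningful but its nominal SEs require the quasi-Poisson inflation.
* Erosion is generated without within-patient persistence; GEE
  marginal estimates are unaffected in expectation, but transition-
  style analyses would need a different generator.
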