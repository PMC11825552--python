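# Methods

## The model

`txapk` implements a population pharmacokinetic (PK) analysis of tranexamic
acid (TXA) in adult cardiac surgery with cardiopulmonary bypass (CPB): a
double 1000-mg IV bolus regimen (at the start of surgery and at CPB
discontinuation), sparse sampling, and a nonlinear mixed-effects treatment
of the concentration data.

**Structural model.** Disposition is linear and compartmental. The
two-compartment IV-bolus solution is evaluated in closed form: with
micro-constants `k10 = CL1/V1`, `k12 = CL2/V1`, `k21 = CL2/V2`, the hybrid
rate constants `alpha >= beta` are the roots of
`s^2 - (k10+k12+k21)s + k10*k21`, and after a dose `D`

    C(t) = (D/V1) * (A e^{-alpha t} + B e^{-beta t}),
    A = (alpha - k21)/(alpha - beta),  B = 1 - A,

superposed over all prior doses. `A + B = 1` makes `C(0+) = D/V1`.
`beta` is computed as `k10*k21/alpha` (product form) to avoid cancellation,
and when `|alpha-beta| < 1e-10*alpha` the repeated-root limit
`(D/V1) e^{-alpha t}(1 + (k21-alpha)t)` is used. (With all rates positive
the discriminant is bounded below by `(k10-k21)^2`, so the degenerate
branch is a numerical guard, not a reachable regime; it is still exercised
against an ODE oracle in the tests.) Setting `CL2 = 0` collapses the model
onto the one-compartment mono-exponential.

**Random effects.** Parameters vary log-normally between subjects,
`P_i = TV(P) exp(eta_i)`, `eta_i ~ N(0, omega^2)`, with a diagonal
covariance (no eta correlations). By default IIV is placed on `CL1` and
`V1` — the two parameters the sparse double-bolus design identifies best —
and this placement is configurable; the source analysis does not report
which parameters carried IIV, so it is an explicit assumption here.

**Residual error.** Combined additive + proportional:
`Cobs = Cpred + eps*sqrt(1 + (Cpred*sigma2/sigma1)^2)` with
`eps ~ N(0, sigma1^2)`, i.e. the SD around a prediction `c` is
`sqrt(sigma1^2 + (sigma2*c)^2)`: `sigma1` (mg/L) dominates near the
quantitation floor, `sigma2` (dimensionless CV) at high concentrations.

**Covariate model.** Power laws on the typical values,
`TV(P) = theta_P * (cov/ref)^exponent`, normalized at the cohort median.
The final published model is

    V1  (L)   = 12.77 * (BW / 61.4)^0.911
    V2  (L)   = 6.857
    CL1 (L/h) = 3.263 * (CLcr / 61.0)^0.752
    CL2 (L/h) = 2.859

Creatinine clearance enters in **mL/min** normalized by 61.0 — the cohort
median on that scale — although the published equation carries an "(L/h)"
unit label; the printed worked example (CLcr 60 mL/min giving CL1
3.223 L/h) is only consistent with the mL/min reading, which this package
adopts and documents. Cockcroft-Gault (`(140-age)*BW/(72*Scr[mg/dL])`,
x0.85 for women; serum creatinine converted from umol/L by /88.4) and
DuBois-DuBois (`0.007184 * BW^0.425 * height^0.725`) supply the derived
covariates. Reference values may be given explicitly or left unset, in
which case the engine re-derives them as the medians of the dataset being
fitted.

## Estimation (FOCE with interaction)

The marginal likelihood of a subject's data integrates over its random
effects and has no closed form. The engine uses the standard published
first-order-conditional-estimation objective with interaction: for each
subject the conditional mode `eta_hat` of the joint -2 log density is
found, the model is linearized there (`G = df/deta`, central differences,
step 1e-4), and the contribution to the objective function value (OFV) is

    OFV_i = r' V^{-1} r + log|V|,
    r = y - f(eta_hat) + G eta_hat,
    V = G Omega G' + diag(sigma1^2 + (sigma2 f(eta_hat))^2),

with `n log 2pi` constants dropped (the usual reporting convention; OFV
*differences* between models are unaffected). `V^{-1}` and `log|V|` go
through the matrix-inversion lemma so only K x K systems are solved. The
commercial implementation used in the source analysis (FOCE-ELS) has
unpublished internals; equivalence is asserted against an adaptive
Gauss-Hermite quadrature oracle (15 nodes per dimension, centered and
scaled at the joint mode), which in the tests agrees with this objective
to well under 0.5 OFV units on 5-subject problems at the study's
variability levels.

**Inner problem.** `eta_hat` is found by a damped Newton iteration,
vectorized across subjects: the Hessian contracts the exact curvature of
the per-observation deviance with respect to the prediction (clamped below
at `0.1/variance` to stay positive definite) with `G G'`, plus the prior
precision. Steps are Armijo-backtracked, clipped to a trust region of 2
per component, and `eta` is hard-bounded at +-10 (a 2e4-fold parameter
deviation; beyond any biology, inside floating-point range). A subject
stops when its gradient sup-norm drops below `1e-8*(1+|g|)` or its Newton
step falls below 1e-9 — the gradient is assembled from a differenced `G`
and cannot resolve much below ~1e-6 in absolute terms, so near the mode
the step criterion is the sharper one. Subjects still carrying a material
gradient after the loop (strongly nonlinear error coupling can make the
damped iteration crawl) are polished by a derivative-free Nelder-Mead
minimization of the same objective. The whole procedure starts from
`eta = 0` on every call, making the OFV a deterministic function of the
population parameters.

**Outer problem.** L-BFGS-B on log-transformed typical values and variance
components (covariate exponents untransformed), finite-difference gradient
step 1e-6, relative objective tolerance 1e-10, bounds wide enough to be
inactive at any plausible optimum. If the line search terminates
abnormally — which can happen on the finite-difference noise floor even at
a stationary point — the optimizer is restarted once from the terminal
point and the fit is declared converged when no material improvement
(>= 0.1 OFV) remains. Standard errors come from the inverse
central-difference Hessian of OFV/2 (step 1e-4 on the transformed scale),
delta-method propagated to the natural scale; %RSE = 100*SE/estimate.

**Model comparison.** Nested models are compared by the likelihood-ratio
(-2 l.l.d.) rule: an extension is significant when its OFV decrease
exceeds the chi-squared upper quantile at p = 0.01 (6.635 for 1 df). The
shotgun covariate search fits *every* subset of the candidate effects
(2^k models, k <= 4), reports each subset against its parent (the same
subset minus the last-added effect), and selects the lowest-OFV subset in
which dropping any single effect would worsen the OFV by more than the
threshold; ties go to the smaller model. Non-convergent fits stay in the
table but are excluded from selection.

## Validation machinery

**Goodness of fit.** PRED is the population prediction (`eta = 0` with
covariates), IPRED the conditional prediction (`eta = eta_hat`), and CWRES
decorrelates the FOCE residual `y - f(eta_hat) + G eta_hat` by the
Cholesky factor of the linearized marginal covariance. With no random
effects CWRES reduces exactly to `(y - PRED)/residual_sd(PRED)`; under a
correctly specified model it is approximately standard normal, which the
tests check on ~450 observations (mean within +-0.1, SD within
[0.85, 1.15], |skewness| < 0.5).

**Visual predictive check.** Replicate datasets are simulated on the
observed design (same subjects, covariates, doses, times) with fresh eta
and residual draws; negative simulated concentrations are truncated at
zero before percentile computation (concentrations are nonnegative; the
additive error component can undershoot). Observations are binned by
nominal sampling occasion — the protocol times after each dose — rather
than by continuous time, because the design is sparse at fixed occasions;
bins are induced by the observations themselves and therefore never empty.
Per bin, each replicate's percentiles bracketing the central interval
(default 90%) are summarized by their across-replicate median, and the
fraction of observations inside the band is reported. Because
observations and simulations within a bin are draws from the same pooled
mixture, the nominal coverage of the 90% band remains 90% despite the
within-bin design heterogeneity.

**Bootstrap.** Subjects are resampled with replacement (cohort size
preserved), the model refitted per replicate starting from the original
point estimate (speed and stability; a failed replicate is counted and
excluded, and more than 50% failures aborts with a diagnostic). Replicate
estimates are summarized as median, 2.5/97.5 percentiles, and
%RSE = 100*SD/median — the formula behind the published bootstrap %RSE
column is not stated, so the common SD/median convention is used.

## The synthetic cohort

No raw data accompany the source analysis, so the study is emulated:

* **Cohort**: n = 77, 51/77 male. Body weight, height, serum creatinine
  and CPB duration are log-normal with parameters chosen so the
  distribution median and quartiles equal the published summaries
  (BW 61.4 [54.6-75.2] kg; height 161.8 [156.5-170.7] cm; Scr 85.7
  [72.5-105.2] umol/L; CPB 170 [136-210] min) — i.e. `mu = log(median)`,
  `sigma = log(q3/q1)/(2*z_{0.75})`. Age is truncated normal on [26, 84]
  years (location 69, scale from the 60-75 IQR). Covariates are drawn
  independently (only univariate summaries are published; independence is
  the minimal assumption); CLcr and BSA are computed, never drawn.
* **Design**: 1000 mg at t = 0; CPB duration drawn per subject; 1000 mg
  again at CPB end; nominal samples at 0.5/1/2/5 h after dose 1 and
  1/6/16 h after dose 2, jittered with SD 0.1 h (the protocol times are
  "approximate"). Any dose-1 sample falling at or after dose 2 is dropped,
  mirroring the reported re-dosing before the 5-h draw; under the default
  design this lands the expected observation count at ~454, bracketing the
  study's 453.
* **Truth**: fixed effects from the final published model; variance
  components are *not* published and default to omega^2 = 0.09 (30% CV) on
  CL1 and V1 and sigma1 = 1 mg/L, sigma2 = 0.15 — typical pharmacometric
  magnitudes, held in configuration rather than code. Simulated
  concentrations <= 0 are redrawn (up to 100 times, then truncated to
  0.01 mg/L and counted in the provenance).

What the generator deliberately does **not** emulate: CPB-circuit
sequestration, hemodilution dynamics, ultrafiltration or bleeding-volume
dependence (discussed qualitatively but never modeled in the source), the
three low-concentration outlier patients (no quantitative mechanism is
given), within-subject covariate drift, or assay-level censoring (no LLOQ
rule is stated; all positive concentrations are used). Passing
recovery/coverage tests therefore demonstrate the estimator's correctness
under the stated design — not robustness to those real-data features.

## Problem sizes and numerical choices in the test suite

Stochastic checks are sized to finish quickly while keeping their
statistical meaning: parameter recovery uses the full 77-subject design
(one cohort for the point check, 10 seeds for the median-bias check);
the VPC coverage check uses 200 replicates at ~454 observations (binomial
99% envelope [0.86, 0.94]); the covariate-retention check uses 40-subject
cohorts over 5 seeds; the decoy-rejection (type-I) check uses 20
replicates of 24-subject one-compartment cohorts, where the chi-squared
p = 0.01 rule should reject in >= 90%; the bootstrap consistency check
uses a 24-subject one-compartment cohort with 20 replicates. Fit options
for repeated experiments disable standard errors and relax the outer
tolerance to 1e-8 — far below the resolution any of the assertions need.

## Known limitations

* Diagonal Omega only; no inter-occasion variability, no SAEM or
  importance-sampling estimators, no mixture models.
* Boluses are instantaneous; infusions of nonzero duration and oral
  absorption are out of scope.
* FOCE is an approximation: agreement with the quadrature oracle is
  asserted at the study's variability levels, not globally.
* The covariate-search ladder reproduces the *procedure* of the published
  Table-2 analysis; with synthetic data the numerical OFVs necessarily
  differ from the published ones (only the printed 1- vs 2-compartment
  dOFV is checked as in-paper arithmetic).
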