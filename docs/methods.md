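# Methods

This note documents the models, algorithms and numerical choices behind
`baclopk`, and what its synthetic-data tests do and do not demonstrate.

## Structural model and units

The disposition of orally dosed baclofen is described by a linear
two-compartment model with a first-order absorption depot and two parallel
first-order elimination routes from the central compartment: renal
(`kel_ur`, feeding a cumulative urine compartment) and all other processes
(`kel`, collected in a bookkeeping state so that mass balance is checkable).
Units are fixed package-wide: time in hours, amounts in mg/kg body weight,
volumes in L/kg, rate constants in 1/hr, plasma concentration in ng/mL.
The single mass-unit conversion (mg/L → ng/mL, factor 1000) lives in
`pk_model.MG_PER_L_TO_NG_PER_ML`.

Two evaluation paths exist and are tested against each other to 1e−8
relative: the canonical matrix-exponential solution (`solve_linear`, exact
for a linear system and immune to repeated eigenvalues) and a stiff-capable
LSODA integration (`solve_numeric`) kept as an independent oracle.  The
estimation and diagnostic layers use a vectorised tri-exponential closed
form (`predict_batch`); when Ka falls within 1e−7 of a disposition exponent
the batch path nudges Ka by one part in 1e6 to keep the coefficients
well-conditioned (the coincidence set has measure zero; `solve_linear`
covers it exactly).

Derived quantities follow the standard definitions: absorption half-life
ln2/Ka; hybrid exponents α ≥ β as roots of
s² − (K12+K21+K10)s + K21·K10 with K10 = Kel + Kel,ur; terminal exponent
the smallest of {α, β, Ka}, with flip-flop kinetics (Ka < β) flagged;
model clearance Vc·K10; urinary recovery fraction Kel,ur/K10.

A note on the published parameter set used as defaults: at those values the
model-implied urinary recovery is F·Kel,ur/K10 ≈ 16% of dose, while the
observed fraction excreted in urine is ~61–62%.  The two elimination labels
may be transposed in the source table.  The package implements the values
as printed and exposes `StructuralParams.swap_elimination_labels()` for
exploration; nothing is corrected silently.  Likewise the model-implied
terminal half-life (~1.7 hr) is shorter than the observed NCA t½
(3.4–4.1 hr); both discrepancies propagate into the synthetic studies,
which therefore test the *machinery* at the published operating point, not
the internal consistency of the published tables.

## Synthetic studies

The generator reproduces the study design: arms control/OY/AB with
n = 6/4/5 (configurable), one 1 mg/kg oral dose, plasma at 5, 15, 30 min
and 1, 2, 4, 8, 12, 24 hr, and one cumulative 0–24 hr urine fraction.
Individual parameters are log-normal, `p_i = median·exp(η)`,
`η ~ N(0, ω²)`, with the CV↔ω convention `ω² = ln(1+CV²)` used consistently
for simulation and reporting (the reported population value is the median).
F is bounded: draws outside (0, 1] are redrawn.  Observed plasma is
`y = Cp(1+ε_prop) + ε_add` with negative values truncated to zero and
flagged as censored; urine carries proportional error only and is stored as
a fraction of dose (no body-weight bookkeeping).

Residual-error magnitudes are not part of the published estimates.  The
defaults — proportional CV 15% plus additive SD 1 ng/mL for plasma,
proportional CV 10% for urine — represent typical bioanalytical error (the
assay's reported precision is ≤5.7%) plus biological noise, and are
configurable.  All randomness derives from one `SeedSequence` with one
child stream per subject, so datasets are bit-reproducible and estimates do
not depend on subject ordering.

What the generator does *not* emulate: assay quantification limits beyond
zero-truncation (LLOQ censoring is off by default), interval urine
collections, day-to-day variability of the 7-day pretreatment (its effect
enters only through the arm-specific Ka/F), or model misspecification —
passing recovery tests therefore show the estimator is consistent *under
the assumed model*, not that the model is right for real rats.

## Noncompartmental analysis

Cmax/Tmax are read directly from the observations (first occurrence on
ties).  λz comes from unweighted log-linear regression over an
automatically selected terminal window: all contiguous windows of ≥3
positive points ending at the last quantifiable observation and strictly
excluding Tmax are fitted; the best adjusted R² with negative slope wins,
with ties within 1e−4 resolved toward more points (commercial tools do not
publish their rule; this mirrors common practice).  AUC uses the
linear-up/log-down trapezoid by default (all-linear available);
AUC_inf = AUC_last + C_last/λz, with the extrapolated percentage reported
as a diagnostic.  CL/F = Dose/AUC_inf (reported in mL/min/kg) and
Vz/F = Dose/(λz·AUC_inf) (L/kg); unit conversions happen at the reporting
boundary.  Absolute bioavailability needs an intravenous reference:
F = 100·(AUC_oral/Dose_oral)/(AUC_iv/Dose_iv).  The package ships two
choices of the dose-normalised reference — one derived from a configured
population model, 1000/(Vc·K10), used throughout the synthetic pipelines;
and one back-derived from the published control-group summary
(100·2051.75/88.02 ≈ 2331 ng·hr/mL per mg/kg) for analyses of the printed
tables.  Failures (no fittable terminal window, too few observations) raise
a structured `NCAError` naming the subject; study-level drivers collect
rather than propagate them.

## Population estimation (importance-sampling EM)

Individual parameters are estimated on the log scale (rates, Vc) and logit
scale (F, keeping it in (0, 1)); the subject-level vector is
z = (ln K12, ln K21, ln Kel, ln Kel,ur, ln Vc, ln Ka, logit F) with a
diagonal between-subject covariance, arm-resolved means for the Ka and F
dimensions, and per-arm variances for both.

**E-step.**  For each subject the conditional density of z given the data
is importance-sampled.  The proposal adapts across iterations: a
full-covariance Gaussian moment-matched to the previous iteration's
weighted posterior (covariance inflated 1.5×), defensively mixed with 30%
population-prior samples, with weights computed against the exact mixture
density.  If the effective sample size still falls below 10 — which happens
when the conditional posterior is far tighter than the prior, e.g. with
small residual error — the E-step retries once from a Laplace proposal:
the conditional mode found by L-BFGS with the inverse numerical Hessian
(eigenvalues floored at 1e−2) as covariance.  Per-subject random streams
are keyed by (seed, sorted subject index, iteration).

**M-step.**  Population means update as the average conditional mean per
dimension (per arm for Ka/F); variances as the average conditional second
moment about the new mean, floored at 1e−6 (floor hits are logged).
Residual parameters maximise the expected log-likelihood over
posterior-resampled predictions — Nelder-Mead for the plasma pair
(additive SD, proportional CV), closed form for the urine CV.  Parameters
*without* between-subject variability cannot move through conditional
moments (their conditional distribution is a point mass), so they are
treated as fixed effects and updated by direct Nelder-Mead maximisation of
the resampled expected likelihood each iteration; this is what makes the
estimator reduce to maximum-likelihood curve fitting when all BSV is
switched off, a property the test suite checks against an independent
direct optimiser.

**Identifiability and the IV anchor.**  Oral data determine Ka, K12, K21,
K10, the amplitude F/Vc, and (with urine) F·Kel,ur/K10 — one direction
remains flat: F, Vc and the Kel/Kel,ur split can be scaled jointly without
changing any prediction.  Absolute bioavailability is simply not defined
without intravenous information, which is why oral-only analyses import an
IV AUC from a prior study.  `FitConfig.iv_auc_reference` supplies that
datum: a dose-normalised IV AUC entering each subject's likelihood as a
log-normal observation of 1000/(Vc_i·K10_i) with CV 5% (configurable).
Synthetic pipelines derive the reference from the generating population,
exactly as a real study inherits it from its predecessor.  Without an
anchor the fit still converges, but lands wherever the initial F places it
along the flat direction; the generic initial guess uses F = 85%
(literature-typical for oral baclofen).

**Convergence and reporting.**  -2·log marginal likelihood is estimated
each iteration from the importance weights and monitored (EM decreases it
in expectation; single-iteration Monte Carlo noise is expected).
Convergence is declared when consecutive 20-iteration window averages of
the population means and residual parameters change by <0.1% relative
(denominator floored at 0.1 so near-zero components are judged
absolutely); defaults are 1000 importance samples per subject and at most
300 iterations.  Variance components are monitored but do not gate
convergence: at this design several of them are so weakly identified that
they random-walk on an essentially flat likelihood — the published analysis
reports their relative standard errors at 340–700%, and simulate-and-refit
shows the same behaviour (e.g. the BSV of K12 and Kel trading off against
each other).  Final estimates are the trailing-window average, which damps
Monte Carlo jitter.  Empirical Bayes individual estimates are reported as
conditional means.  Relative standard errors come from the empirical
(outer-product) Fisher information over per-subject score vectors — scores
for means and variances via the Fisher identity from the conditional
moments, for residual parameters by central differences over the stored
importance samples — with a nonparametric bootstrap over subjects available
as the slower alternative.  Non-convergence returns a flagged result with
diagnostics, never an exception.

## Diagnostics

The VPC simulates replicate studies (default 500) from the model at the
design, forms 10/25/50/75/90 percentile bands of the *simulated
observations* at the nominal times (fixed-time design; no binning or
smoothing), overlays the data, and reports the fraction inside the 10–90
band (≈80% under the true model).  The NPDE (default 1000 replicates)
decorrelates each subject's simulated vectors by the Cholesky factor of
their simulated covariance (ridge-regularised with a warning if singular),
ranks the decorrelated observation among the decorrelated simulations with
the (count+½)/(K+1) correction, and maps through Φ⁻¹; zero-truncated
observations are censored and excluded.  Group comparisons report Welch
*and* pooled t-tests (the source analysis does not say which it used) plus
one-way ANOVA with Scheffé's post hoc test implemented from the contrast
form (pairwise statistic referred to (k−1)·F(k−1, N−k)); a
summary-statistic path accepts printed mean ± SD ± n tables.  Zero
within-group variance short-circuits to an exact-equality answer with a
note.

## Problem sizes in the shipped experiments

The simulate-and-refit recovery experiment uses 50 rats per arm — large
enough that the sampling error of the arm medians (e.g. ≈8% for Ka,control
with its 55.8% CV) sits inside the 15%/10-percentage-point recovery bands,
while one fit completes in a few minutes on a single core.  Diagnostic
calibration checks use 30 rats per arm (810 plasma observations), making
the binomial band around 80% VPC coverage and the N(0,1) NPDE tolerances
(±0.1 mean, 0.8–1.2 variance) meaningful.  The end-to-end `reproduce`
pipeline runs at the real study size (6/4/5), where the small-sample
uncertainty of the original experiment is plainly visible in the output
tables.

## Known limitations

- Single-dose, linear kinetics only; no multiple-dose superposition,
  saturable processes, or effect-site/CSF compartments.
- BSV of the disposition micro-constants is weakly identified at a 9-point
  design; estimates of ω for K12/Kel trade off and should be read with
  their (large) RSEs.
- The logit-normal law used for F in estimation differs slightly from the
  bounded log-normal used in simulation; at the few-percent CVs involved
  the difference is negligible, and the reported F "CV" uses the
  small-variance mapping CV ≈ ω_logit·(1−F).
- The likelihood ignores the zero-truncation of plasma observations
  (truncated points are rare at the default error magnitudes and carry the
  additive-error floor).
- Printed-table inconsistencies of the source study (urinary recovery,
  terminal half-life) are surfaced as diagnostics, not resolved.
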