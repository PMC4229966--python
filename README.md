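# baclopk

Population pharmacokinetics of oral baclofen under herbal pretreatment —
simulation, noncompartmental analysis, nonlinear mixed-effects estimation,
and model diagnostics for a rat drug–herb interaction study design.

## The problem

Baclofen, the reference treatment for spasticity, is often co-used with
traditional herbal medicines — notably Oyaksungisan (OY, a twelve-herb
formula) and *Achyranthes bidentata* radix extract (AB).  In rats pretreated
daily for a week with distilled water (control), OY, or AB, a single 1 mg/kg
oral baclofen dose shows a characteristic interaction signature: OY slows
the *rate* of absorption (lower Cmax, later Tmax, smaller Ka) without
changing its *extent* (AUC, urinary recovery, bioavailability).  The raw
animal data behind that finding are not publicly deposited, so this package
implements the full analysis chain as reusable, testable code and pairs it
with a synthetic-study generator that emulates the design: three arms
(n = 6/4/5), plasma sampled at 5, 15, 30 min and 1, 2, 4, 8, 12, 24 hr, and
a cumulative 0–24 hr urine collection.

## The model

A linear two-compartment model with first-order absorption and a cumulative
urine compartment (amounts per kg body weight):

    dXgut/dt = −Ka·Xgut                     Xgut(0) = F·Dose
    dX1/dt   = Ka·Xgut − (K12 + Kel + Kel,ur)·X1 + K21·X2
    dX2/dt   = K12·X1 − K21·X2
    dXu/dt   = Kel,ur·X1
    Cp       = X1 / Vc

Ka and F are resolved per pretreatment arm (Ka,control / Ka,OY / Ka,AB and
F,control / F,OY / F,AB); the disposition constants K12, K21, Kel, Kel,ur
and Vc are shared.  Between-subject variability is log-normal per parameter
(`ω² = ln(1+CV²)`); plasma observations carry combined additive +
proportional error, urine proportional error.

The population model is estimated by an importance-sampling Monte Carlo
parametric EM (MC-PEM) algorithm: per-subject conditional distributions of
the random effects are approximated by adaptively-proposed importance
samples (with a conditional-mode Laplace fallback), population medians and
variances are updated from the weighted conditional moments, and residual
error by direct likelihood maximisation.  Parameters declared without
between-subject variability are updated as fixed effects by direct
maximisation, so the estimator reduces to maximum-likelihood curve fitting
in the no-BSV limit.  Because oral data alone identify only F/Vc and
F·Kel,ur/(Kel+Kel,ur), absolute bioavailability is anchored — as in any
oral-only analysis — by a dose-normalised intravenous AUC reference supplied
as an external datum (see `docs/methods.md`).

Alongside the population route, the package provides classical
noncompartmental analysis (Cmax/Tmax, λz and t½ = ln2/λz, linear-up/log-down
AUC to the last observation and to infinity, CL/F, Vz/F, Fe,urine, and
F = 100·(AUC_oral/Dose_oral)/(AUC_iv/Dose_iv)), visual predictive checks,
normalized prediction distribution errors, and the conventional statistics
(Welch/pooled t-tests; one-way ANOVA with Scheffé's post hoc test, also from
printed mean ± SD summaries).

## Worked example

```python
import baclopk as b
from baclopk.synthetic_data import iv_auc_reference

pop = b.default_population()                 # published estimates as truth
design = b.default_design(seed=42)           # n = 6/4/5, real schedule
records = b.simulate_study(pop, design)

results, failures = b.run_study_nca(records, iv_auc_reference(pop))
print(b.study_table(results).loc[["cmax", "tmax", "auc_inf", "f_pct"]])

fit = b.fit_mcpem(records, b.FitConfig(
    initial=b.default_initial_guess(),
    iv_auc_reference=iv_auc_reference(pop), seed=0,
))
print({a: round(fit.population.ka[a], 3) for a in fit.population.arms})
```

The same chain runs end to end from the command line:

```bash
baclopk reproduce --config examples/config.yaml --out-dir results/repro
```

which simulates the study, writes the NCA summary and the population-
estimate table, per-group VPC plots, NPDE and statistics reports, and a
derived-quantities block.  With the shipped config (seed 1234) it prints:

```json
{
  "absorption_half_life_hr": {"control": 0.50, "OY": 1.50, "AB": 0.44},
  "bioavailability": {
    "control": {"nca_pct": 84.6, "model_pct": 87.5, "rel_error_pct": 3.36},
    "OY":      {"nca_pct": 81.8, "model_pct": 82.8, "rel_error_pct": 1.25},
    "AB":      {"nca_pct": 91.1, "model_pct": 93.9, "rel_error_pct": 3.07}
  }
}
VPC 10–90 coverage: 0.778; NPDE mean 0.027, variance 1.030
```

Reading: even at the study's small size (15 rats), the refitted absorption
half-lives separate the OY arm (~1.5 hr) from control (~0.50 hr) — the
slower-absorption signature — while NCA and model bioavailability agree
within ~3%, and the diagnostics sit at their nominal values (≈80% band
coverage; NPDE ≈ N(0,1)).  The generating values were ln2/Ka = 0.54 hr
(control) and 1.33 hr (OY).

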