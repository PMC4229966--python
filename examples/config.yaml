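# Default run configuration: the published rat baclofen population model as
# generating values, at the real study design (control n=6, OY n=4, AB n=5).
# Any key omitted here falls back to the package default; unknown keys are
# rejected.  See `baclopk.io.default_config()` for the full schema.

seed: 1234
outdir: results

design:
  groups:
    - {label: control, n: 6}
    - {label: OY, n: 4}
    - {label: AB, n: 5}
  dose: {amount: 1.0, time: 0.0, route: oral}
  plasma_times: [0.0833333333, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0]
  urine_interval: 24.0

population:
  medians: {k12: 0.803, k21: 0.965, kel: 0.839, kel_ur: 0.190, vc: 0.448}
  ka: {control: 1.28, OY: 0.523, AB: 1.74}
  f: {control: 0.867, OY: 0.788, AB: 0.895}
  bsv:
    k12: 0.102
    k21: 0.045
    kel: 0.185
    kel_ur: 0.066
    vc: 0.013
    ka.control: 0.558
    ka.OY: 0.161
    ka.AB: 0.122
    f.control: 0.072
    f.OY: 0.038
    f.AB: 0.011
  residual: {add_sd: 1.0, prop_cv: 0.15, urine_cv: 0.10}

nca:
  # null: derive the dose-normalised IV AUC reference from the population
  # block (1000 / (Vc * K10)); set a number to override.
  iv_auc_reference: null
  method: lin-up-log-down

fit:
  initial: generic      # or "population" to start at the population block
  n_importance: 1000
  max_iter: 300
  tol: 1.0e-3
  use_urine: true

diagnostics:
  vpc_nsim: 500
  npde_nsim: 1000
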