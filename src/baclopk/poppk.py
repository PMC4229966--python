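"""Population (nonlinear mixed-effects) estimation by importance-sampling EM.

The estimator is a Monte Carlo parametric expectation-maximisation (MC-PEM)
scheme for the two-compartment oral model: individual parameters are
log-normally distributed around population medians (bioavailability on the
logit scale, keeping F in (0, 1)), with the absorption rate constant Ka and
bioavailability F resolved per pretreatment arm and the systemic disposition
parameters shared across arms.

E-step: for each subject, the conditional distribution of the individual
random effects given the data is approximated by importance sampling.  The
proposal is adapted across iterations — a Gaussian moment-matched to the
previous iteration's weighted posterior, defensively mixed with the
population prior — so weights stay well conditioned without per-subject mode
searches.  Weighted first and second moments give the conditional means and
variances.

M-step: population medians are updated as the average conditional mean per
dimension (per arm for Ka/F), between-subject variances as the average
conditional second moment about the new mean, and residual-error parameters
by direct likelihood maximisation over posterior-resampled predictions.

Monte Carlo noise is handled by averaging the parameter trajectory over a
trailing window; convergence is declared when successive window averages
change by less than a relative tolerance.  Uncertainties (relative standard
errors) come from the empirical Fisher information built from per-subject
score vectors (the bootstrap over subjects is available as a slower
alternative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp

from .errors import ConfigurationError, IdentifiabilityWarning
from .pk_model import StructuralParams, predict, predict_batch
from .synthetic_data import (
    PopulationModel,
    ResidualModel,
    SubjectRecord,
    cv_from_omega,
    omega_from_cv,
)

SHARED = ("k12", "k21", "kel", "kel_ur", "vc")
_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Settings for :func:`fit_mcpem`.

    ``initial`` supplies both the starting values and the model structure
    (which arms exist).  ``bsv_params`` restricts which parameters carry
    between-subject variability (names like ``"kel"`` or ``"ka.OY"``;
    ``"ka"`` covers every arm); omitted dimensions are frozen at a
    negligible floor.  ``fix_params`` freezes population means at their
    initial values.

    ``iv_auc_reference`` optionally supplies a dose-normalised intravenous
    AUC (ng*hr/mL per mg/kg) as an external datum with log-normal
    uncertainty ``iv_auc_cv``.  Oral data alone identify only the ratios
    F/Vc and F*Kel,ur/(Kel+Kel,ur); the IV reference pins Vc*(Kel+Kel,ur)
    and thereby separates F from Vc, mirroring how oral-only analyses
    anchor absolute bioavailability against a prior IV study.
    """

    initial: PopulationModel
    n_importance: int = 1000
    max_iter: int = 300
    tol: float = 1e-3
    seed: int = 0
    bsv_params: frozenset[str] | None = None
    fix_params: frozenset[str] = frozenset()
    estimate_bsv: bool = True
    estimate_residual: bool = True
    use_urine: bool = True
    iv_auc_reference: float | None = None
    iv_auc_cv: float = 0.05
    omega_floor: float = 1e-6
    defensive: float = 0.3
    proposal_inflation: float = 1.5
    n_resample: int = 100
    min_iter: int = 60
    avg_window: int = 20
    compute_rse: bool = True

    def __post_init__(self) -> None:
        if self.n_importance < 100:
            raise ConfigurationError("n_importance must be >= 100")
        if self.tol <= 0:
            raise ConfigurationError("tol must be > 0")
        if not (0 <= self.defensive < 1):
            raise ConfigurationError("defensive mixture weight must be in [0, 1)")


@dataclass
class FitResult:
    """Population estimates with uncertainty and per-subject summaries."""

    population: PopulationModel
    rse: dict[str, float]                 # population means, RSE %
    bsv_cv: dict[str, float]              # BSV as CV %
    bsv_rse: dict[str, float]             # RSE % of the CVs
    residual_rse: dict[str, float]
    individual: pd.DataFrame              # conditional-mean individual params
    objective_trace: list[float]          # -2 * log marginal likelihood
    converged: bool
    n_iter: int
    ess_summary: dict[str, float]
    messages: list[str] = field(default_factory=list)
    config_hash: str | None = None

    @property
    def objective(self) -> float:
        return self.objective_trace[-1] if self.objective_trace else float("nan")

    def to_dict(self) -> dict:
        pop = self.population
        return {
            "population": {
                "medians": dict(pop.medians),
                "ka": dict(pop.ka),
                "f": dict(pop.f),
                "bsv": dict(pop.bsv),
                "residual": {
                    "add_sd": pop.residual.add_sd,
                    "prop_cv": pop.residual.prop_cv,
                    "urine_cv": pop.residual.urine_cv,
                },
            },
            "rse_pct": self.rse,
            "bsv_cv_pct": self.bsv_cv,
            "bsv_rse_pct": self.bsv_rse,
            "residual_rse_pct": self.residual_rse,
            "individual": self.individual.to_dict(orient="records"),
            "objective_trace": self.objective_trace,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "ess_summary": self.ess_summary,
            "messages": self.messages,
            "config_hash": self.config_hash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        p = d["population"]
        pop = PopulationModel(
            medians=p["medians"], ka=p["ka"], f=p["f"], bsv=p["bsv"],
            residual=ResidualModel(**p["residual"]),
        )
        return cls(
            population=pop, rse=d["rse_pct"], bsv_cv=d["bsv_cv_pct"],
            bsv_rse=d["bsv_rse_pct"], residual_rse=d["residual_rse_pct"],
            individual=pd.DataFrame(d["individual"]),
            objective_trace=d["objective_trace"], converged=d["converged"],
            n_iter=d["n_iter"], ess_summary=d["ess_summary"],
            messages=d.get("messages", []), config_hash=d.get("config_hash"),
        )


def default_initial_guess(arms: Sequence[str] = ("control", "OY", "AB")) -> PopulationModel:
    """Generic starting values for the estimator.

    Deliberately uninformative about any particular dataset: unit exchange
    and absorption rates, moderate clearance split evenly between renal and
    non-renal routes, and an oral bioavailability of 85% (literature-typical
    for baclofen).  BSV starts wide (30% CV) so early EM iterations can move
    the population means freely.
    """
    return PopulationModel(
        medians={"k12": 1.0, "k21": 1.0, "kel": 0.5, "kel_ur": 0.5, "vc": 0.6},
        ka={a: 1.0 for a in arms},
        f={a: 0.85 for a in arms},
        bsv={**{k: 0.30 for k in SHARED},
             **{f"ka.{a}": 0.30 for a in arms},
             **{f"f.{a}": 0.30 for a in arms}},
        residual=ResidualModel(add_sd=1.0, prop_cv=0.2, urine_cv=0.15),
    )


# ---------------------------------------------------------------------------
# internal state
# ---------------------------------------------------------------------------

@dataclass
class _PopState:
    """Transformed-scale population state: log medians (logit for F)."""

    arms: list[str]
    mu: np.ndarray        # (5,) log of shared disposition params
    mu_ka: np.ndarray     # (n_arms,)
    mu_f: np.ndarray      # (n_arms,) logit scale
    om2: np.ndarray       # (5,)
    om2_ka: np.ndarray
    om2_f: np.ndarray
    add_sd: float
    prop_cv: float
    urine_cv: float
    iv_ref: float | None = None
    iv_cv: float = 0.05

    def copy(self) -> "_PopState":
        return _PopState(
            list(self.arms), self.mu.copy(), self.mu_ka.copy(), self.mu_f.copy(),
            self.om2.copy(), self.om2_ka.copy(), self.om2_f.copy(),
            self.add_sd, self.prop_cv, self.urine_cv, self.iv_ref, self.iv_cv,
        )

    def subject_prior(self, arm_idx: int) -> tuple[np.ndarray, np.ndarray]:
        mu = np.concatenate([self.mu, [self.mu_ka[arm_idx]], [self.mu_f[arm_idx]]])
        om2 = np.concatenate([self.om2, [self.om2_ka[arm_idx]], [self.om2_f[arm_idx]]])
        return mu, np.sqrt(om2)


def _state_from_population(pop: PopulationModel, floor: float) -> _PopState:
    arms = list(pop.ka)
    mu = np.array([np.log(pop.medians[k]) for k in SHARED])
    mu_ka = np.array([np.log(pop.ka[a]) for a in arms])
    mu_f = np.array([logit(pop.f[a]) for a in arms])
    om2 = np.array([max(omega_from_cv(pop.bsv_cv(k)) ** 2, floor) for k in SHARED])
    om2_ka = np.array([max(omega_from_cv(pop.bsv_cv("ka", a)) ** 2, floor) for a in arms])
    # logit-scale spread approximating the stated CV: sd(logit F) ~ CV / (1 - F),
    # capped at 1 (the small-CV mapping degenerates for wide F distributions)
    om2_f = np.array([
        min(max((pop.bsv_cv("f", a) / max(1.0 - pop.f[a], 1e-3)) ** 2, floor), 1.0)
        for a in arms
    ])
    r = pop.residual
    return _PopState(arms, mu, mu_ka, mu_f, om2, om2_ka, om2_f,
                     r.add_sd, r.prop_cv, r.urine_cv)


def _population_from_state(st: _PopState) -> PopulationModel:
    medians = {k: float(np.exp(st.mu[i])) for i, k in enumerate(SHARED)}
    ka = {a: float(np.exp(st.mu_ka[i])) for i, a in enumerate(st.arms)}
    fvals = {a: float(expit(st.mu_f[i])) for i, a in enumerate(st.arms)}
    bsv = {k: cv_from_omega(np.sqrt(st.om2[i])) for i, k in enumerate(SHARED)}
    for i, a in enumerate(st.arms):
        bsv[f"ka.{a}"] = cv_from_omega(np.sqrt(st.om2_ka[i]))
        bsv[f"f.{a}"] = float(np.sqrt(st.om2_f[i]) * (1.0 - fvals[a]))
    return PopulationModel(
        medians=medians, ka=ka, f=fvals, bsv=bsv,
        residual=ResidualModel(st.add_sd, st.prop_cv, st.urine_cv),
    )


@dataclass
class _Subj:
    id: str
    group: str
    arm_idx: int
    times: np.ndarray
    y: np.ndarray
    urine_frac: float | None
    urine_time: float
    dose: float


def _prepare_subjects(dataset: Sequence[SubjectRecord], arms: list[str],
                      use_urine: bool) -> list[_Subj]:
    subjects = []
    for rec in sorted(dataset, key=lambda r: r.id):
        if rec.group not in arms:
            raise ConfigurationError(
                f"subject {rec.id!r} group {rec.group!r} has no declared Ka/F arm"
            )
        subjects.append(_Subj(
            id=rec.id, group=rec.group, arm_idx=arms.index(rec.group),
            times=np.asarray(rec.plasma_times, dtype=float),
            y=np.asarray(rec.plasma_conc, dtype=float),
            urine_frac=(rec.urine_fraction if use_urine else None),
            urine_time=float(rec.urine_time or 24.0),
            dose=rec.dose.amount,
        ))
    return subjects


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _check_residual(res: ResidualModel, need_urine: bool) -> None:
    if res.add_sd <= 0 and res.prop_cv <= 0:
        raise ConfigurationError("plasma residual variance must be positive")
    if need_urine and res.urine_cv <= 0:
        raise ConfigurationError("urine residual CV must be positive when urine data enter the likelihood")


def individual_loglik(
    params: StructuralParams,
    subject: SubjectRecord,
    residual: ResidualModel,
    use_urine: bool = True,
) -> float:
    """Gaussian log-likelihood of one subject's observations.

    Plasma points have variance ``add_sd^2 + (prop_cv * pred)^2``; the
    cumulative urine fraction (if present and ``use_urine``) has proportional
    variance ``(urine_cv * pred)^2``.
    """
    has_urine = use_urine and subject.urine_fraction is not None
    _check_residual(residual, has_urine)
    if subject.plasma_times.size < 1:
        raise ConfigurationError("subject has no observations")
    cp, _ = predict(params, subject.dose, subject.plasma_times)
    v = residual.add_sd ** 2 + (residual.prop_cv * cp) ** 2
    if np.any(v <= 0):
        raise ConfigurationError("zero total variance at an observation")
    ll = -0.5 * np.sum(_LOG2PI + np.log(v) + (subject.plasma_conc - cp) ** 2 / v)
    if has_urine:
        _, xu = predict(params, subject.dose, np.array([subject.urine_time or 24.0]))
        pu = max(float(xu[-1]) / subject.dose.amount, 1e-10)
        vu = (residual.urine_cv * pu) ** 2
        ll += -0.5 * (_LOG2PI + np.log(vu) + (subject.urine_fraction - pu) ** 2 / vu)
    return float(ll)


_TRANSFORMED_NAMES = ("k12", "k21", "kel", "kel_ur", "vc", "ka", "f")


def _loglik_from_z(z, subj_times, y, dose, urine_time, urine_frac, res: ResidualModel):
    """Log-likelihood as a holomorphic function of the transformed parameter
    vector z = (log k12, log k21, log kel, log kel_ur, log vc, log ka, logit f);
    supports complex-step differentiation."""
    k12, k21, kel, kel_ur, vc, ka = (np.exp(z[i]) for i in (0, 1, 2, 3, 4, 5))
    f = 1.0 / (1.0 + np.exp(-z[6]))
    times = subj_times if urine_frac is None else np.concatenate([subj_times, [urine_time]])
    cp, xu = predict_batch(
        np.array([ka]), np.array([k12]), np.array([k21]), np.array([kel]),
        np.array([kel_ur]), np.array([vc]), np.array([f]), dose, times,
    )
    nt = subj_times.size
    cpp = cp[0, :nt]
    v = res.add_sd ** 2 + (res.prop_cv * cpp) ** 2
    ll = -0.5 * np.sum(_LOG2PI + np.log(v) + (y - cpp) ** 2 / v)
    if urine_frac is not None:
        pu = xu[0, -1] / dose
        vu = (res.urine_cv * pu) ** 2
        ll = ll - 0.5 * (_LOG2PI + np.log(vu) + (urine_frac - pu) ** 2 / vu)
    return ll


def individual_loglik_grad(
    params: StructuralParams,
    subject: SubjectRecord,
    residual: ResidualModel,
    use_urine: bool = True,
) -> dict[str, float]:
    """Exact gradient of :func:`individual_loglik` with respect to the
    transformed parameters (log scale; logit for F), by complex-step
    differentiation of the closed-form solution."""
    has_urine = use_urine and subject.urine_fraction is not None
    _check_residual(residual, has_urine)
    z0 = np.array([
        np.log(params.k12) if params.k12 > 0 else -30.0,
        np.log(params.k21) if params.k21 > 0 else -30.0,
        np.log(params.kel) if params.kel > 0 else -30.0,
        np.log(params.kel_ur) if params.kel_ur > 0 else -30.0,
        np.log(params.vc),
        np.log(params.ka),
        logit(params.f) if params.f < 1 else 30.0,
    ], dtype=complex)
    h = 1e-20
    grad = {}
    for i, name in enumerate(_TRANSFORMED_NAMES):
        z = z0.copy()
        z[i] += 1j * h
        val = _loglik_from_z(
            z, subject.plasma_times, subject.plasma_conc, subject.dose.amount,
            subject.urine_time or 24.0,
            subject.urine_fraction if has_urine else None, residual,
        )
        grad[name] = float(np.imag(val) / h)
    return grad


def _batch_loglik(
    z: np.ndarray, subj: _Subj, st: _PopState
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised log-likelihood for a matrix of transformed parameter draws.

    Returns ``(ll_data, ll_anchor, plasma predictions, urine predictions)``
    where ``ll_anchor`` is the optional IV-reference term (zero when no
    reference is configured); it is kept separate because it does not depend
    on the residual-error parameters."""
    # clip transformed draws: beyond +-15 log units the posterior mass is
    # nil and underflowing rates would produce 0/0 in the closed form
    z = np.clip(z, -15.0, 15.0)
    ka = np.exp(z[:, 5])
    f = expit(z[:, 6])
    times = subj.times if subj.urine_frac is None else np.concatenate([subj.times, [subj.urine_time]])
    cp, xu = predict_batch(
        ka, np.exp(z[:, 0]), np.exp(z[:, 1]), np.exp(z[:, 2]),
        np.exp(z[:, 3]), np.exp(z[:, 4]), f, subj.dose, times,
    )
    nt = subj.times.size
    cpp = cp[:, :nt]
    v = st.add_sd ** 2 + (st.prop_cv * cpp) ** 2
    v = np.maximum(v, 1e-12)
    ll = -0.5 * np.sum(_LOG2PI + np.log(v) + (subj.y[np.newaxis, :] - cpp) ** 2 / v, axis=1)
    pu = np.zeros(z.shape[0])
    if subj.urine_frac is not None:
        pu = np.maximum(xu[:, -1] / subj.dose, 1e-10)
        vu = np.maximum((st.urine_cv * pu) ** 2, 1e-14)
        ll = ll - 0.5 * (_LOG2PI + np.log(vu) + (subj.urine_frac - pu) ** 2 / vu)
    ll_anchor = np.zeros(z.shape[0])
    if st.iv_ref is not None:
        k10 = np.exp(z[:, 2]) + np.exp(z[:, 3])
        auc_iv = 1000.0 / (np.exp(z[:, 4]) * k10)  # ng*hr/mL per mg/kg
        s2 = st.iv_cv ** 2
        ll_anchor = -0.5 * (np.log(2.0 * np.pi * s2) + np.log(auc_iv / st.iv_ref) ** 2 / s2)
    return ll, ll_anchor, cpp, pu


def _diag_normal_logpdf(z: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return -0.5 * np.sum(_LOG2PI + 2.0 * np.log(sd) + ((z - mu) / sd) ** 2, axis=1)


def _systematic_resample(w: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(w), positions).clip(max=w.size - 1)


def _neg_log_posterior(z: np.ndarray, subj: _Subj, st: _PopState,
                       mu_i: np.ndarray, sd_i: np.ndarray) -> float:
    zz = z[np.newaxis, :]
    ll, ll_anchor, _, _ = _batch_loglik(zz, subj, st)
    lp = _diag_normal_logpdf(zz, mu_i, sd_i)
    return -float(ll[0] + ll_anchor[0] + lp[0])


def _safe_cholesky(cov: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    cov = 0.5 * (cov + cov.T)
    for ridge in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            return np.linalg.cholesky(cov + ridge * np.eye(cov.shape[0]))
        except np.linalg.LinAlgError:
            continue
    return np.diag(np.sqrt(np.maximum(np.diag(cov), floor)))


def _mvn_logpdf_chol(z: np.ndarray, m: np.ndarray, chol: np.ndarray) -> np.ndarray:
    u = solve_triangular(chol, (z - m).T, lower=True)
    return -0.5 * (7 * _LOG2PI + np.sum(u * u, axis=0)) - np.sum(np.log(np.diag(chol)))


def _laplace_proposal(subj: _Subj, st: _PopState, mu_i: np.ndarray,
                      sd_i: np.ndarray, z0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Conditional-mode (Laplace) proposal for a subject whose posterior is
    far tighter than the population prior: mode of the conditional density
    with the inverse full Hessian (numeric) as proposal covariance."""
    opt = minimize(
        _neg_log_posterior, z0, args=(subj, st, mu_i, sd_i),
        method="L-BFGS-B", options={"maxiter": 120},
    )
    mode = opt.x
    h = 1e-3
    hess = np.empty((7, 7))
    f0 = _neg_log_posterior(mode, subj, st, mu_i, sd_i)
    fp = np.empty(7)
    fm = np.empty(7)
    for d in range(7):
        zp = mode.copy(); zp[d] += h
        zm = mode.copy(); zm[d] -= h
        fp[d] = _neg_log_posterior(zp, subj, st, mu_i, sd_i)
        fm[d] = _neg_log_posterior(zm, subj, st, mu_i, sd_i)
        hess[d, d] = (fp[d] + fm[d] - 2.0 * f0) / h ** 2
    for a in range(7):
        for b in range(a + 1, 7):
            zpp = mode.copy(); zpp[a] += h; zpp[b] += h
            fab = _neg_log_posterior(zpp, subj, st, mu_i, sd_i)
            hess[a, b] = hess[b, a] = (
                fab - fp[a] - fp[b] + f0
            ) / h ** 2
    # clip deficient curvature so no proposal direction is wider than ~10 sd
    w, v = np.linalg.eigh(0.5 * (hess + hess.T))
    w = np.maximum(w, 1e-2)
    cov = (v / w) @ v.T
    return mode, _safe_cholesky(cov * 1.5 ** 2)


def _estep_subject(
    subj: _Subj,
    st: _PopState,
    nsamp: int,
    rng: np.random.Generator,
    proposal: tuple[np.ndarray, np.ndarray] | None,
    defensive: float,
    n_resample: int,
    store_all: bool = False,
    inflation: float = 1.5,
    ess_floor: float = 10.0,
) -> dict:
    """Importance-sampled conditional moments for one subject.

    A degenerate weight distribution (effective sample size below
    ``ess_floor``) triggers one retry from a Laplace proposal centred at the
    conditional mode.
    """
    mu_i, sd_i = st.subject_prior(subj.arm_idx)
    for attempt in range(2):
        if proposal is None or defensive >= 1.0:
            z = mu_i + sd_i * rng.standard_normal((nsamp, 7))
            logq = _diag_normal_logpdf(z, mu_i, sd_i)
        else:
            m_p, chol_p = proposal
            n_prop = int(round(nsamp * (1.0 - defensive)))
            z_prop = m_p + rng.standard_normal((n_prop, 7)) @ chol_p.T
            z_prior = mu_i + sd_i * rng.standard_normal((nsamp - n_prop, 7))
            z = np.vstack([z_prop, z_prior])
            lq_prop = _mvn_logpdf_chol(z, m_p, chol_p)
            lq_prior = _diag_normal_logpdf(z, mu_i, sd_i)
            logq = np.logaddexp(np.log(1.0 - defensive) + lq_prop,
                                np.log(defensive) + lq_prior)
        logprior = _diag_normal_logpdf(z, mu_i, sd_i)
        ll, ll_anchor, cpp, pu = _batch_loglik(z, subj, st)
        lw = logprior + ll + ll_anchor - logq
        lw[~np.isfinite(lw)] = -np.inf
        lw_max = np.max(lw)
        if not np.isfinite(lw_max):  # pathological state: weight uniformly
            lw = np.zeros_like(lw)
            lw_max = 0.0
        w = np.exp(lw - lw_max)
        w = w / w.sum()
        ess = 1.0 / np.sum(w ** 2)
        if ess >= ess_floor or attempt == 1:
            break
        z_best = z[int(np.argmax(lw))]
        proposal = _laplace_proposal(subj, st, mu_i, sd_i, z_best)
    m = w @ z
    dev = z - m
    var = w @ dev ** 2
    marg = float(logsumexp(lw) - np.log(z.shape[0]))
    idx = _systematic_resample(w, n_resample, rng)
    if ess >= ess_floor:
        cov = (dev * w[:, np.newaxis]).T @ dev
        cov += np.diag(np.maximum(var, 1e-10)) * 1e-3  # guard exact singularity
        prop_next = (m, _safe_cholesky(cov * inflation ** 2))
    else:
        prop_next = proposal  # keep the Laplace proposal for the next pass
    out = {
        "m": m, "var": var, "ess": float(ess), "marg": marg,
        "proposal_next": prop_next, "z_res": z[idx],
        "cp_res": cpp[idx], "pu_res": pu[idx] if subj.urine_frac is not None else None,
    }
    if store_all:
        out["z"] = z
        out["cp"] = cpp
        out["pu"] = pu
        out["lw_base"] = logprior + ll_anchor - logq
    return out


# ---------------------------------------------------------------------------
# M-step helpers
# ---------------------------------------------------------------------------

def _update_residual(
    st: _PopState,
    subjects: Sequence[_Subj],
    estats: Sequence[dict],
) -> tuple[float, float, float]:
    ys, ps = [], []
    yu, pu = [], []
    for subj, e in zip(subjects, estats):
        nres = e["cp_res"].shape[0]
        ys.append(np.broadcast_to(subj.y, (nres, subj.y.size)).ravel())
        ps.append(e["cp_res"].ravel())
        if subj.urine_frac is not None and e["pu_res"] is not None:
            yu.append(np.full(nres, subj.urine_frac))
            pu.append(e["pu_res"])
    y = np.concatenate(ys)
    p = np.concatenate(ps)

    def nll(x):
        a = np.exp(x[0])
        b = np.exp(x[1])
        v = a * a + (b * p) ** 2
        return 0.5 * np.sum(np.log(v) + (y - p) ** 2 / v)

    x0 = np.log([max(st.add_sd, 1e-3), max(st.prop_cv, 1e-3)])
    opt = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-3, "maxiter": 200})
    add_sd, prop_cv = np.exp(opt.x)
    urine_cv = st.urine_cv
    if yu:
        yu_all = np.concatenate(yu)
        pu_all = np.maximum(np.concatenate(pu), 1e-10)
        urine_cv = float(np.sqrt(np.mean((yu_all / pu_all - 1.0) ** 2)))
        urine_cv = max(urine_cv, 1e-4)
    return float(max(add_sd, 1e-6)), float(max(prop_cv, 1e-6)), urine_cv


def _update_fixed_effects(
    st: _PopState,
    subjects: Sequence[_Subj],
    estats: Sequence[dict],
    shared_dims: list[int],
    ka_arms: list[int],
    f_arms: list[int],
) -> None:
    """Direct M-step maximisation for parameters carrying no between-subject
    variability.

    Dimensions whose variance sits at the floor behave as fixed effects: the
    conditional distribution of their individual values is a point mass at
    the population value, so the moment update cannot move them.  They are
    instead updated by maximising the importance-resampled expected
    log-likelihood (random-effect dimensions held at their resampled draws),
    which is how EM handles parameters outside the random-effects model.
    Updates ``st`` in place.
    """
    n_sh = len(shared_dims)
    x0 = np.concatenate([
        st.mu[shared_dims],
        st.mu_ka[ka_arms],
        st.mu_f[f_arms],
    ])
    if x0.size == 0:
        return

    def neg_expected_ll(x: np.ndarray) -> float:
        total = 0.0
        for subj, e in zip(subjects, estats):
            zc = e["z_res"].copy()
            zc[:, shared_dims] = x[:n_sh]
            for j, a in enumerate(ka_arms):
                if subj.arm_idx == a:
                    zc[:, 5] = x[n_sh + j]
            for j, a in enumerate(f_arms):
                if subj.arm_idx == a:
                    zc[:, 6] = x[n_sh + len(ka_arms) + j]
            ll, ll_anchor, _, _ = _batch_loglik(zc, subj, st)
            total += float(np.mean(ll + ll_anchor))
        return -total

    opt = minimize(
        neg_expected_ll, x0, method="Nelder-Mead",
        options={"maxiter": 40 * max(x0.size, 2), "xatol": 1e-6, "fatol": 1e-8},
    )
    x = opt.x
    st.mu[shared_dims] = x[:n_sh]
    for j, a in enumerate(ka_arms):
        st.mu_ka[a] = x[n_sh + j]
    for j, a in enumerate(f_arms):
        st.mu_f[a] = x[n_sh + len(ka_arms) + j]


def _nat_vector(st: _PopState) -> np.ndarray:
    return np.concatenate([
        np.exp(st.mu), np.exp(st.mu_ka), expit(st.mu_f),
        np.sqrt(st.om2), np.sqrt(st.om2_ka), np.sqrt(st.om2_f),
        [st.add_sd, st.prop_cv, st.urine_cv],
    ])


def _state_from_nat(vec: np.ndarray, template: _PopState) -> _PopState:
    na = len(template.arms)
    st = template.copy()
    i = 0
    st.mu = np.log(vec[i:i + 5]); i += 5
    st.mu_ka = np.log(vec[i:i + na]); i += na
    st.mu_f = logit(np.clip(vec[i:i + na], 1e-6, 1 - 1e-6)); i += na
    st.om2 = vec[i:i + 5] ** 2; i += 5
    st.om2_ka = vec[i:i + na] ** 2; i += na
    st.om2_f = vec[i:i + na] ** 2; i += na
    st.add_sd, st.prop_cv, st.urine_cv = vec[i], vec[i + 1], vec[i + 2]
    return st


def _bsv_active(cfg: FitConfig, arms: list[str]) -> dict[str, bool]:
    if cfg.bsv_params is None:
        names = set(SHARED) | {f"ka.{a}" for a in arms} | {f"f.{a}" for a in arms}
    else:
        names = set()
        for item in cfg.bsv_params:
            if item in ("ka", "f"):
                names |= {f"{item}.{a}" for a in arms}
            else:
                names.add(item)
    out = {k: (k in names) for k in SHARED}
    for a in arms:
        out[f"ka.{a}"] = f"ka.{a}" in names
        out[f"f.{a}"] = f"f.{a}" in names
    return out


# ---------------------------------------------------------------------------
# main fit
# ---------------------------------------------------------------------------

def fit_mcpem(dataset: Sequence[SubjectRecord], config: FitConfig) -> FitResult:
    """Fit the population model to a study dataset by importance-sampling EM.

    Subjects are processed in sorted-id order with per-subject random
    streams, so estimates do not depend on the input ordering.  Returns a
    :class:`FitResult`; non-convergence within ``max_iter`` is reported via
    ``converged=False`` plus a diagnostic message, not an exception.
    """
    if len(dataset) < 3:
        raise ConfigurationError("need at least 3 subjects for a population fit")
    st = _state_from_population(config.initial, config.omega_floor)
    st.iv_ref = config.iv_auc_reference
    st.iv_cv = config.iv_auc_cv
    arms = st.arms
    subjects = _prepare_subjects(dataset, arms, config.use_urine)
    need_urine = any(s.urine_frac is not None for s in subjects)
    _check_residual(config.initial.residual, need_urine)
    arm_members: dict[int, list[int]] = {i: [] for i in range(len(arms))}
    for i, s in enumerate(subjects):
        arm_members[s.arm_idx].append(i)
    active_arms = [a for a in range(len(arms)) if arm_members[a]]

    bsv_on = _bsv_active(config, arms)
    for d, k in enumerate(SHARED):
        if not bsv_on[k]:
            st.om2[d] = config.omega_floor
    for a, arm in enumerate(arms):
        if not bsv_on[f"ka.{arm}"]:
            st.om2_ka[a] = config.omega_floor
        if not bsv_on[f"f.{arm}"]:
            st.om2_f[a] = config.omega_floor

    # dimensions without BSV are fixed effects: moment updates cannot move
    # them, so they get a direct likelihood-maximisation update instead
    fe_shared = [d for d, k in enumerate(SHARED)
                 if not bsv_on[k] and k not in config.fix_params]
    fe_ka = [a for a in active_arms
             if not bsv_on[f"ka.{arms[a]}"] and f"ka.{arms[a]}" not in config.fix_params]
    fe_f = [a for a in active_arms
            if not bsv_on[f"f.{arms[a]}"] and f"f.{arms[a]}" not in config.fix_params]

    proposals: list[tuple[np.ndarray, np.ndarray] | None] = [None] * len(subjects)
    history: list[np.ndarray] = []
    trace: list[float] = []
    messages: list[str] = []
    converged = False
    n_iter = 0
    floor_hits = 0

    for it in range(config.max_iter):
        n_iter = it + 1
        estats = []
        for i, subj in enumerate(subjects):
            rng = np.random.default_rng(
                np.random.SeedSequence([abs(int(config.seed)) % (2**31), i, it])
            )
            e = _estep_subject(
                subj, st, config.n_importance, rng, proposals[i],
                config.defensive, config.n_resample,
                inflation=config.proposal_inflation,
            )
            proposals[i] = e["proposal_next"]
            estats.append(e)
        trace.append(-2.0 * sum(e["marg"] for e in estats))

        # --- M-step: means
        M = np.array([e["m"] for e in estats])
        V = np.array([e["var"] for e in estats])
        for d, name in enumerate(SHARED):
            if name not in config.fix_params:
                st.mu[d] = M[:, d].mean()
        for a in active_arms:
            rows = arm_members[a]
            if f"ka.{arms[a]}" not in config.fix_params:
                st.mu_ka[a] = M[rows, 5].mean()
            if f"f.{arms[a]}" not in config.fix_params:
                st.mu_f[a] = M[rows, 6].mean()

        # --- M-step: between-subject variances
        if config.estimate_bsv:
            for d, name in enumerate(SHARED):
                if bsv_on[name]:
                    val = np.mean(V[:, d] + (M[:, d] - st.mu[d]) ** 2)
                    if val < config.omega_floor:
                        floor_hits += 1
                    st.om2[d] = max(val, config.omega_floor)
            for a in active_arms:
                rows = arm_members[a]
                if bsv_on[f"ka.{arms[a]}"]:
                    val = np.mean(V[rows, 5] + (M[rows, 5] - st.mu_ka[a]) ** 2)
                    st.om2_ka[a] = max(val, config.omega_floor)
                if bsv_on[f"f.{arms[a]}"]:
                    val = np.mean(V[rows, 6] + (M[rows, 6] - st.mu_f[a]) ** 2)
                    st.om2_f[a] = max(val, config.omega_floor)

        # --- M-step: residual error
        if config.estimate_residual:
            st.add_sd, st.prop_cv, st.urine_cv = _update_residual(st, subjects, estats)

        # --- M-step: direct update of no-BSV fixed effects
        if fe_shared or fe_ka or fe_f:
            _update_fixed_effects(st, subjects, estats, fe_shared, fe_ka, fe_f)

        history.append(_nat_vector(st))

        w = config.avg_window
        if n_iter >= max(config.min_iter, 2 * w):
            a1 = np.mean(history[-w:], axis=0)
            a0 = np.mean(history[-2 * w:-w], axis=0)
            # gate on population means and residual error; variance
            # components are monitored only — weakly identified variances
            # random-walk on a near-flat likelihood without moving anything
            # a report depends on
            n_mean = 5 + 2 * len(arms)
            gate = np.r_[np.arange(n_mean), np.arange(len(a1) - 3, len(a1))]
            rel = np.max(np.abs(a1 - a0)[gate] / np.maximum(np.abs(a0)[gate], 0.1))
            if rel < config.tol:
                converged = True
                break

    if not converged:
        messages.append(
            f"window-averaged parameter change did not drop below tol={config.tol} "
            f"within {config.max_iter} iterations"
        )
    if floor_hits:
        messages.append(f"between-subject variance hit the floor {floor_hits} time(s)")

    # final estimates: trailing-window average damps Monte Carlo jitter
    w = min(config.avg_window, len(history))
    st_final = _state_from_nat(np.mean(history[-w:], axis=0), st)

    # one clean E-step pass at the final state (EBEs, objective, scores)
    finals = []
    for i, subj in enumerate(subjects):
        rng = np.random.default_rng(
            np.random.SeedSequence([abs(int(config.seed)) % (2**31), i, config.max_iter + 1])
        )
        finals.append(_estep_subject(
            subj, st_final, config.n_importance, rng, proposals[i],
            config.defensive, config.n_resample, store_all=True,
        ))
    trace.append(-2.0 * sum(e["marg"] for e in finals))
    ess = np.array([e["ess"] for e in finals])

    individual = pd.DataFrame([
        {
            "subject": subj.id, "group": subj.group,
            **{name: float(np.exp(e["m"][d])) for d, name in enumerate(SHARED)},
            "ka": float(np.exp(e["m"][5])), "f": float(expit(e["m"][6])),
        }
        for subj, e in zip(subjects, finals)
    ])

    rse, bsv_rse, res_rse = {}, {}, {}
    if config.compute_rse:
        try:
            rse, bsv_rse, res_rse = _fisher_rse(
                st_final, subjects, finals, arm_members, active_arms, bsv_on, config
            )
        except Exception as exc:  # RSEs are advisory; never fail the fit
            messages.append(f"RSE computation failed: {exc}")

    pop = _population_from_state(st_final)
    bsv_cv = {k: 100.0 * v for k, v in pop.bsv.items()}
    return FitResult(
        population=pop,
        rse=rse, bsv_cv=bsv_cv, bsv_rse=bsv_rse, residual_rse=res_rse,
        individual=individual,
        objective_trace=trace,
        converged=converged,
        n_iter=n_iter,
        ess_summary={"min": float(ess.min()), "median": float(np.median(ess))},
        messages=messages,
    )


# ---------------------------------------------------------------------------
# uncertainty
# ---------------------------------------------------------------------------

def _fisher_rse(st, subjects, finals, arm_members, active_arms, bsv_on, config):
    """Empirical (outer-product) Fisher information from per-subject scores.

    Scores for population means and variances follow from the Fisher
    identity (posterior moments of the random-effects prior score); scores
    for the residual parameters come from central differences of each
    subject's marginal log-likelihood, reusing the stored importance samples.
    """
    arms = st.arms
    names: list[str] = []
    cols: list[np.ndarray] = []
    n = len(subjects)
    M = np.array([e["m"] for e in finals])
    V = np.array([e["var"] for e in finals])

    def member_mask(a):
        mask = np.zeros(n)
        mask[arm_members[a]] = 1.0
        return mask

    for d, name in enumerate(SHARED):
        names.append(f"mu.{name}")
        cols.append((M[:, d] - st.mu[d]) / st.om2[d])
    for a in active_arms:
        mask = member_mask(a)
        names.append(f"mu.ka.{arms[a]}")
        cols.append(mask * (M[:, 5] - st.mu_ka[a]) / st.om2_ka[a])
        names.append(f"mu.f.{arms[a]}")
        cols.append(mask * (M[:, 6] - st.mu_f[a]) / st.om2_f[a])

    def om2_score(mdim, mu, om2, mask=None):
        e2 = V[:, mdim] + (M[:, mdim] - mu) ** 2
        s = -0.5 / om2 + 0.5 * e2 / om2 ** 2
        return s if mask is None else s * mask

    for d, name in enumerate(SHARED):
        if bsv_on[name]:
            names.append(f"om2.{name}")
            cols.append(om2_score(d, st.mu[d], st.om2[d]))
    for a in active_arms:
        if bsv_on[f"ka.{arms[a]}"]:
            names.append(f"om2.ka.{arms[a]}")
            cols.append(om2_score(5, st.mu_ka[a], st.om2_ka[a], member_mask(a)))
        if bsv_on[f"f.{arms[a]}"]:
            names.append(f"om2.f.{arms[a]}")
            cols.append(om2_score(6, st.mu_f[a], st.om2_f[a], member_mask(a)))

    # residual scores by central differences on the stored samples
    def marg_with_residual(add_sd, prop_cv, urine_cv):
        out = np.zeros(n)
        for i, (subj, e) in enumerate(zip(subjects, finals)):
            cpp = e["cp"]
            v = np.maximum(add_sd ** 2 + (prop_cv * cpp) ** 2, 1e-12)
            ll = -0.5 * np.sum(
                _LOG2PI + np.log(v) + (subj.y[np.newaxis, :] - cpp) ** 2 / v, axis=1
            )
            if subj.urine_frac is not None:
                pu = e["pu"]
                vu = np.maximum((urine_cv * pu) ** 2, 1e-14)
                ll = ll - 0.5 * (_LOG2PI + np.log(vu) + (subj.urine_frac - pu) ** 2 / vu)
            lw = e["lw_base"] + ll
            out[i] = logsumexp(lw) - np.log(lw.size)
        return out

    res_names = []
    if config.estimate_residual:
        base = (st.add_sd, st.prop_cv, st.urine_cv)
        have_urine = any(s.urine_frac is not None for s in subjects)
        for j, rname in enumerate(("add_sd", "prop_cv", "urine_cv")):
            if rname == "urine_cv" and not have_urine:
                continue
            h = max(1e-4, 1e-3 * base[j])
            hi = list(base); hi[j] += h
            lo = list(base); lo[j] -= h
            cols.append((marg_with_residual(*hi) - marg_with_residual(*lo)) / (2 * h))
            names.append(f"res.{rname}")
            res_names.append(rname)

    S = np.column_stack(cols)
    info = S.T @ S
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    rse: dict[str, float] = {}
    bsv_rse: dict[str, float] = {}
    res_rse: dict[str, float] = {}
    for name, s in zip(names, se):
        if name.startswith("mu."):
            key = name[3:]
            if key.startswith("f."):
                a = arms.index(key[2:])
                fhat = expit(st.mu_f[a])
                rse[key] = 100.0 * s * (1.0 - fhat)  # SE(F)/F via logit delta method
            else:
                rse[key] = 100.0 * s  # log-scale SE approximates relative SE
        elif name.startswith("om2."):
            key = name[4:]
            if key.startswith("f."):
                a = arms.index(key[2:])
                om2 = st.om2_f[a]
            elif key.startswith("ka."):
                a = arms.index(key[3:])
                om2 = st.om2_ka[a]
            else:
                om2 = st.om2[SHARED.index(key)]
            # CV ~ omega to first order: RSE(CV) ~ SE(om2) / (2 om2)
            bsv_rse[key] = 100.0 * s / (2.0 * om2)
        elif name.startswith("res."):
            key = name[4:]
            val = {"add_sd": st.add_sd, "prop_cv": st.prop_cv, "urine_cv": st.urine_cv}[key]
            res_rse[key] = 100.0 * s / max(val, 1e-12)
    return rse, bsv_rse, res_rse


def bootstrap_rse(
    dataset: Sequence[SubjectRecord],
    config: FitConfig,
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Nonparametric bootstrap (resampling subjects within groups) of the
    population means.  The slow gold standard behind the Fisher-based RSEs."""
    rng = np.random.default_rng(seed)
    by_group: dict[str, list[SubjectRecord]] = {}
    for rec in dataset:
        by_group.setdefault(rec.group, []).append(rec)
    rows = []
    for b in range(n_boot):
        sample: list[SubjectRecord] = []
        for g, recs in by_group.items():
            picks = rng.integers(0, len(recs), size=len(recs))
            for j, k in enumerate(picks):
                rec = recs[k]
                sample.append(replace_id(rec, f"{g}-b{j:02d}"))
        res = fit_mcpem(sample, replace(config, seed=int(rng.integers(2**31)), compute_rse=False))
        row = {**{k: res.population.medians[k] for k in SHARED}}
        for a in res.population.arms:
            row[f"ka.{a}"] = res.population.ka[a]
            row[f"f.{a}"] = res.population.f[a]
        rows.append(row)
    return pd.DataFrame(rows)


def replace_id(rec: SubjectRecord, new_id: str) -> SubjectRecord:
    return SubjectRecord(
        id=new_id, group=rec.group, dose=rec.dose,
        plasma_times=rec.plasma_times, plasma_conc=rec.plasma_conc,
        truncated=rec.truncated, urine_time=rec.urine_time,
        urine_fraction=rec.urine_fraction, true_params=rec.true_params,
    )


# ---------------------------------------------------------------------------
# profile likelihood
# ---------------------------------------------------------------------------

_PROFILE_TARGETS = set(SHARED) | {"ka", "f"}


def profile_objective(
    dataset: Sequence[SubjectRecord],
    fitted: FitResult,
    parameter: str,
    grid: Sequence[float],
    n_importance: int = 500,
    seed: int = 0,
    use_urine: bool = True,
    flat_tol: float = 0.1,
) -> pd.DataFrame:
    """Marginal log-likelihood profile of one population parameter.

    ``parameter`` is a shared name (``"vc"``) or arm-resolved (``"ka.OY"``).
    Returns a DataFrame with columns ``value`` and ``loglik``; emits an
    :class:`IdentifiabilityWarning` when the profile is flat (range below
    ``flat_tol`` log-likelihood units).
    """
    base = parameter.split(".")[0]
    if base not in _PROFILE_TARGETS:
        raise ConfigurationError(f"unknown parameter {parameter!r}")
    st0 = _state_from_population(fitted.population, 1e-6)
    subjects = _prepare_subjects(dataset, st0.arms, use_urine)
    vals, lls = [], []
    for v in grid:
        st = st0.copy()
        if parameter in SHARED:
            st.mu[SHARED.index(parameter)] = np.log(v)
        elif base == "ka":
            st.mu_ka[st.arms.index(parameter[3:])] = np.log(v)
        else:
            st.mu_f[st.arms.index(parameter[2:])] = logit(np.clip(v, 1e-6, 1 - 1e-6))
        total = 0.0
        for i, subj in enumerate(subjects):
            rng = np.random.default_rng(np.random.SeedSequence([abs(int(seed)) % (2**31), i]))
            e = _estep_subject(subj, st, n_importance, rng, None, 1.0, 10)
            total += e["marg"]
        vals.append(float(v))
        lls.append(total)
    lls_arr = np.asarray(lls)
    if np.ptp(lls_arr) < flat_tol:
        warnings.warn(
            f"profile of {parameter!r} is flat over the grid "
            f"(range {np.ptp(lls_arr):.3g} < {flat_tol}); parameter may be unidentifiable",
            IdentifiabilityWarning,
        )
    return pd.DataFrame({"value": vals, "loglik": lls})
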