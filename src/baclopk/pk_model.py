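"""Two-compartment oral-absorption model of baclofen disposition with urinary excretion.

The structural model is a linear compartmental system: an absorption (gut)
depot feeding a central compartment that exchanges with one peripheral
compartment and loses drug by two parallel first-order routes — renal
excretion into a cumulative urine compartment (rate ``kel_ur``) and all other
elimination processes (rate ``kel``).  States, with amounts normalised per kg
body weight::

    dXgut/dt = -Ka * Xgut
    dX1/dt   =  Ka * Xgut - (K12 + Kel + Kel,ur) * X1 + K21 * X2
    dX2/dt   =  K12 * X1 - K21 * X2
    dXu/dt   =  Kel,ur * X1
    dXo/dt   =  Kel * X1          (bookkeeping for non-renal losses)

Plasma concentration is ``Cp = X1 / Vc`` with a single documented unit
conversion (mg/kg over L/kg -> mg/L -> ng/mL).

Two evaluation paths are provided.  :func:`solve_linear` (matrix exponential)
is the canonical path: the system is linear, so the solution is exact to
machine precision and degenerate (repeated) eigenvalues need no special
casing.  :func:`solve_numeric` integrates the same ODEs with a stiff-capable
solver and exists as an independent oracle and hook for future nonlinear
extensions.  A vectorised tri-exponential closed form (:func:`predict_batch`)
backs the Monte-Carlo-heavy estimation and diagnostic layers.

Units, package-wide: time hr, amounts mg/kg, volumes L/kg, rate constants
1/hr, concentrations ng/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .errors import NumericalError, ParameterError

#: mg/L -> ng/mL.  With dose in mg/kg and Vc in L/kg, X1/Vc is in mg/L;
#: 1 mg/L = 1000 ng/mL.  This is the only mass-unit conversion in the package.
MG_PER_L_TO_NG_PER_ML = 1000.0

STATE_LABELS = ("gut", "central", "peripheral", "urine", "other")


@dataclass(frozen=True)
class StructuralParams:
    """One subject's structural parameters.

    Parameters
    ----------
    ka : float
        First-order absorption rate constant (1/hr).
    k12, k21 : float
        Intercompartmental rate constants central<->peripheral (1/hr).
        Both zero collapses the model to one compartment.
    kel : float
        Non-urinary elimination rate constant (1/hr).
    kel_ur : float
        Urinary elimination rate constant (1/hr).
    vc : float
        Central volume of distribution (L/kg).
    f : float
        Bioavailable fraction of an oral dose, 0 < f <= 1.
    """

    ka: float
    k12: float
    k21: float
    kel: float
    kel_ur: float
    vc: float
    f: float

    def __post_init__(self) -> None:
        if not (self.ka > 0):
            raise ParameterError(f"ka must be > 0, got {self.ka}")
        for name in ("k12", "k21", "kel", "kel_ur"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (self.kel + self.kel_ur > 0):
            raise ParameterError("total elimination kel + kel_ur must be > 0")
        if not (self.vc > 0):
            raise ParameterError(f"vc must be > 0, got {self.vc}")
        if not (0 < self.f <= 1):
            raise ParameterError(f"f must be in (0, 1], got {self.f}")

    @property
    def k10(self) -> float:
        """Total first-order elimination rate from the central compartment."""
        return self.kel + self.kel_ur

    def swap_elimination_labels(self) -> "StructuralParams":
        """Return a copy with ``kel`` and ``kel_ur`` exchanged.

        The published population estimates imply a model urinary recovery of
        ~16% of dose while the observed fraction excreted is ~61%; exchanging
        the two elimination labels reconciles them.  The package never applies
        this silently — callers opt in.
        """
        return replace(self, kel=self.kel_ur, kel_ur=self.kel)


@dataclass(frozen=True)
class DoseEvent:
    """A single dose, normalised per kg body weight (mg/kg)."""

    amount: float
    time: float = 0.0
    route: Literal["oral", "intravenous"] = "oral"

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ParameterError(f"dose amount must be >= 0, got {self.amount}")
        if self.time < 0:
            raise ParameterError(f"dose time must be >= 0, got {self.time}")
        if self.route not in ("oral", "intravenous"):
            raise ParameterError(f"unknown route {self.route!r}")


@dataclass
class StateTrajectory:
    """Solved amounts (mg/kg) and plasma concentration (ng/mL) on a time grid."""

    times: np.ndarray
    xgut: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    xurine: np.ndarray
    xother: np.ndarray
    cp: np.ndarray

    def total_amount(self) -> np.ndarray:
        """Total drug accounted for at each time (mass-balance check)."""
        return self.xgut + self.x1 + self.x2 + self.xurine + self.xother

    def to_frame(self):
        """Long-format DataFrame (one row per state per time)."""
        import pandas as pd

        wide = pd.DataFrame(
            {
                "time": self.times,
                "gut": self.xgut,
                "central": self.x1,
                "peripheral": self.x2,
                "urine": self.xurine,
                "other": self.xother,
                "cp": self.cp,
            }
        )
        return wide.melt(id_vars="time", var_name="state", value_name="value")


def _rate_matrix(p: StructuralParams) -> np.ndarray:
    a = np.zeros((5, 5))
    a[0, 0] = -p.ka
    a[1, 0] = p.ka
    a[1, 1] = -(p.k12 + p.k10)
    a[1, 2] = p.k21
    a[2, 1] = p.k12
    a[2, 2] = -p.k21
    a[3, 1] = p.kel_ur
    a[4, 1] = p.kel
    return a


def _initial_state(p: StructuralParams, dose: DoseEvent) -> np.ndarray:
    x0 = np.zeros(5)
    if dose.route == "oral":
        x0[0] = p.f * dose.amount
    else:  # intravenous bolus straight into the central compartment
        x0[1] = dose.amount
    return x0


def _check_times(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ParameterError("times must be a non-empty 1-D grid")
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ParameterError("times must be sorted and nonnegative")
    return t


def solve_linear(p: StructuralParams, dose: DoseEvent, times: np.ndarray) -> StateTrajectory:
    """Exact solution of the linear system via the matrix exponential.

    Handles repeated eigenvalues (e.g. Ka coinciding with a disposition
    exponent) without special-case formulas.  Times before the dose event
    yield zero states.
    """
    t = _check_times(times)
    a = _rate_matrix(p)
    x0 = _initial_state(p, dose)
    states = np.zeros((5, t.size))
    for j, tj in enumerate(t):
        dt = tj - dose.time
        if dt < 0:
            continue
        if dt == 0:
            states[:, j] = x0
        else:
            states[:, j] = expm(a * dt) @ x0
    # tiny negative round-off is nonphysical; clip at zero
    np.clip(states, 0.0, None, out=states)
    cp = states[1] / p.vc * MG_PER_L_TO_NG_PER_ML
    return StateTrajectory(t, states[0], states[1], states[2], states[3], states[4], cp)


def solve_numeric(
    p: StructuralParams,
    dose: DoseEvent,
    times: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> StateTrajectory:
    """Stiff-capable numerical integration of the same system (LSODA).

    Agrees with :func:`solve_linear` to within the requested tolerances;
    kept as an independent oracle for the closed-form path.
    """
    t = _check_times(times)
    a = _rate_matrix(p)
    x0 = _initial_state(p, dose)
    post = t >= dose.time
    states = np.zeros((5, t.size))
    if np.any(post):
        t_eval = t[post] - dose.time
        t_end = float(t_eval[-1]) if t_eval[-1] > 0 else 1e-12
        sol = solve_ivp(
            lambda _t, x: a @ x,
            (0.0, t_end),
            x0,
            method="LSODA",
            t_eval=np.maximum(t_eval, 0.0),
            rtol=rtol,
            atol=atol,
            jac=lambda _t, x: a,
        )
        if not sol.success:
            raise NumericalError(f"ODE integration failed: {sol.message}")
        states[:, post] = sol.y
    np.clip(states, 0.0, None, out=states)
    cp = states[1] / p.vc * MG_PER_L_TO_NG_PER_ML
    return StateTrajectory(t, states[0], states[1], states[2], states[3], states[4], cp)


def disposition_exponents(p: StructuralParams) -> tuple[float, float]:
    """Hybrid macro rate constants alpha >= beta of the 2x2 disposition matrix.

    Roots of ``s^2 - (K12 + K21 + K10) s + K21 * K10 = 0``.  The discriminant
    ``(K12 + K10 - K21)^2 + 4 K12 K21`` is nonnegative, so both roots are real.
    """
    s = p.k12 + p.k21 + p.k10
    disc = np.sqrt(max(s * s - 4.0 * p.k21 * p.k10, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return alpha, beta


def macro_constants(p: StructuralParams) -> dict:
    """Derived kinetic quantities for one parameter set.

    Returns a dict with:

    - ``absorption_half_life``: ln2 / Ka (hr)
    - ``alpha``, ``beta``: disposition exponents (1/hr), alpha >= beta
    - ``terminal_exponent``: smallest positive of {alpha, beta, Ka} (1/hr)
    - ``terminal_half_life``: ln2 / terminal_exponent (hr)
    - ``flip_flop``: True when absorption is rate-limiting (Ka < beta)
    - ``clearance``: model total clearance Vc * (Kel + Kel,ur) (L/hr/kg)
    - ``urinary_fraction``: fraction of absorbed drug recovered in urine,
      Kel,ur / (Kel + Kel,ur)
    """
    alpha, beta = disposition_exponents(p)
    candidates = [x for x in (alpha, beta, p.ka) if x > 0]
    lam_z = min(candidates)
    return {
        "absorption_half_life": np.log(2.0) / p.ka,
        "alpha": alpha,
        "beta": beta,
        "terminal_exponent": lam_z,
        "terminal_half_life": np.log(2.0) / lam_z,
        "flip_flop": bool(p.ka < beta),
        "clearance": p.vc * p.k10,
        "urinary_fraction": p.kel_ur / p.k10,
    }


# ---------------------------------------------------------------------------
# Vectorised closed form (hot path for simulation / estimation / diagnostics)
# ---------------------------------------------------------------------------

def _tri_exp_core(ka, k12, k21, k10, times):
    """Tri-exponential kernel: coefficients c_j and exponents lam_j such that
    X1(t) = F * Dose * Ka * sum_j c_j * exp(-lam_j t) for an oral bolus.

    Pure arithmetic (complex-step differentiable).  Parameters may be scalars
    or broadcastable column arrays; ``times`` is a 1-D grid.
    """
    s = k12 + k21 + k10
    disc = np.sqrt(s * s - 4.0 * k21 * k10)
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    ca = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    cb = (k21 - beta) / ((ka - beta) * (alpha - beta))
    ck = (k21 - ka) / ((alpha - ka) * (beta - ka))
    t = times[np.newaxis, :] if np.ndim(times) == 1 else times
    ea = np.exp(-alpha * t)
    eb = np.exp(-beta * t)
    ek = np.exp(-ka * t)
    x1_kernel = ca * ea + cb * eb + ck * ek
    # integral of the kernel from 0 to t (for cumulative urine)
    int_kernel = ca * (1.0 - ea) / alpha + cb * (1.0 - eb) / beta + ck * (1.0 - ek) / ka
    return x1_kernel, int_kernel


def predict_batch(ka, k12, k21, kel, kel_ur, vc, f, amount, times):
    """Plasma concentration and cumulative urine amount for a batch of
    parameter vectors after a single oral bolus at t=0.

    All parameter arguments broadcast as column vectors of shape ``(n, 1)``
    or scalars; ``times`` is a 1-D array of length ``nt``.  Returns
    ``(cp, xu)`` of shape ``(n, nt)`` — cp in ng/mL, xu in mg/kg.
    """
    ka = np.atleast_1d(np.asarray(ka))[..., np.newaxis] if np.ndim(ka) <= 1 else ka
    def col(x):
        x = np.asarray(x)
        return x[..., np.newaxis] if x.ndim == 1 else x
    k12, k21, kel, kel_ur, vc, f = map(col, (k12, k21, kel, kel_ur, vc, f))
    t = np.asarray(times, dtype=float)
    k10 = kel + kel_ur
    if not np.iscomplexobj(ka):
        # keep ka strictly away from alpha/beta for numerical conditioning
        s = k12 + k21 + k10
        disc = np.sqrt(np.maximum(s * s - 4.0 * k21 * k10, 0.0))
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
        gap = 1e-7
        near = np.minimum(np.abs(ka - alpha), np.abs(ka - beta)) < gap * ka
        if np.any(near):
            ka = np.where(near, ka * (1.0 + 1e-6), ka)
    x1_kernel, int_kernel = _tri_exp_core(ka, k12, k21, k10, t)
    scale = f * amount * ka
    x1 = scale * x1_kernel
    xu = kel_ur * scale * int_kernel
    if not np.iscomplexobj(x1):
        x1 = np.maximum(x1, 0.0)
        xu = np.maximum(xu, 0.0)
    cp = x1 / vc * MG_PER_L_TO_NG_PER_ML
    return cp, xu


def predict(p: StructuralParams, dose: DoseEvent, times: np.ndarray):
    """Closed-form plasma concentration (ng/mL) and cumulative urine amount
    (mg/kg) for one subject.  Oral doses use the tri-exponential form; IV and
    dose offsets fall back to :func:`solve_linear`."""
    t = _check_times(times)
    if dose.route != "oral" or dose.time != 0.0 or dose.amount == 0.0:
        traj = solve_linear(p, dose, t)
        return traj.cp, traj.xurine
    cp, xu = predict_batch(
        np.array([p.ka]), np.array([p.k12]), np.array([p.k21]),
        np.array([p.kel]), np.array([p.kel_ur]), np.array([p.vc]),
        np.array([p.f]), dose.amount, t,
    )
    return cp[0], xu[0]
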