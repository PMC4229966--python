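"""Virtual rat studies with log-normal between-subject variability and
combined additive + proportional residual error.

The generator emulates the real study design this package models: three
pretreatment arms (control, OY, AB) sharing systemic disposition parameters
while the absorption rate constant Ka and bioavailability F are resolved per
arm; a single 1 mg/kg oral dose; nine plasma samples over 24 hr; and one
cumulative 0-24 hr urine collection.  Individual parameters are drawn as
``p_i = median * exp(eta_i)`` with ``eta_i ~ N(0, omega^2)`` and
``omega^2 = ln(1 + CV^2)``, so the stated CV is the coefficient of variation
of the log-normal law and the population value is its median.  F draws above
1 are redrawn (bounded parameter); the redraw rate is recorded.

Observed plasma concentrations are ``y = Cp * (1 + eps_prop) + eps_add`` with
independent Gaussian errors; negative values are truncated to zero and
flagged (an assay cannot report negative concentrations).  The urine amount
is observed with proportional error only, stored as a fraction of dose.

Residual-error magnitudes are not part of the published estimates; package
defaults are proportional CV 15% plus additive SD 1 ng/mL for plasma and
proportional CV 10% for urine — typical bioanalytical error (the assay's
reported precision is <= 5.7%) plus biological noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import reference
from .errors import ConfigurationError, ParameterError
from .pk_model import DoseEvent, StructuralParams, predict

SHARED_PARAMS = ("k12", "k21", "kel", "kel_ur", "vc")


@dataclass(frozen=True)
class ResidualModel:
    """Residual-error magnitudes for observed data."""

    add_sd: float = 1.0       # additive SD for plasma, ng/mL
    prop_cv: float = 0.15     # proportional CV for plasma, fraction
    urine_cv: float = 0.10    # proportional CV for urine, fraction

    def __post_init__(self) -> None:
        if self.add_sd < 0 or self.prop_cv < 0 or self.urine_cv < 0:
            raise ParameterError("residual error magnitudes must be >= 0")


@dataclass(frozen=True)
class PopulationModel:
    """Population medians, between-subject CVs and residual error.

    ``medians`` holds the shared disposition parameters (k12, k21, kel,
    kel_ur, vc); ``ka`` and ``f`` map arm label -> median (f as a fraction).
    ``bsv`` maps parameter name -> CV fraction, with arm-specific entries
    written ``"ka.<arm>"`` / ``"f.<arm>"``.
    """

    medians: Mapping[str, float]
    ka: Mapping[str, float]
    f: Mapping[str, float]
    bsv: Mapping[str, float]
    residual: ResidualModel = field(default_factory=ResidualModel)

    def __post_init__(self) -> None:
        missing = set(SHARED_PARAMS) - set(self.medians)
        if missing:
            raise ConfigurationError(f"medians missing {sorted(missing)}")
        if set(self.ka) != set(self.f):
            raise ConfigurationError("ka and f must declare the same arms")
        for arm, fval in self.f.items():
            if not (0 < fval <= 1):
                raise ConfigurationError(f"f[{arm}] must be in (0, 1], got {fval}")
        for key, cv in self.bsv.items():
            if cv < 0:
                raise ConfigurationError(f"bsv[{key}] must be >= 0")
        # constructing a StructuralParams validates the medians' domain
        self.arm_params(self.arms[0])

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(self.ka)

    def bsv_cv(self, name: str, arm: str | None = None) -> float:
        key = f"{name}.{arm}" if arm is not None else name
        return float(self.bsv.get(key, 0.0))

    def arm_params(self, arm: str) -> StructuralParams:
        """Population-median parameter set for one arm."""
        if arm not in self.ka:
            raise ConfigurationError(f"unknown arm {arm!r}; declared: {list(self.ka)}")
        m = self.medians
        return StructuralParams(
            ka=float(self.ka[arm]), k12=float(m["k12"]), k21=float(m["k21"]),
            kel=float(m["kel"]), kel_ur=float(m["kel_ur"]), vc=float(m["vc"]),
            f=float(self.f[arm]),
        )


@dataclass(frozen=True)
class GroupSpec:
    """One study group: label, size, and the Ka/F arms it maps to
    (defaulting to the label itself)."""

    label: str
    n: int
    ka_arm: str | None = None
    f_arm: str | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"group {self.label!r} must have n >= 1")


@dataclass(frozen=True)
class StudyDesign:
    """Dosing and sampling design of a virtual study."""

    groups: Sequence[GroupSpec]
    dose: DoseEvent = DoseEvent(amount=reference.DOSE_MG_PER_KG)
    plasma_times: Sequence[float] = reference.PLASMA_TIMES_HR
    urine_interval: float = reference.URINE_INTERVAL_HR
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.plasma_times, dtype=float)
        if t.size < 1 or np.any(t < 0) or np.any(np.diff(t) < 0):
            raise ConfigurationError("plasma_times must be sorted and nonnegative")
        if self.urine_interval <= 0:
            raise ConfigurationError("urine_interval must be > 0")


@dataclass
class SubjectRecord:
    """Observed data for one virtual animal.

    ``true_params`` retains the generating individual parameters for
    recovery tests only; estimation code never reads it.
    """

    id: str
    group: str
    dose: DoseEvent
    plasma_times: np.ndarray
    plasma_conc: np.ndarray
    truncated: np.ndarray              # bool mask: observation clipped at 0
    urine_time: float | None = None
    urine_fraction: float | None = None  # observed 0-24 hr amount / dose
    true_params: StructuralParams | None = None


def omega_from_cv(cv: float) -> float:
    """Log-normal scale parameter omega from a CV fraction: omega^2 = ln(1+CV^2)."""
    return float(np.sqrt(np.log1p(cv * cv)))


def cv_from_omega(omega: float) -> float:
    """Inverse of :func:`omega_from_cv`."""
    return float(np.sqrt(np.expm1(omega * omega)))


def iv_auc_reference(pop: PopulationModel) -> float:
    """Dose-normalised intravenous AUC implied by a population model
    (ng*hr/mL per mg/kg): 1000 / (Vc * (Kel + Kel,ur)).

    Absolute bioavailability is only defined against an intravenous
    reference; a virtual study inherits its reference from the generating
    model, just as a real oral-only study imports AUC_iv from a prior IV
    study.
    """
    vc = float(pop.medians["vc"])
    k10 = float(pop.medians["kel"]) + float(pop.medians["kel_ur"])
    return 1000.0 / (vc * k10)


def default_population() -> PopulationModel:
    """The published population estimates as a generating model."""
    means = {k: v[0] for k, v in reference.POPPK_MEANS.items()}
    return PopulationModel(
        medians={k: means[k] for k in SHARED_PARAMS},
        ka={g: means[f"ka.{g}"] for g in reference.GROUPS},
        f={g: means[f"f.{g}"] for g in reference.GROUPS},
        bsv={k: v[0] for k, v in reference.POPPK_BSV_CV.items()},
    )


def default_design(n_per_group: Mapping[str, int] | None = None, seed: int | None = None) -> StudyDesign:
    """The real study's design (n=6/4/5 unless overridden)."""
    sizes = dict(reference.GROUP_N if n_per_group is None else n_per_group)
    return StudyDesign(
        groups=[GroupSpec(label=g, n=sizes[g]) for g in sizes],
        seed=seed,
    )


def draw_individual(
    pop: PopulationModel,
    group: str | GroupSpec,
    rng: np.random.Generator,
    max_redraws: int = 1000,
) -> StructuralParams:
    """Draw one individual's parameters from the log-normal population law.

    The F draw is redrawn until it lies in (0, 1]; with the CVs of interest
    (a few percent) redraws are rare.
    """
    spec = group if isinstance(group, GroupSpec) else GroupSpec(label=group, n=1)
    ka_arm = spec.ka_arm or spec.label
    f_arm = spec.f_arm or spec.label
    if ka_arm not in pop.ka or f_arm not in pop.f:
        raise ConfigurationError(
            f"group {spec.label!r} maps to undeclared arm ({ka_arm!r}/{f_arm!r})"
        )
    values = {}
    for name in SHARED_PARAMS:
        om = omega_from_cv(pop.bsv_cv(name))
        values[name] = pop.medians[name] * np.exp(rng.normal(0.0, om)) if om > 0 else pop.medians[name]
    om_ka = omega_from_cv(pop.bsv_cv("ka", ka_arm))
    values["ka"] = pop.ka[ka_arm] * np.exp(rng.normal(0.0, om_ka)) if om_ka > 0 else pop.ka[ka_arm]
    om_f = omega_from_cv(pop.bsv_cv("f", f_arm))
    fmed = pop.f[f_arm]
    fval = fmed
    if om_f > 0:
        for _ in range(max_redraws):
            fval = fmed * np.exp(rng.normal(0.0, om_f))
            if 0 < fval <= 1:
                break
        else:
            fval = min(fmed, 1.0)
    return StructuralParams(
        ka=values["ka"], k12=values["k12"], k21=values["k21"], kel=values["kel"],
        kel_ur=values["kel_ur"], vc=values["vc"], f=fval,
    )


def simulate_study(
    pop: PopulationModel,
    design: StudyDesign,
    seed: int | None = None,
) -> list[SubjectRecord]:
    """Simulate one complete virtual study.

    Randomness is fully determined by the seed (argument, falling back to
    ``design.seed``): each subject receives an independent child stream of a
    single :class:`numpy.random.SeedSequence`, so the output is reproducible
    bit for bit.
    """
    if seed is None:
        seed = design.seed
    root = np.random.SeedSequence(seed)
    total_n = sum(g.n for g in design.groups)
    children = root.spawn(total_n)
    times = np.asarray(design.plasma_times, dtype=float)
    res = pop.residual
    records: list[SubjectRecord] = []
    idx = 0
    for spec in design.groups:
        for j in range(spec.n):
            rng = np.random.default_rng(children[idx])
            idx += 1
            params = draw_individual(pop, spec, rng)
            cp, _ = predict(params, design.dose, times)
            _, xu = predict(params, design.dose, np.array([design.urine_interval]))
            y = cp * (1.0 + rng.normal(0.0, res.prop_cv, size=cp.shape)) if res.prop_cv > 0 else cp.copy()
            if res.add_sd > 0:
                y = y + rng.normal(0.0, res.add_sd, size=cp.shape)
            truncated = y < 0
            y = np.maximum(y, 0.0)
            true_frac = float(xu[0] / design.dose.amount) if design.dose.amount > 0 else 0.0
            u = true_frac
            if res.urine_cv > 0:
                u = true_frac * (1.0 + rng.normal(0.0, res.urine_cv))
            u = max(u, 0.0)
            records.append(
                SubjectRecord(
                    id=f"{spec.label}{j + 1:02d}",
                    group=spec.label,
                    dose=design.dose,
                    plasma_times=times.copy(),
                    plasma_conc=y,
                    truncated=truncated,
                    urine_time=design.urine_interval,
                    urine_fraction=u,
                    true_params=params,
                )
            )
    return records


def draw_params_batch(
    pop: PopulationModel,
    spec: GroupSpec,
    n: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Vectorised individual-parameter draws (arrays of length n) for one
    group; used by the simulation-heavy diagnostics (VPC/NPDE)."""
    ka_arm = spec.ka_arm or spec.label
    f_arm = spec.f_arm or spec.label
    if ka_arm not in pop.ka or f_arm not in pop.f:
        raise ConfigurationError(f"group {spec.label!r} maps to undeclared arm")
    out: dict[str, np.ndarray] = {}
    for name in SHARED_PARAMS:
        om = omega_from_cv(pop.bsv_cv(name))
        out[name] = pop.medians[name] * np.exp(rng.normal(0.0, om, size=n))
    om_ka = omega_from_cv(pop.bsv_cv("ka", ka_arm))
    out["ka"] = pop.ka[ka_arm] * np.exp(rng.normal(0.0, om_ka, size=n))
    om_f = omega_from_cv(pop.bsv_cv("f", f_arm))
    fvals = pop.f[f_arm] * np.exp(rng.normal(0.0, om_f, size=n))
    bad = ~((fvals > 0) & (fvals <= 1))
    for _ in range(100):
        if not bad.any():
            break
        fvals[bad] = pop.f[f_arm] * np.exp(rng.normal(0.0, om_f, size=int(bad.sum())))
        bad = ~((fvals > 0) & (fvals <= 1))
    fvals[bad] = min(pop.f[f_arm], 1.0)
    out["f"] = fvals
    return out
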