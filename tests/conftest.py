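import numpy as np
import pytest

from baclopk import (
    DoseEvent,
    StructuralParams,
    default_design,
    default_population,
    simulate_study,
)


@pytest.fixture(scope="session")
def control_params() -> StructuralParams:
    """Published control-arm population estimates."""
    return StructuralParams(
        ka=1.28, k12=0.803, k21=0.965, kel=0.839, kel_ur=0.190, vc=0.448, f=0.867
    )


@pytest.fixture(scope="session")
def oral_dose() -> DoseEvent:
    return DoseEvent(amount=1.0)


@pytest.fixture(scope="session")
def population():
    return default_population()


@pytest.fixture(scope="session")
def study_records(population):
    """One simulated study at the real design (n=6/4/5), fixed seed."""
    return simulate_study(population, default_design(seed=42))


def random_params(rng: np.random.Generator) -> StructuralParams:
    """A random valid parameter set spanning a wide kinetic range."""
    logu = lambda lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return StructuralParams(
        ka=logu(0.05, 5.0), k12=logu(0.05, 5.0), k21=logu(0.05, 5.0),
        kel=logu(0.05, 5.0), kel_ur=logu(0.01, 2.0),
        vc=logu(0.1, 2.0), f=float(rng.uniform(0.3, 1.0)),
    )
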