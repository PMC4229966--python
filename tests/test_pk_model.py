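"""Structural model: closed forms, mass balance, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from baclopk import (
    DoseEvent,
    ParameterError,
    StructuralParams,
    macro_constants,
    predict,
    solve_linear,
    solve_numeric,
)
from baclopk.pk_model import disposition_exponents

from conftest import random_params

GRID = np.array([0.0, 5 / 60, 0.25, 0.5, 1, 2, 4, 8, 12, 24.0])


def rates_strategy():
    return st.floats(min_value=0.05, max_value=5.0, allow_nan=False)


class TestSolveLinear:
    def test_one_compartment_iv_closed_form(self):
        p = StructuralParams(ka=1.0, k12=0.0, k21=0.0, kel=0.2, kel_ur=0.0, vc=0.5, f=1.0)
        t = np.linspace(0, 24, 40)
        traj = solve_linear(p, DoseEvent(1.0, route="intravenous"), t)
        expected = 1.0 / 0.5 * np.exp(-0.2 * t) * 1000.0
        np.testing.assert_allclose(traj.cp, expected, rtol=1e-10)

    def test_oral_initial_conditions(self, control_params, oral_dose):
        traj = solve_linear(control_params, oral_dose, np.array([0.0, 1.0]))
        assert traj.cp[0] == 0.0
        assert traj.xurine[0] == 0.0
        assert traj.xgut[0] == pytest.approx(control_params.f * oral_dose.amount)

    def test_control_peak_below_complete_central_transfer(self, control_params, oral_dose):
        # Cp can never exceed the value of the full bioavailable dose placed
        # in the central volume at once
        t = np.linspace(0, 24, 400)
        traj = solve_linear(control_params, oral_dose, t)
        assert traj.cp.max() < 1000.0 * 0.867 / 0.448

    def test_urine_asymptote(self, control_params, oral_dose):
        traj = solve_linear(control_params, oral_dose, np.array([200.0]))
        expected = 0.867 * 1.0 * 0.190 / (0.839 + 0.190)
        assert traj.xurine[-1] == pytest.approx(expected, abs=1e-6)

    def test_cp_nonnegative_and_unimodal(self, control_params, oral_dose):
        t = np.linspace(0, 24, 600)
        cp = solve_linear(control_params, oral_dose, t).cp
        assert np.all(cp >= 0)
        k = int(np.argmax(cp))
        assert np.all(np.diff(cp[: k + 1]) >= -1e-9)
        assert np.all(np.diff(cp[k:]) <= 1e-9)

    def test_dose_time_offset(self, control_params):
        dose = DoseEvent(1.0, time=2.0)
        traj = solve_linear(control_params, dose, np.array([0.0, 1.0, 2.0, 3.0]))
        assert np.all(traj.cp[:2] == 0.0)
        assert traj.cp[3] > 0

    def test_repeated_eigenvalue_handled(self):
        # force ka to coincide exactly with the fast disposition exponent
        base = StructuralParams(ka=1.0, k12=0.8, k21=0.9, kel=0.8, kel_ur=0.2, vc=0.5, f=0.9)
        alpha, _ = disposition_exponents(base)
        p = StructuralParams(ka=alpha, k12=0.8, k21=0.9, kel=0.8, kel_ur=0.2, vc=0.5, f=0.9)
        t = np.linspace(0, 12, 30)
        lin = solve_linear(p, DoseEvent(1.0), t)
        num = solve_numeric(p, DoseEvent(1.0), t)
        scale = lin.cp.max()
        np.testing.assert_allclose(lin.cp / scale, num.cp / scale, atol=1e-8)


class TestNumericOracle:
    def test_matches_closed_form_control(self, control_params, oral_dose):
        t = np.linspace(0, 24, 60)
        lin = solve_linear(control_params, oral_dose, t)
        num = solve_numeric(control_params, oral_dose, t)
        scale = lin.cp.max()
        assert np.max(np.abs(lin.cp - num.cp)) / scale < 1e-8

    def test_zero_dose_all_zero(self, control_params):
        traj = solve_numeric(control_params, DoseEvent(0.0), GRID)
        assert np.all(traj.total_amount() == 0)
        assert np.all(traj.cp == 0)

    def test_fast_absorption_approaches_iv_bolus(self):
        p = StructuralParams(ka=1e3, k12=0.8, k21=0.9, kel=0.8, kel_ur=0.2, vc=0.5, f=0.8)
        t = np.linspace(0.05, 12, 50)
        oral = solve_numeric(p, DoseEvent(1.0), t, rtol=1e-11, atol=1e-13)
        iv = solve_linear(p, DoseEvent(0.8, route="intravenous"), t)
        np.testing.assert_allclose(oral.cp, iv.cp, rtol=1e-2)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_mass_balance_and_monotonicity(seed):
    """Conservation: everything dosed is in some compartment at all times;
    cumulative outputs never decrease, the depot never refills."""
    rng = np.random.default_rng(seed)
    p = random_params(rng)
    dose = DoseEvent(1.0)
    t = np.linspace(0, 48, 80)
    traj = solve_linear(p, dose, t)
    np.testing.assert_allclose(traj.total_amount(), p.f * dose.amount, atol=1e-9 * dose.amount)
    assert np.all(np.diff(traj.xurine) >= -1e-12)
    assert np.all(np.diff(traj.xother) >= -1e-12)
    assert np.all(np.diff(traj.xgut) <= 1e-12)


def test_predict_matches_solve_linear(control_params, oral_dose):
    cp, xu = predict(control_params, oral_dose, GRID)
    traj = solve_linear(control_params, oral_dose, GRID)
    np.testing.assert_allclose(cp, traj.cp, rtol=1e-9, atol=1e-9)
    np.testing.assert_allclose(xu, traj.xurine, rtol=1e-9, atol=1e-12)


class TestMacroConstants:
    @pytest.mark.parametrize("ka,expected", [(1.28, 0.54), (0.523, 1.33)])
    def test_absorption_half_life(self, ka, expected):
        p = StructuralParams(ka=ka, k12=0.803, k21=0.965, kel=0.839, kel_ur=0.190,
                             vc=0.448, f=0.85)
        assert round(macro_constants(p)["absorption_half_life"], 2) == expected

    def test_disposition_exponents_against_eigendecomposition(self, control_params):
        mc = macro_constants(control_params)
        k10 = control_params.k10
        a = np.array([[-(0.803 + k10), 0.965], [0.803, -0.965]])
        eig = sorted(-np.linalg.eigvals(a))
        assert mc["beta"] == pytest.approx(eig[0], rel=1e-10)
        assert mc["alpha"] == pytest.approx(eig[1], rel=1e-10)
        assert mc["alpha"] * mc["beta"] == pytest.approx(0.965 * k10, rel=1e-10)
        assert mc["alpha"] + mc["beta"] == pytest.approx(0.803 + 0.965 + k10, rel=1e-10)

    def test_clearance_and_urinary_fraction(self, control_params):
        mc = macro_constants(control_params)
        assert mc["clearance"] == pytest.approx(0.448 * 1.029)
        assert mc["urinary_fraction"] == pytest.approx(0.190 / 1.029)

    def test_flip_flop_flag(self):
        slow = StructuralParams(ka=0.1, k12=0.8, k21=0.9, kel=0.8, kel_ur=0.2,
                                vc=0.5, f=0.9)
        assert macro_constants(slow)["flip_flop"]
        assert macro_constants(slow)["terminal_exponent"] == pytest.approx(0.1)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"ka": -1.0}, {"ka": 0.0}, {"vc": 0.0}, {"f": 0.0}, {"f": 1.2},
        {"k12": -0.1}, {"kel": 0.0, "kel_ur": 0.0},
    ],
)
def test_parameter_domain_errors(kwargs):
    base = dict(ka=1.0, k12=0.8, k21=0.9, kel=0.8, kel_ur=0.2, vc=0.5, f=0.9)
    base.update(kwargs)
    with pytest.raises(ParameterError):
        StructuralParams(**base)


def test_unsorted_times_rejected(control_params, oral_dose):
    with pytest.raises(ParameterError):
        solve_linear(control_params, oral_dose, np.array([1.0, 0.5]))
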