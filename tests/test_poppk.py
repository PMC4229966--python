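"""Population estimator: likelihood correctness, ML equivalence, invariances."""

import numpy as np
import pytest
from scipy.optimize import minimize

import baclopk
from baclopk import (
    ConfigurationError,
    DoseEvent,
    FitConfig,
    PopulationModel,
    ResidualModel,
    StructuralParams,
    SubjectRecord,
    fit_mcpem,
    individual_loglik,
    individual_loglik_grad,
    profile_objective,
    simulate_study,
)
from baclopk.errors import IdentifiabilityWarning
from baclopk.poppk import default_initial_guess
from baclopk.reference import PLASMA_TIMES_HR
from baclopk.synthetic_data import GroupSpec, StudyDesign
from baclopk.pk_model import predict

CONTROL = StructuralParams(ka=1.28, k12=0.803, k21=0.965, kel=0.839,
                           kel_ur=0.190, vc=0.448, f=0.867)


def _subject_at_prediction(params, subject_id="s1", group="control"):
    times = np.asarray(PLASMA_TIMES_HR)
    cp, xu = predict(params, DoseEvent(1.0), times)
    _, xu24 = predict(params, DoseEvent(1.0), np.array([24.0]))
    return SubjectRecord(
        id=subject_id, group=group, dose=DoseEvent(1.0),
        plasma_times=times, plasma_conc=cp,
        truncated=np.zeros(times.size, dtype=bool),
        urine_time=24.0, urine_fraction=float(xu24[0]),
    )


class TestIndividualLoglik:
    def test_value_at_exact_prediction(self):
        """Observation equal to prediction with unit additive SD contributes
        -0.5*ln(2*pi) per point."""
        rec = _subject_at_prediction(CONTROL)
        res = ResidualModel(add_sd=1.0, prop_cv=0.0, urine_cv=0.1)
        ll = individual_loglik(CONTROL, rec, res, use_urine=False)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi) * rec.plasma_times.size, rel=1e-9)

    def test_zero_variance_rejected(self):
        rec = _subject_at_prediction(CONTROL)
        with pytest.raises(ConfigurationError):
            individual_loglik(CONTROL, rec, ResidualModel(add_sd=0.0, prop_cv=0.0))

    def test_urine_term_included(self):
        rec = _subject_at_prediction(CONTROL)
        res = ResidualModel(add_sd=1.0, prop_cv=0.1, urine_cv=0.1)
        with_urine = individual_loglik(CONTROL, rec, res, use_urine=True)
        without = individual_loglik(CONTROL, rec, res, use_urine=False)
        assert with_urine != without

    def test_gradient_matches_central_differences(self):
        rec = _subject_at_prediction(CONTROL)
        rec.plasma_conc = rec.plasma_conc * 1.1 + 2.0  # move off the optimum
        res = ResidualModel(add_sd=1.0, prop_cv=0.15, urine_cv=0.1)
        grad = individual_loglik_grad(CONTROL, rec, res)
        h = 1e-5
        for name in ("ka", "vc", "kel", "k12"):
            hi = {name: getattr(CONTROL, name) * np.exp(h)}
            lo = {name: getattr(CONTROL, name) * np.exp(-h)}
            from dataclasses import replace
            fd = (
                individual_loglik(replace(CONTROL, **hi), rec, res)
                - individual_loglik(replace(CONTROL, **lo), rec, res)
            ) / (2 * h)
            assert grad[name] == pytest.approx(fd, rel=1e-4)


def _pooled_dataset(n=4, noise_seed=0):
    """n copies of the control profile with small independent residual noise
    and no between-subject variability."""
    rng = np.random.default_rng(noise_seed)
    recs = []
    for i in range(n):
        rec = _subject_at_prediction(CONTROL, subject_id=f"s{i}")
        rec.plasma_conc = rec.plasma_conc * (1 + rng.normal(0, 0.02, rec.plasma_conc.size))
        rec.urine_fraction = rec.urine_fraction * (1 + rng.normal(0, 0.05))
        recs.append(rec)
    return recs


def _offset_initial():
    return PopulationModel(
        medians={"k12": 0.803 * 0.8, "k21": 0.965 * 1.2, "kel": 0.839 * 1.3,
                 "kel_ur": 0.190 * 0.8, "vc": 0.448 * 1.2},
        ka={"control": 1.28 * 1.3},
        f={"control": 0.867},
        bsv={**{k: 0.2 for k in ("k12", "k21", "kel", "kel_ur", "vc", "ka.control")},
             "f.control": 0.0},
        residual=ResidualModel(add_sd=0.1, prop_cv=0.02, urine_cv=0.05),
    )


class TestMaximumLikelihoodEquivalence:
    """Without between-subject variability the EM estimator must agree with
    direct maximum-likelihood curve fitting of the pooled data."""

    def test_pooled_fit_matches_direct_ml(self):
        recs = _pooled_dataset()
        res = ResidualModel(add_sd=0.1, prop_cv=0.02, urine_cv=0.05)

        names = ("k12", "k21", "kel", "kel_ur", "vc", "ka")
        def nll(z):
            p = StructuralParams(
                ka=np.exp(z[5]), k12=np.exp(z[0]), k21=np.exp(z[1]),
                kel=np.exp(z[2]), kel_ur=np.exp(z[3]), vc=np.exp(z[4]), f=0.867,
            )
            return -sum(individual_loglik(p, r, res) for r in recs)

        init = _offset_initial()
        z0 = np.log([init.medians["k12"], init.medians["k21"], init.medians["kel"],
                     init.medians["kel_ur"], init.medians["vc"], init.ka["control"]])
        direct = minimize(nll, z0, method="Nelder-Mead",
                          options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 8000})
        assert direct.success
        ml = dict(zip(names, np.exp(direct.x)))

        cfg = FitConfig(
            initial=init, n_importance=500, max_iter=60, tol=5e-4,
            seed=11, fix_params=frozenset({"f.control"}),
            bsv_params=frozenset(),  # no BSV: the estimator must reduce to ML
            estimate_bsv=False, estimate_residual=False, compute_rse=False,
            min_iter=20, avg_window=5,
        )
        fit = fit_mcpem(recs, cfg)
        est = fit.population
        for name in ("k12", "k21", "kel", "kel_ur", "vc"):
            assert est.medians[name] == pytest.approx(ml[name], rel=0.01), name
        assert est.ka["control"] == pytest.approx(ml["ka"], rel=0.01)


@pytest.fixture(scope="module")
def small_fit():
    """A quick single-group fit reused by the profile/invariance tests."""
    pop = baclopk.default_population()
    design = StudyDesign(groups=[GroupSpec("control", 8)], seed=3)
    recs = simulate_study(pop, design)
    cfg = FitConfig(
        initial=default_initial_guess(("control",)), n_importance=400,
        max_iter=80, seed=5, min_iter=40, avg_window=10, compute_rse=True,
        iv_auc_reference=2169.235,
    )
    return recs, fit_mcpem(recs, cfg)


class TestFitContracts:
    def test_too_few_subjects(self):
        with pytest.raises(ConfigurationError):
            fit_mcpem(_pooled_dataset(2), FitConfig(initial=_offset_initial()))

    def test_undeclared_group(self):
        recs = _pooled_dataset(3)
        recs[1].group = "mystery"
        with pytest.raises(ConfigurationError):
            fit_mcpem(recs, FitConfig(initial=_offset_initial(), max_iter=1, min_iter=1))

    def test_subject_order_invariance(self):
        """Per-subject random streams are keyed by sorted id, so shuffling
        the input leaves the estimates bit-identical."""
        pop = baclopk.default_population()
        design = StudyDesign(groups=[GroupSpec("control", 5)], seed=9)
        recs = simulate_study(pop, design)
        cfg = FitConfig(initial=default_initial_guess(("control",)),
                        n_importance=200, max_iter=45, min_iter=40,
                        avg_window=10, seed=2, compute_rse=False)
        a = fit_mcpem(list(recs), cfg)
        b = fit_mcpem(list(reversed(recs)), cfg)
        assert a.population.medians == b.population.medians
        assert a.population.ka == b.population.ka

    def test_objective_trace_monitored(self, small_fit):
        _, fit = small_fit
        trace = np.array(fit.objective_trace)
        assert trace.size >= 2
        # EM drives -2LL down in expectation: the tail must sit well below the start
        assert trace[-1] < trace[0]

    def test_rse_reported_for_means(self, small_fit):
        _, fit = small_fit
        assert fit.rse["ka.control"] > 0
        assert fit.rse["vc"] >= 0


class TestProfileObjective:
    def test_maximum_near_estimate(self, small_fit):
        recs, fit = small_fit
        ka_hat = fit.population.ka["control"]
        prof = profile_objective(recs, fit, "ka.control",
                                 [0.5 * ka_hat, ka_hat, 2.0 * ka_hat],
                                 n_importance=400, seed=4)
        assert prof["loglik"].idxmax() == 1

    def test_flat_profile_warns(self, small_fit):
        recs, fit = small_fit
        ka_hat = fit.population.ka["control"]
        with pytest.warns(IdentifiabilityWarning):
            profile_objective(recs, fit, "ka.control", [ka_hat, ka_hat, ka_hat],
                              n_importance=200, seed=4)

    def test_marginal_likelihood_stable_in_sample_count(self, small_fit):
        """Doubling the importance-sample count moves the marginal
        log-likelihood by well under 1%."""
        recs, fit = small_fit
        ka_hat = fit.population.ka["control"]
        a = profile_objective(recs, fit, "ka.control", [ka_hat], n_importance=500, seed=21)
        b = profile_objective(recs, fit, "ka.control", [ka_hat], n_importance=1000, seed=22)
        la, lb = a["loglik"].iloc[0], b["loglik"].iloc[0]
        assert abs(la - lb) < 0.01 * abs(la)

    def test_unknown_parameter(self, small_fit):
        recs, fit = small_fit
        with pytest.raises(ConfigurationError):
            profile_objective(recs, fit, "nonsense", [1.0])
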