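"""Diagnostics: VPC calibration, NPDE null behaviour, group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from baclopk import (
    ConfigurationError,
    PopulationModel,
    anova_from_summary,
    compare_groups,
    default_design,
    npde,
    scheffe_from_summary,
    simulate_study,
    vpc,
    welch_from_summary,
)
from baclopk.nca import run_study_nca
from baclopk.reference import NCA_SUMMARY


@pytest.fixture(scope="module")
def null_study(population):
    """Data simulated from the same model later used for diagnostics."""
    design = default_design(seed=31)
    return design, simulate_study(population, design)


class TestVPC:
    def test_bands_nested(self, population, null_study):
        design, recs = null_study
        res = vpc(population, design, nsim=300, seed=1, dataset=recs)
        for bands in res.bands.values():
            b = bands.to_numpy()
            assert np.all(np.diff(b, axis=1) >= 0)  # p10 <= p25 <= ... <= p90

    def test_coverage_near_nominal_under_true_model(self, population, null_study):
        design, recs = null_study
        res = vpc(population, design, nsim=400, seed=2, dataset=recs)
        # 135 observations: allow a generous binomial band around 0.8
        assert 0.6 < res.overall_coverage < 0.95

    def test_monte_carlo_stability(self, population, null_study):
        design, _ = null_study
        a = vpc(population, design, nsim=400, seed=3)
        b = vpc(population, design, nsim=800, seed=4)
        med_a = a.bands["control"]["p50"].to_numpy()
        med_b = b.bands["control"]["p50"].to_numpy()
        assert np.max(np.abs(med_a - med_b) / med_b.max()) < 0.05

    def test_nsim_floor(self, population, null_study):
        design, _ = null_study
        with pytest.raises(ConfigurationError):
            vpc(population, design, nsim=50)

    def test_unknown_dataset_group(self, population, null_study):
        design, recs = null_study
        bad = simulate_study(population, design)
        bad[0].group = "ghost"
        with pytest.raises(ConfigurationError):
            vpc(population, design, nsim=300, dataset=bad)


class TestNPDE:
    def test_null_calibration(self, population, null_study):
        _, recs = null_study
        res = npde(population, recs, nsim=1000, seed=5)
        assert abs(res.mean) < 0.15
        assert 0.7 < res.variance < 1.3

    def test_misspecified_model_detected(self, population, null_study):
        """Halving every absorption rate in the evaluation model inflates
        the NPDE location."""
        _, recs = null_study
        wrong = PopulationModel(
            medians=population.medians,
            ka={a: v / 2 for a, v in population.ka.items()},
            f=population.f, bsv=population.bsv, residual=population.residual,
        )
        good = npde(population, recs, nsim=800, seed=6)
        bad = npde(wrong, recs, nsim=800, seed=6)
        assert abs(bad.mean) > abs(good.mean)
        assert abs(bad.mean) > 0.1

    def test_deterministic_under_seed(self, population, null_study):
        _, recs = null_study
        a = npde(population, recs, nsim=500, seed=7)
        b = npde(population, recs, nsim=500, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_excludes_censored_observations(self, population, null_study):
        _, recs = null_study
        recs = [r for r in recs]
        rec = recs[0]
        rec.truncated = rec.truncated.copy()
        rec.truncated[-1] = True
        res = npde(population, recs, nsim=400, seed=8)
        sub = res.table[res.table["subject"] == rec.id]
        assert len(sub) == rec.plasma_times.size - 1


class TestCompareGroups:
    def test_published_cmax_difference_significant(self):
        """Welch's test on the published control-vs-OY Cmax summaries flags
        the difference at the 5% level."""
        m1, s1 = NCA_SUMMARY["cmax"]["control"]
        m2, s2 = NCA_SUMMARY["cmax"]["OY"]
        out = welch_from_summary(m1, s1, 6, m2, s2, 4)
        assert out["welch_p"] < 0.05

    def test_identical_groups_p_one(self):
        df = pd.DataFrame({
            "group": ["a"] * 3 + ["b"] * 3,
            "cmax": [5.0, 6.0, 7.0] * 2,
        })
        rep = compare_groups(df, parameters=("cmax",))
        pair = rep["parameters"]["cmax"]["pairwise"]["a vs b"]
        assert pair["pooled_p"] == pytest.approx(1.0)

    def test_zero_variance_shortcut(self):
        df = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3, "cmax": [5.0] * 3 + [6.0] * 3})
        rep = compare_groups(df, parameters=("cmax",))
        pair = rep["parameters"]["cmax"]["pairwise"]["a vs b"]
        assert "note" in pair
        assert pair["pooled_p"] == 0.0

    def test_summary_anova_matches_raw_anova(self):
        """ANOVA computed from summary statistics equals ANOVA on raw samples
        constructed to match those summaries exactly."""
        rng = np.random.default_rng(3)
        raw = []
        for n in (6, 4, 5):
            x = rng.normal(size=n)
            x = (x - x.mean()) / x.std(ddof=1)
            raw.append(10 + rng.uniform(0, 5) + rng.uniform(1, 2) * x)
        means = [r.mean() for r in raw]
        sds = [r.std(ddof=1) for r in raw]
        ns = [len(r) for r in raw]
        summary = anova_from_summary(means, sds, ns)
        f_raw, p_raw = stats.f_oneway(*raw)
        assert summary["F"] == pytest.approx(f_raw, rel=1e-10)
        assert summary["p"] == pytest.approx(p_raw, rel=1e-10)

    def test_scheffe_never_more_liberal_than_pooled_t(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({
            "group": np.repeat(["a", "b", "c"], 6),
            "cmax": rng.normal(10, 2, 18),
        })
        rep = compare_groups(df, parameters=("cmax",))
        for pair in rep["parameters"]["cmax"]["pairwise"].values():
            assert pair["scheffe_p"] >= pair["pooled_p"] - 1e-12

    def test_scheffe_from_summary_consistency(self):
        means, sds, ns = [744.0, 441.5, 831.8], [252.96, 63.30, 53.0], [6, 4, 5]
        p = scheffe_from_summary(means, sds, ns, 0, 1)
        assert 0 <= p <= 1

    def test_single_group_rejected(self):
        df = pd.DataFrame({"group": ["a"] * 4, "cmax": [1.0, 2, 3, 4]})
        with pytest.raises(ConfigurationError):
            compare_groups(df)

    def test_end_to_end_on_simulated_study(self, null_study):
        _, recs = null_study
        results, _ = run_study_nca(recs)
        rep = compare_groups(results)
        assert "anova" in rep["parameters"]["cmax"]
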