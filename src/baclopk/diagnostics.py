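"""Model-evaluation diagnostics: visual predictive checks, normalized
prediction distribution errors, and between-group statistics.

The VPC simulates replicate studies from a fitted (or specified) population
model at the study design and summarises the simulated observations as
percentile bands (10/25/50/75/90) at the nominal sampling times, overlaid
with the observed data; the fraction of observations inside the 10th-90th
band is the headline coverage statistic (~80% expected under the true
model).

The NPDE decorrelates each subject's simulated observation vectors with the
Cholesky factor of their simulated covariance, ranks the decorrelated
observation within the decorrelated simulations, and maps the rank through
the standard normal quantile; under the true model the NPDEs are iid
N(0, 1).

Group comparisons mirror the conventional small-animal analysis: unpaired
t-tests for two groups (Welch and pooled variants both reported, since
tool conventions differ) and one-way ANOVA with Scheffé's post hoc test for
three or more; a summary-statistic path allows printed mean ± SD tables to
be analysed without raw data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, solve_triangular
from scipy.special import ndtri

from .errors import ConfigurationError
from .nca import NCA_PARAMS, NCAResult, results_frame
from .poppk import FitResult
from .synthetic_data import (
    GroupSpec,
    PopulationModel,
    StudyDesign,
    SubjectRecord,
    draw_params_batch,
)
from .pk_model import predict_batch

PERCENTILES = (10, 25, 50, 75, 90)


def _as_population(fit: FitResult | PopulationModel) -> PopulationModel:
    return fit.population if isinstance(fit, FitResult) else fit


@dataclass
class VPCResult:
    """Percentile bands and coverage per group.

    ``bands[group]`` is a DataFrame indexed by time with columns
    ``p10..p90``; ``observed[group]`` holds the overlaid points;
    ``coverage[group]`` is the fraction of observations inside the
    10th-90th percentile band.
    """

    bands: dict[str, pd.DataFrame]
    urine_bands: dict[str, pd.DataFrame]
    observed: dict[str, pd.DataFrame]
    coverage: dict[str, float]
    overall_coverage: float
    nsim: int


def vpc(
    fit: FitResult | PopulationModel,
    design: StudyDesign,
    nsim: int = 500,
    seed: int = 0,
    dataset: Sequence[SubjectRecord] | None = None,
) -> VPCResult:
    """Visual predictive check of a population model at a study design.

    Simulates ``nsim`` replicate studies (between-subject variability plus
    residual error) and reduces them to percentile bands per nominal time.
    When ``dataset`` is given, observations are overlaid and band coverage
    is computed.
    """
    if nsim < 200:
        raise ConfigurationError("vpc requires nsim >= 200")
    pop = _as_population(fit)
    times = np.asarray(design.plasma_times, dtype=float)
    res = pop.residual
    root = np.random.SeedSequence(seed)
    bands: dict[str, pd.DataFrame] = {}
    urine_bands: dict[str, pd.DataFrame] = {}
    observed: dict[str, pd.DataFrame] = {}
    coverage: dict[str, float] = {}
    n_in, n_tot = 0, 0

    obs_by_group: dict[str, list[SubjectRecord]] = {}
    if dataset is not None:
        for rec in dataset:
            obs_by_group.setdefault(rec.group, []).append(rec)
        unknown = set(obs_by_group) - {g.label for g in design.groups}
        if unknown:
            raise ConfigurationError(f"dataset groups {sorted(unknown)} absent from design")

    for spec in design.groups:
        if (spec.ka_arm or spec.label) not in pop.ka:
            raise ConfigurationError(f"design group {spec.label!r} has no arm in the model")
        rng = np.random.default_rng(root.spawn(1)[0])
        total = nsim * spec.n
        draws = draw_params_batch(pop, spec, total, rng)
        eval_times = np.concatenate([times, [design.urine_interval]])
        cp, xu = predict_batch(
            draws["ka"], draws["k12"], draws["k21"], draws["kel"],
            draws["kel_ur"], draws["vc"], draws["f"],
            design.dose.amount, eval_times,
        )
        cpp = cp[:, : times.size]
        y = cpp * (1.0 + rng.normal(0.0, res.prop_cv, size=cpp.shape))
        y = y + rng.normal(0.0, res.add_sd, size=cpp.shape)
        y = np.maximum(y, 0.0)
        pct = np.percentile(y, PERCENTILES, axis=0)
        bands[spec.label] = pd.DataFrame(
            {f"p{p}": pct[k] for k, p in enumerate(PERCENTILES)}, index=pd.Index(times, name="time"),
        )
        uf = xu[:, -1] / design.dose.amount
        uobs = np.maximum(uf * (1.0 + rng.normal(0.0, res.urine_cv, size=uf.shape)), 0.0)
        upct = np.percentile(uobs, PERCENTILES)
        urine_bands[spec.label] = pd.DataFrame(
            {f"p{p}": [upct[k]] for k, p in enumerate(PERCENTILES)},
            index=pd.Index([design.urine_interval], name="time"),
        )

        if spec.label in obs_by_group:
            rows = []
            inside = 0
            total_obs = 0
            b = bands[spec.label]
            for rec in obs_by_group[spec.label]:
                for t, v in zip(rec.plasma_times, rec.plasma_conc):
                    rows.append({"subject": rec.id, "time": t, "value": v})
                    j = int(np.argmin(np.abs(times - t)))
                    if np.isclose(times[j], t):
                        total_obs += 1
                        if b["p10"].iloc[j] <= v <= b["p90"].iloc[j]:
                            inside += 1
            observed[spec.label] = pd.DataFrame(rows)
            coverage[spec.label] = inside / total_obs if total_obs else float("nan")
            n_in += inside
            n_tot += total_obs

    return VPCResult(
        bands=bands, urine_bands=urine_bands, observed=observed,
        coverage=coverage,
        overall_coverage=(n_in / n_tot if n_tot else float("nan")),
        nsim=nsim,
    )


@dataclass
class NPDEResult:
    """Per-observation NPDEs and global calibration summary."""

    table: pd.DataFrame        # subject, group, time, observed, npde
    mean: float
    variance: float
    t_pvalue: float            # H0: mean = 0
    shapiro_stat: float
    shapiro_pvalue: float
    nsim: int


def npde(
    fit: FitResult | PopulationModel,
    dataset: Sequence[SubjectRecord],
    nsim: int = 1000,
    seed: int = 0,
) -> NPDEResult:
    """Normalized prediction distribution errors for a dataset under a model.

    Truncated (zero-clipped) observations are censored and excluded.  A
    singular simulated covariance is ridge-regularised with a warning.
    """
    pop = _as_population(fit)
    res = pop.residual
    root = np.random.SeedSequence(seed)
    rows = []
    values = []
    for rec in sorted(dataset, key=lambda r: r.id):
        if rec.group not in pop.ka:
            raise ConfigurationError(f"subject {rec.id!r}: group {rec.group!r} not in model")
        keep = ~np.asarray(rec.truncated, dtype=bool)
        if not np.any(keep):
            continue
        t = np.asarray(rec.plasma_times, dtype=float)[keep]
        y = np.asarray(rec.plasma_conc, dtype=float)[keep]
        rng = np.random.default_rng(root.spawn(1)[0])
        draws = draw_params_batch(pop, GroupSpec(label=rec.group, n=1), nsim, rng)
        cp, _ = predict_batch(
            draws["ka"], draws["k12"], draws["k21"], draws["kel"],
            draws["kel_ur"], draws["vc"], draws["f"], rec.dose.amount, t,
        )
        ysim = cp * (1.0 + rng.normal(0.0, res.prop_cv, size=cp.shape))
        ysim = ysim + rng.normal(0.0, res.add_sd, size=cp.shape)
        mu = ysim.mean(axis=0)
        cov = np.cov(ysim, rowvar=False)
        cov = np.atleast_2d(cov)
        try:
            L = cholesky(cov, lower=True)
        except np.linalg.LinAlgError:
            ridge = 1e-8 * np.trace(cov) / cov.shape[0]
            warnings.warn("singular simulated covariance; ridge-regularising")
            L = cholesky(cov + ridge * np.eye(cov.shape[0]), lower=True)
        y_dec = solve_triangular(L, y - mu, lower=True)
        ysim_dec = solve_triangular(L, (ysim - mu).T, lower=True)
        counts = np.sum(ysim_dec < y_dec[:, np.newaxis], axis=1)
        pde = (counts + 0.5) / (nsim + 1.0)
        vals = ndtri(pde)
        for tj, yj, nj in zip(t, y, vals):
            rows.append({
                "subject": rec.id, "group": rec.group, "time": tj,
                "observed": yj, "npde": nj,
            })
        values.append(vals)
    all_vals = np.concatenate(values)
    tstat, tp = stats.ttest_1samp(all_vals, 0.0)
    sw = stats.shapiro(all_vals if all_vals.size <= 5000 else all_vals[:5000])
    return NPDEResult(
        table=pd.DataFrame(rows),
        mean=float(all_vals.mean()),
        variance=float(all_vals.var(ddof=1)),
        t_pvalue=float(tp),
        shapiro_stat=float(sw.statistic),
        shapiro_pvalue=float(sw.pvalue),
        nsim=nsim,
    )


# ---------------------------------------------------------------------------
# between-group statistics
# ---------------------------------------------------------------------------

ALPHA = 0.05


def _welch_pooled(x: np.ndarray, y: np.ndarray) -> dict:
    if np.allclose(x, x[0]) and np.allclose(y, y[0]):
        equal = float(x[0]) == float(y[0])
        return {
            "welch_p": 1.0 if equal else 0.0,
            "pooled_p": 1.0 if equal else 0.0,
            "note": "zero within-group variance; exact-equality shortcut",
        }
    tw, pw = stats.ttest_ind(x, y, equal_var=False)
    tp, pp = stats.ttest_ind(x, y, equal_var=True)
    return {"welch_p": float(pw), "pooled_p": float(pp)}


def _scheffe_pairwise(values: Mapping[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Scheffé post hoc p-values from the contrast form: the pairwise
    statistic (mean difference squared over MSE*(1/ni+1/nj)) is referred to
    (k-1) * F(k-1, N-k)."""
    groups = list(values)
    k = len(groups)
    ns = {g: len(values[g]) for g in groups}
    N = sum(ns.values())
    means = {g: float(np.mean(values[g])) for g in groups}
    ssw = sum(float(np.sum((values[g] - means[g]) ** 2)) for g in groups)
    df2 = N - k
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            g1, g2 = groups[i], groups[j]
            if ssw == 0:
                out[(g1, g2)] = 1.0 if means[g1] == means[g2] else 0.0
                continue
            mse = ssw / df2
            stat = (means[g1] - means[g2]) ** 2 / (mse * (1 / ns[g1] + 1 / ns[g2]))
            out[(g1, g2)] = float(stats.f.sf(stat / (k - 1), k - 1, df2))
    return out


def compare_groups(
    results: Sequence[NCAResult] | pd.DataFrame,
    parameters: Sequence[str] = NCA_PARAMS,
    alpha: float = ALPHA,
) -> dict:
    """Between-group comparison of NCA parameters.

    For each parameter: pairwise Welch and pooled unpaired t-tests, and
    (with 3+ groups) one-way ANOVA followed by Scheffé's post hoc test.
    Returns a nested report dict with significance flags at ``alpha``.
    """
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ConfigurationError("need >= 2 groups to compare")
    report: dict = {"alpha": alpha, "groups": groups, "parameters": {}}
    for p in parameters:
        if p not in df.columns:
            continue
        values = {}
        for g in groups:
            v = df.loc[df["group"] == g, p].dropna().to_numpy(dtype=float)
            if v.size >= 2:
                values[g] = v
        if len(values) < 2:
            continue
        entry: dict = {"pairwise": {}}
        if len(values) >= 3:
            fstat, fp = stats.f_oneway(*values.values())
            entry["anova"] = {"F": float(fstat), "p": float(fp), "significant": bool(fp < alpha)}
            scheffe = _scheffe_pairwise(values)
        else:
            scheffe = {}
        glist = list(values)
        for i in range(len(glist)):
            for j in range(i + 1, len(glist)):
                g1, g2 = glist[i], glist[j]
                pair = _welch_pooled(values[g1], values[g2])
                if (g1, g2) in scheffe:
                    pair["scheffe_p"] = scheffe[(g1, g2)]
                    pair["scheffe_significant"] = bool(scheffe[(g1, g2)] < alpha)
                pair["welch_significant"] = bool(pair["welch_p"] < alpha)
                pair["pooled_significant"] = bool(pair["pooled_p"] < alpha)
                entry["pairwise"][f"{g1} vs {g2}"] = pair
        report["parameters"][p] = entry
    return report


def welch_from_summary(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> dict:
    """Welch (and pooled) unpaired t-test from printed mean ± SD summaries."""
    tw, pw = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    tp, pp = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return {
        "welch_t": float(tw), "welch_p": float(pw),
        "pooled_t": float(tp), "pooled_p": float(pp),
    }


def anova_from_summary(means: Sequence[float], sds: Sequence[float], ns: Sequence[int]) -> dict:
    """One-way ANOVA from per-group summary statistics."""
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, int)
    k = means.size
    N = int(ns.sum())
    grand = float(np.sum(ns * means) / N)
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(np.sum((ns - 1) * sds ** 2))
    if ssw == 0:
        return {"F": float("inf") if ssb > 0 else 0.0,
                "p": 0.0 if ssb > 0 else 1.0,
                "note": "zero within-group variance"}
    F = (ssb / (k - 1)) / (ssw / (N - k))
    return {"F": float(F), "p": float(stats.f.sf(F, k - 1, N - k))}


def scheffe_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int],
    i: int = 0, j: int = 1,
) -> float:
    """Scheffé post hoc p-value for the (i, j) pairwise contrast from
    summary statistics."""
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, int)
    k = means.size
    N = int(ns.sum())
    ssw = float(np.sum((ns - 1) * sds ** 2))
    if ssw == 0:
        return 1.0 if means[i] == means[j] else 0.0
    mse = ssw / (N - k)
    stat = (means[i] - means[j]) ** 2 / (mse * (1 / ns[i] + 1 / ns[j]))
    return float(stats.f.sf(stat / (k - 1), k - 1, N - k))


def plot_vpc(result: VPCResult, group: str, path: str | None = None):
    """Plot one group's VPC (bands + observations).  Returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    b = result.bands[group]
    fig, ax = plt.subplots(figsize=(6, 4))
    t = b.index.to_numpy()
    ax.fill_between(t, b["p10"], b["p90"], alpha=0.2, color="C0", label="10th–90th")
    ax.fill_between(t, b["p25"], b["p75"], alpha=0.3, color="C0", label="25th–75th")
    ax.plot(t, b["p50"], color="C0", label="median")
    if group in result.observed and len(result.observed[group]):
        obs = result.observed[group]
        ax.plot(obs["time"], obs["value"], "ko", ms=4, alpha=0.7, label="observed")
    ax.set_xlabel("time (hr)")
    ax.set_ylabel("plasma concentration (ng/mL)")
    ax.set_title(f"VPC — {group}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
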