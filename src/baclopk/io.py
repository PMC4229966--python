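"""Dataset and configuration I/O.

The dataset dialect is a long-format CSV, one row per event::

    subject,group,kind,time,value,flag

``kind`` is one of ``dose`` (value = amount, mg/kg), ``plasma`` (value =
concentration, ng/mL) or ``urine`` (value = cumulative amount as a fraction
of dose).  Every subject carries exactly one dose row; observation times may
not precede the dose.  ``flag`` is empty or ``truncated`` (a plasma value
clipped at zero by the assay floor).

Run configuration is a single YAML (or JSON) document with blocks for the
population model, study design, NCA options, fit options, diagnostics, seed
and output directory; unknown keys are rejected.  Every result file embeds
the SHA-256 hash of the canonical configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import reference
from .errors import ConfigurationError, DataError
from .pk_model import DoseEvent
from .synthetic_data import (
    GroupSpec,
    PopulationModel,
    ResidualModel,
    StudyDesign,
    SubjectRecord,
    default_population,
)

DATASET_COLUMNS = ("subject", "group", "kind", "time", "value", "flag")
KINDS = ("dose", "plasma", "urine")


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

def records_to_table(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records into the long-format dataset table."""
    rows = []
    for rec in records:
        rows.append({
            "subject": rec.id, "group": rec.group, "kind": "dose",
            "time": rec.dose.time, "value": rec.dose.amount, "flag": "",
        })
        for t, v, trunc in zip(rec.plasma_times, rec.plasma_conc, rec.truncated):
            rows.append({
                "subject": rec.id, "group": rec.group, "kind": "plasma",
                "time": float(t), "value": float(v),
                "flag": "truncated" if trunc else "",
            })
        if rec.urine_fraction is not None:
            rows.append({
                "subject": rec.id, "group": rec.group, "kind": "urine",
                "time": float(rec.urine_time or 24.0),
                "value": float(rec.urine_fraction), "flag": "",
            })
    return _canonical(pd.DataFrame(rows, columns=list(DATASET_COLUMNS)))


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    kind_order = {k: i for i, k in enumerate(KINDS)}
    out = df.copy()
    out["flag"] = out["flag"].fillna("")
    out["_k"] = out["kind"].map(kind_order)
    out = out.sort_values(["subject", "_k", "time"], kind="mergesort").drop(columns="_k")
    return out.reset_index(drop=True)


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Strict validation of a dataset table; returns the canonical form.

    Raises :class:`DataError` naming the offending row or subject.
    """
    missing = set(DATASET_COLUMNS) - {"flag"} - set(df.columns)
    if missing:
        raise DataError(f"dataset missing columns {sorted(missing)}")
    df = df.copy()
    if "flag" not in df.columns:
        df["flag"] = ""
    df["flag"] = df["flag"].fillna("")
    for i, row in df.iterrows():
        if row["kind"] not in KINDS:
            raise DataError(f"row {i}: unknown kind {row['kind']!r}")
        try:
            t = float(row["time"])
            v = float(row["value"])
        except (TypeError, ValueError):
            raise DataError(f"row {i}: non-numeric time or value") from None
        if not np.isfinite(t) or t < 0:
            raise DataError(f"row {i}: invalid time {row['time']!r}")
        if not np.isfinite(v):
            raise DataError(f"row {i}: invalid value {row['value']!r}")
        if row["kind"] == "plasma" and v < 0:
            raise DataError(f"row {i}: negative plasma concentration {v}")
        if row["kind"] == "urine" and not (0 <= v <= 1):
            raise DataError(f"row {i}: urine fraction {v} outside [0, 1]")
        if row["kind"] == "dose" and v < 0:
            raise DataError(f"row {i}: negative dose {v}")
    for subj, sub in df.groupby("subject"):
        ndose = int((sub["kind"] == "dose").sum())
        if ndose == 0:
            raise DataError(f"subject {subj!r}: missing dose row")
        if ndose > 1:
            raise DataError(f"subject {subj!r}: duplicate dose rows")
        t0 = float(sub.loc[sub["kind"] == "dose", "time"].iloc[0])
        obs = sub[sub["kind"] != "dose"]
        if (obs["time"].astype(float) < t0).any():
            raise DataError(f"subject {subj!r}: observation before dose time")
        if sub["group"].nunique() > 1:
            raise DataError(f"subject {subj!r}: inconsistent group labels")
    return _canonical(df)


def write_dataset(data: pd.DataFrame | Sequence[SubjectRecord], path: str | Path) -> None:
    """Write a dataset CSV in canonical (sorted) form."""
    df = data if isinstance(data, pd.DataFrame) else records_to_table(data)
    df = validate_dataset(df)
    df.to_csv(path, index=False)


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a dataset CSV."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"dataset file not found: {path}")
    df = pd.read_csv(
        path,
        dtype={"subject": str, "group": str, "kind": str, "flag": str},
        float_precision="round_trip",
    )
    return validate_dataset(df)


def table_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    """Reconstruct subject records from a (validated) dataset table."""
    df = validate_dataset(df)
    records = []
    for subj, sub in df.groupby("subject", sort=True):
        dose_row = sub[sub["kind"] == "dose"].iloc[0]
        dose = DoseEvent(amount=float(dose_row["value"]), time=float(dose_row["time"]))
        plasma = sub[sub["kind"] == "plasma"].sort_values("time")
        urine = sub[sub["kind"] == "urine"]
        records.append(SubjectRecord(
            id=str(subj),
            group=str(sub["group"].iloc[0]),
            dose=dose,
            plasma_times=plasma["time"].to_numpy(dtype=float),
            plasma_conc=plasma["value"].to_numpy(dtype=float),
            truncated=(plasma["flag"] == "truncated").to_numpy(),
            urine_time=float(urine["time"].iloc[0]) if len(urine) else None,
            urine_fraction=float(urine["value"].iloc[0]) if len(urine) else None,
        ))
    return records


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """The shipped default run configuration: the published population
    estimates as generating values at the real study design."""
    pop = default_population()
    return {
        "population": {
            "medians": dict(pop.medians),
            "ka": dict(pop.ka),
            "f": dict(pop.f),
            "bsv": dict(pop.bsv),
            "residual": {"add_sd": 1.0, "prop_cv": 0.15, "urine_cv": 0.10},
        },
        "design": {
            "groups": [{"label": g, "n": n} for g, n in reference.GROUP_N.items()],
            "dose": {"amount": reference.DOSE_MG_PER_KG, "time": 0.0, "route": "oral"},
            "plasma_times": list(reference.PLASMA_TIMES_HR),
            "urine_interval": reference.URINE_INTERVAL_HR,
        },
        # iv_auc_reference: None derives the dose-normalised IV reference
        # from the configured population (1000 / (Vc * K10)); a number
        # overrides it (e.g. reference.IV_AUC_REFERENCE, back-derived from
        # the published summary table).
        "nca": {
            "iv_auc_reference": None,
            "method": "lin-up-log-down",
        },
        "fit": {
            "initial": "generic",
            "n_importance": 1000,
            "max_iter": 300,
            "tol": 1.0e-3,
            "use_urine": True,
        },
        "diagnostics": {"vpc_nsim": 500, "npde_nsim": 1000},
        "seed": 1234,
        "outdir": "results",
    }


def _check_keys(cfg: Mapping, template: Mapping, path: str = "") -> None:
    for key, val in cfg.items():
        if key not in template:
            raise ConfigurationError(f"unknown configuration key {path + str(key)!r}")
        tval = template[key]
        if isinstance(tval, Mapping) and isinstance(val, Mapping) and path + key not in (
            "population.medians", "population.ka", "population.f", "population.bsv",
        ):
            _check_keys(val, tval, path + key + ".")


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML/JSON run configuration, filling defaults and rejecting
    unknown keys.  ``None`` returns the shipped defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    user = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(user, dict):
        raise ConfigurationError("configuration must be a mapping")
    _check_keys(user, cfg)

    def merge(base: dict, over: Mapping, path: str = "") -> dict:
        out = dict(base)
        for k, v in over.items():
            full = path + k
            if isinstance(v, Mapping) and isinstance(base.get(k), Mapping) and full not in (
                "population.medians", "population.ka", "population.f", "population.bsv",
            ):
                out[k] = merge(base[k], v, full + ".")
            else:
                out[k] = v if not isinstance(v, Mapping) else dict(v)
        return out

    return merge(cfg, user)


def config_hash(cfg: Mapping[str, Any]) -> str:
    """SHA-256 of the canonical JSON form of a configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def iv_reference_from_config(cfg: Mapping) -> float:
    """The IV AUC reference for a run: explicit config value, or derived
    from the configured population model."""
    from .synthetic_data import iv_auc_reference

    val = cfg["nca"].get("iv_auc_reference")
    return float(val) if val is not None else iv_auc_reference(population_from_config(cfg))


def population_from_config(cfg: Mapping) -> PopulationModel:
    p = cfg["population"]
    return PopulationModel(
        medians={k: float(v) for k, v in p["medians"].items()},
        ka={k: float(v) for k, v in p["ka"].items()},
        f={k: float(v) for k, v in p["f"].items()},
        bsv={k: float(v) for k, v in p["bsv"].items()},
        residual=ResidualModel(**{k: float(v) for k, v in p["residual"].items()}),
    )


def design_from_config(cfg: Mapping) -> StudyDesign:
    d = cfg["design"]
    dose = d["dose"]
    return StudyDesign(
        groups=[GroupSpec(label=g["label"], n=int(g["n"]),
                          ka_arm=g.get("ka_arm"), f_arm=g.get("f_arm"))
                for g in d["groups"]],
        dose=DoseEvent(amount=float(dose["amount"]), time=float(dose.get("time", 0.0)),
                       route=dose.get("route", "oral")),
        plasma_times=[float(t) for t in d["plasma_times"]],
        urine_interval=float(d["urine_interval"]),
        seed=cfg.get("seed"),
    )


def write_json(obj: Any, path: str | Path, cfg: Mapping | None = None) -> None:
    """Write a JSON result file, embedding the config hash when given."""
    payload = dict(obj)
    if cfg is not None:
        payload["config_hash"] = config_hash(cfg)
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2))


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="records")
    return x
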