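"""CSV/JSON persistence for cohorts, matched pairs and results.

Cohort CSV schema: one row per patient with columns id, arm, covariates,
survival_time_days, censor_time_days, observed_time_days, event,
egfr_result, and wide monthly cost columns cost_m01..cost_m36 /
oop_m01..oop_m36.  Trailing empty cost cells (early deaths) parse as zero
accrual.  A JSON sidecar carries the generating configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from panelcea.matching import MatchResult
from panelcea.synthetic import (CensoringModel, CohortConfig, CohortTable,
                                CostModel, CovariateSpec, N_COST_MONTHS)

REQUIRED_COLUMNS = ("id", "arm", "survival_time_days", "censor_time_days",
                    "observed_time_days", "event", "egfr_result")


def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["covariate_specs"] = [dataclasses.asdict(s)
                            for s in config.covariate_specs]
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    d["covariate_specs"] = tuple(CovariateSpec(**s)
                                 for s in d["covariate_specs"])
    d["censoring"] = CensoringModel(**d["censoring"])
    d["cost_model"] = CostModel(**d["cost_model"])
    return CohortConfig(**d)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path, chash: str | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if chash:
            fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_cohort_csv(cohort: CohortTable, path,
                     chash: str | None = None) -> None:
    """Write the cohort plus a JSON sidecar with config and seed."""
    path = Path(path)
    _write_csv(cohort.data, path, chash)
    sidecar = {"seed": cohort.config.seed if cohort.config else None,
               "config": (config_to_dict(cohort.config)
                          if cohort.config else None),
               "config_hash": chash}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2,
                                                    default=str))


def read_cohort_csv(path, specs: tuple | None = None) -> CohortTable:
    """Read a cohort CSV, validating the schema.

    Covariate specs come from the JSON sidecar when present (or from
    ``specs``); otherwise kinds are inferred from the column dtypes with
    exact_match unknown (False).
    """
    path = Path(path)
    df = read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    config = None
    sidecar = path.with_suffix(".json")
    if specs is None and sidecar.exists():
        payload = json.loads(sidecar.read_text())
        if payload.get("config"):
            config = config_from_dict(payload["config"])
            specs = config.covariate_specs

    cost_cols = [f"cost_m{j:02d}" for j in range(1, N_COST_MONTHS + 1)]
    for col in cost_cols:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    oop_cols = [c for c in df.columns if c.startswith("oop_m")]
    # trailing empty cost cells for early deaths parse as zero accrual
    df[cost_cols] = df[cost_cols].fillna(0.0)
    if oop_cols:
        df[oop_cols] = df[oop_cols].fillna(0.0)

    for col in ("survival_time_days", "censor_time_days",
                "observed_time_days"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-numeric or missing value in column "
                             f"{col!r} at row {row}")
        if (vals < 0).any():
            row = int(np.flatnonzero(vals < 0)[0])
            raise ValueError(f"negative time in column {col!r} at row {row}")
        df[col] = vals
    bad_cost = ~df[cost_cols].apply(
        lambda c: pd.to_numeric(c, errors="coerce").notna()).all(axis=None)
    if bad_cost:
        raise ValueError("non-numeric monthly cost value")
    if (df[cost_cols].to_numpy() < 0).any():
        raise ValueError("negative monthly cost value")

    if specs is None:
        specs = _infer_specs(df)
    return CohortTable(data=df, covariate_specs=tuple(specs), config=config)


def _infer_specs(df: pd.DataFrame) -> tuple:
    reserved = set(REQUIRED_COLUMNS)
    specs = []
    for col in df.columns:
        if col in reserved or col.startswith(("cost_m", "oop_m")):
            continue
        v = df[col]
        if v.dtype == object:
            levels = sorted(v.unique().tolist())
            specs.append(CovariateSpec(col, "categorical",
                                       {"levels": levels,
                                        "probs": [1 / len(levels)] * len(levels)}))
        elif set(np.unique(v.to_numpy())) <= {0.0, 1.0}:
            specs.append(CovariateSpec(col, "binary", {"p": float(v.mean())}))
        else:
            specs.append(CovariateSpec(col, "continuous",
                                       {"dist": "normal",
                                        "mean": float(v.mean()),
                                        "sd": float(v.std())}))
    return tuple(specs)


def write_pairs_csv(match: MatchResult, path,
                    chash: str | None = None) -> None:
    df = pd.DataFrame({
        "treated_id": match.treated_ids(),
        "control_id": match.control_ids(),
        "stratum": [match.strata_map[t] for t, _ in match.pairs],
        "distance": match.distances,
    })
    _write_csv(df, path, chash)
    sidecar = {"weight_vector": match.weight_vector,
               "n_matched": match.n_matched,
               "n_treated": match.n_treated,
               "fitness_trace": [list(map(float, v))
                                 for v in match.fitness_trace],
               "config_hash": chash}
    Path(path).with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2))


def read_pairs_csv(path) -> MatchResult:
    path = Path(path)
    df = read_csv(path)
    pairs = list(zip(df["treated_id"].tolist(), df["control_id"].tolist()))
    sidecar = path.with_suffix(".json")
    weights, trace, n_treated = {}, [], len(pairs)
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        weights = payload.get("weight_vector", {})
        trace = [np.asarray(v) for v in payload.get("fitness_trace", [])]
        n_treated = payload.get("n_treated", n_treated)
    return MatchResult(
        pairs=pairs, distances=df["distance"].to_numpy(),
        weight_vector=weights, fitness_trace=trace,
        n_matched=len(pairs), n_treated=n_treated,
        strata_map=dict(zip(df["treated_id"], df["stratum"])))
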