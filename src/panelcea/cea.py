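"""Bootstrap cost-effectiveness analysis: INMB, BC intervals, CEAC, plane.

Uncertainty is quantified by resampling matched pairs with replacement --
each replicate keeps the 1:1 structure, so the within-pair cost-effect
correlation survives into the (delta_c, delta_e) sampling distribution --
and re-running the reverse Kaplan-Meier fit, the IPCW weights and the
partitioned estimator inside every replicate.  Intervals are bias-corrected
(BC, no acceleration) percentile intervals.  Matching itself is not re-run
inside replicates by default (see ``rematch_in_bootstrap``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from panelcea.grid import IntervalGrid, build_grid
from panelcea.ipcw import (accrual_arrays, arm_estimate_arrays,
                           matched_arm_frames, sur_estimates)
from panelcea.matching import MatchingConfig, MatchResult, genetic_search
from panelcea.synthetic import CohortTable

DEFAULT_WTP = (50_000.0, 100_000.0)
DEFAULT_CEAC_GRID = np.arange(0.0, 200_000.0 + 1, 2_500.0)


def inmb(delta_e: float, delta_c: float, wtp: float) -> float:
    """Incremental net monetary benefit wtp * delta_e - delta_c.

    Positive values indicate cost-effectiveness at willingness-to-pay wtp.
    """
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * delta_e - delta_c


def bc_interval(draws: np.ndarray, point_estimate: float,
                alpha: float = 0.05) -> tuple:
    """Bias-corrected (BC, no acceleration) bootstrap percentile interval.

    z0 is the normal quantile of the fraction of draws below the point
    estimate; the endpoints are the Phi(2*z0 +/- z_{alpha/2}) percentiles of
    the draws.  With a median-unbiased bootstrap (z0 = 0) this reduces to
    the plain percentile interval.
    """
    draws = np.asarray(draws, dtype=float)
    if len(draws) < 100:
        raise ValueError("need >= 100 bootstrap draws")
    if np.all(draws == draws[0]):
        warnings.warn("all bootstrap draws identical; degenerate interval",
                      stacklevel=2)
        return float(draws[0]), float(draws[0])
    frac = float(np.mean(draws < point_estimate))
    if frac <= 0.0 or frac >= 1.0:
        warnings.warn("point estimate outside the bootstrap distribution; "
                      "clamping bias correction", stacklevel=2)
        frac = np.clip(frac, 1.0 / (len(draws) + 1),
                       len(draws) / (len(draws) + 1.0))
    z0 = stats.norm.ppf(frac)
    zq = stats.norm.ppf(1 - alpha / 2)
    lo_q = stats.norm.cdf(2 * z0 - zq)
    hi_q = stats.norm.cdf(2 * z0 + zq)
    return (float(np.percentile(draws, 100 * lo_q)),
            float(np.percentile(draws, 100 * hi_q)))


def ceac(draws: np.ndarray, wtp_grid: np.ndarray) -> np.ndarray:
    """P(INMB > 0) over the bootstrap draws, per willingness-to-pay value.

    ``draws`` has columns (delta_c, delta_e).
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if np.any(wtp_grid < 0) or np.any(np.diff(wtp_grid) < 0):
        raise ValueError("wtp grid must be nonnegative and ascending")
    dc = draws[:, 0][None, :]
    de = draws[:, 1][None, :]
    return (wtp_grid[:, None] * de - dc > 0).mean(axis=1)


def ce_plane(draws: np.ndarray) -> dict:
    """Cost-effectiveness-plane quadrant proportions.

    x = delta_e, y = delta_c; NE = more effective & more costly, SE = more
    effective & cheaper (dominant).  Draws on an axis count toward the
    positive side.
    """
    if len(draws) == 0:
        raise ValueError("no draws")
    dc, de = draws[:, 0], draws[:, 1]
    east, north = de >= 0, dc >= 0
    n = len(draws)
    return {"NE": float((east & north).sum()) / n,
            "SE": float((east & ~north).sum()) / n,
            "NW": float((~east & north).sum()) / n,
            "SW": float((~east & ~north).sum()) / n}


@dataclass
class CEResult:
    """Bootstrap cost-effectiveness summary."""

    draws: np.ndarray                 # (B, 2): delta_c, delta_e
    point_estimates: tuple            # (delta_c, delta_e)
    delta_c_ci: tuple
    delta_e_ci: tuple
    inmb_by_threshold: dict           # wtp -> {'point', 'ci'}
    prob_ce_by_threshold: dict        # wtp -> probability
    ceac_grid: np.ndarray
    ceac_probs: np.ndarray
    quadrant_props: dict
    B: int
    seed: int
    n_pairs: int
    n_redraws: int = 0

    def summary_row(self) -> dict:
        dc, de = self.point_estimates
        row = {"n_pairs": self.n_pairs, "delta_e": de,
               "delta_e_ci_low": self.delta_e_ci[0],
               "delta_e_ci_high": self.delta_e_ci[1],
               "delta_c": dc,
               "delta_c_ci_low": self.delta_c_ci[0],
               "delta_c_ci_high": self.delta_c_ci[1]}
        for wtp, d in self.inmb_by_threshold.items():
            key = f"{int(wtp) // 1000}k"
            row[f"inmb_{key}"] = d["point"]
            row[f"inmb_{key}_ci_low"] = d["ci"][0]
            row[f"inmb_{key}_ci_high"] = d["ci"][1]
            row[f"pct_ce_{key}"] = 100.0 * self.prob_ce_by_threshold[wtp]
        return row


class _PairedArrays:
    """Pair-ordered accrual arrays for fast replicate evaluation."""

    def __init__(self, cohort: CohortTable, match: MatchResult,
                 grid: IntervalGrid, societal: bool = False,
                 treated_cost_m1_delta: float = 0.0):
        df_t, df_c = matched_arm_frames(cohort, match)
        self.arms = []
        for k, df in enumerate((df_t, df_c)):
            costs, alive, X, death = accrual_arrays(df, grid,
                                                    societal=societal)
            if k == 0 and treated_cost_m1_delta != 0.0:
                costs = costs.copy()
                costs[:, 0] += treated_cost_m1_delta
            egfr = df["egfr_result"].to_numpy()
            self.arms.append((costs, alive, X, death, egfr))
        self.n_pairs = len(df_t)
        self.grid = grid

    def estimate(self, idx: np.ndarray,
                 subgroup: str | None = None) -> tuple:
        """(delta_c, delta_e) for the pair subset ``idx``."""
        out = []
        for costs, alive, X, death, egfr in self.arms:
            sel = idx
            if subgroup is not None:
                sel = idx[egfr[idx] == subgroup]
                if len(sel) < 5 or death[sel].sum() == 0:
                    raise ValueError("degenerate subgroup replicate")
            tot = arm_estimate_arrays(costs[sel], alive[sel], X[sel],
                                      death[sel], self.grid,
                                      warn_truncate=False)
            out.append(tot)
        return (out[0].mean_cost - out[1].mean_cost,
                out[0].mean_ly - out[1].mean_ly)


def bootstrap_ce(cohort: CohortTable, match: MatchResult,
                 grid: IntervalGrid | None = None, B: int = 1000,
                 seed: int = 0, wtp_thresholds=DEFAULT_WTP,
                 ceac_grid: np.ndarray | None = None,
                 societal: bool = False,
                 treated_cost_m1_delta: float = 0.0,
                 subgroup: str | None = None) -> CEResult:
    """Paired nonparametric bootstrap of the IPCW incremental estimates.

    Matched pairs are resampled with replacement; the reverse KM censoring
    fit, the IPCW weights and the partitioned estimator are recomputed in
    every replicate.  Degenerate replicates (undefined weights or an empty
    subgroup arm) are redrawn, up to 5% of B.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if grid is None:
        grid = build_grid()
    if ceac_grid is None:
        ceac_grid = DEFAULT_CEAC_GRID
    arrays = _PairedArrays(cohort, match, grid, societal=societal,
                           treated_cost_m1_delta=treated_cost_m1_delta)
    nP = arrays.n_pairs
    rng = np.random.default_rng([seed, 55_001])
    point = arrays.estimate(np.arange(nP), subgroup=subgroup)

    draws = np.empty((B, 2))
    redraws, max_redraws = 0, max(1, int(0.05 * B))
    b = 0
    while b < B:
        idx = rng.integers(0, nP, nP)
        try:
            dc, de = arrays.estimate(idx, subgroup=subgroup)
        except ValueError:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("more than 5% of bootstrap replicates "
                                   "degenerate; cohort too small")
            continue
        draws[b] = (dc, de)
        b += 1
    if redraws:
        warnings.warn(f"{redraws} degenerate bootstrap replicate(s) redrawn",
                      stacklevel=2)

    dc_pt, de_pt = point
    probs = ceac(draws, ceac_grid)
    inmb_map, prob_map = {}, {}
    for lam in wtp_thresholds:
        per_draw = lam * draws[:, 1] - draws[:, 0]
        inmb_map[lam] = {"point": inmb(de_pt, dc_pt, lam),
                         "ci": bc_interval(per_draw, inmb(de_pt, dc_pt, lam))}
        prob_map[lam] = float(np.mean(per_draw > 0))
    return CEResult(
        draws=draws,
        point_estimates=(dc_pt, de_pt),
        delta_c_ci=bc_interval(draws[:, 0], dc_pt),
        delta_e_ci=bc_interval(draws[:, 1], de_pt),
        inmb_by_threshold=inmb_map,
        prob_ce_by_threshold=prob_map,
        ceac_grid=np.asarray(ceac_grid, float),
        ceac_probs=probs,
        quadrant_props=ce_plane(draws),
        B=B, seed=seed, n_pairs=nP, n_redraws=redraws)


# ---------------------------------------------------------------------------
# sensitivity suite

STANDARD_SCENARIOS = ("base", "replacement", "reduced_test_cost", "societal",
                      "horizon_2y", "horizon_1y", "egfr_positive",
                      "egfr_negative", "sur")


def run_sensitivity(cohort: CohortTable, match: MatchResult,
                    matching_config: MatchingConfig | None = None,
                    B: int = 1000, seed: int = 0,
                    annual_discount_rate: float = 0.015,
                    scenarios=STANDARD_SCENARIOS) -> pd.DataFrame:
    """Sensitivity-analysis grid, one summary row per scenario.

    Scenarios: matching with replacement capped at 3 uses per control
    (re-runs the genetic search), treated-arm test cost replaced by the
    single-gene cost, societal perspective (adds out-of-pocket drug costs),
    1- and 2-year horizons, EGFR-positive / -negative subgroups (each arm
    stratified by the patient's own result after matching), and the
    SUR-style joint estimator.  Subgroups below 30 pairs are flagged, not
    dropped.
    """
    base_grid = build_grid(3, annual_discount_rate)
    cm = cohort.config.cost_model if cohort.config is not None else None
    test_delta = -(cm.test_cost_treated - cm.test_cost_control) if cm \
        else -(1200.0 - 228.0)
    rows = []
    base_result = None
    for k, name in enumerate(scenarios):
        scen_seed = (seed + 1000 * (k + 1)) % (2 ** 31)
        kwargs = dict(grid=base_grid, B=B, seed=scen_seed)
        scen_match, flagged = match, False
        if name == "base":
            pass
        elif name == "replacement":
            if matching_config is None:
                raise ValueError("replacement scenario needs matching_config")
            rep_cfg = dc_replace(matching_config,
                                 replacement_mode=("capped", 3))
            scen_match = genetic_search(cohort, rep_cfg)
        elif name == "reduced_test_cost":
            kwargs["treated_cost_m1_delta"] = test_delta
        elif name == "societal":
            kwargs["societal"] = True
        elif name == "horizon_2y":
            kwargs["grid"] = build_grid(2, annual_discount_rate)
        elif name == "horizon_1y":
            kwargs["grid"] = build_grid(1, annual_discount_rate)
        elif name in ("egfr_positive", "egfr_negative"):
            kwargs["subgroup"] = name.split("_")[1]
        elif name == "sur":
            est = sur_estimates(cohort, match, base_grid)
            if base_result is None:
                base_result = bootstrap_ce(cohort, match, grid=base_grid,
                                           B=B, seed=(seed + 1000) % 2**31)
            row = {"scenario": name, **base_result.summary_row(),
                   "residual_correlation": est.residual_correlation,
                   "flagged": False}
            row["delta_c"], row["delta_e"] = est.delta_c, est.delta_e
            rows.append(row)
            continue
        else:
            raise ValueError(f"unknown scenario {name!r}")
        res = bootstrap_ce(cohort, scen_match, **kwargs)
        if name == "base":
            base_result = res
        if name.startswith("egfr"):
            sub = name.split("_")[1]
            df_t, df_c = matched_arm_frames(cohort, scen_match)
            n_sub = min((df_t["egfr_result"] == sub).sum(),
                        (df_c["egfr_result"] == sub).sum())
            flagged = bool(n_sub < 30)
        rows.append({"scenario": name, **res.summary_row(),
                     "residual_correlation": np.nan, "flagged": flagged})
    return pd.DataFrame(rows)
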