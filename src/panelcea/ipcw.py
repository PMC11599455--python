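"""Partitioned IPCW estimation of mean discounted costs and life-years.

Follow-up is split into monthly intervals; within each interval the mean
cost and survival-time accrual is estimated as a weighted mean over patients
whose follow-up fully accounts for the interval, with inverse-probability
weights 1/G(min(T, interval end)-) from the reverse Kaplan-Meier censoring
survival function.  Deceased patients keep contributing zero-accrual
observations weighted at their death time (the zero-accrual convention for
the partitioned estimator), while censored patients drop out from the
interval containing the censoring onward.  Interval means are discounted at
interval start and summed.  With no censoring all weights are 1 and the
estimator reduces exactly to the naive sample mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from panelcea.grid import DAYS_PER_YEAR, IntervalGrid
from panelcea.survival import StepSurvival, reverse_km_censoring
from panelcea.synthetic import CohortTable, N_COST_MONTHS
from panelcea.matching import MatchResult


@dataclass
class ArmTotals:
    """Per-arm partitioned IPCW estimates."""

    mean_cost: float
    mean_ly: float
    interval_cost_means: np.ndarray
    interval_ly_means: np.ndarray
    weights_summary: dict
    n: int


@dataclass
class IPCWEstimates:
    """Incremental cost/effect estimates (treated minus control)."""

    mean_cost_by_arm: dict
    mean_ly_by_arm: dict
    delta_c: float
    delta_e: float
    weights_summary: dict
    residual_correlation: float | None = None


# ---------------------------------------------------------------------------
# array extraction

def accrual_arrays(df: pd.DataFrame, grid: IntervalGrid,
                   societal: bool = False):
    """(costs, alive_days, observed_time, is_death) arrays for one arm.

    ``costs[i, j]`` is the observed payer cost in interval j (plus
    out-of-pocket costs when ``societal``); ``alive_days[i, j]`` the observed
    days alive in interval j, prorated to the event day.
    """
    J = grid.n_intervals
    if J > N_COST_MONTHS:
        raise ValueError("grid longer than available cost columns")
    cols = [f"cost_m{j:02d}" for j in range(1, J + 1)]
    costs = df[cols].to_numpy(dtype=float)
    if societal:
        oop = [f"oop_m{j:02d}" for j in range(1, J + 1)]
        costs = costs + df[oop].to_numpy(dtype=float)
    X = df["observed_time_days"].to_numpy(dtype=float)
    is_death = (df["event"] == "death").to_numpy()
    alive = np.clip(X[:, None] - grid.start_days[None, :], 0.0,
                    grid.interval_length_days)
    return costs, alive, X, is_death


def matched_arm_frames(cohort: CohortTable, match: MatchResult):
    """Treated and control data frames in matched-pair order."""
    d = cohort.data.set_index("id")
    return (d.loc[match.treated_ids()].reset_index(),
            d.loc[match.control_ids()].reset_index())


# ---------------------------------------------------------------------------
# weights and the estimator core

def ipcw_weight_matrix(X: np.ndarray, is_death: np.ndarray,
                       grid: IntervalGrid, ghat: StepSurvival):
    """Per-patient per-interval weights and inclusion mask.

    A record enters interval j only if its follow-up fully accounts for the
    interval: either the patient dies on observation (any time), or remains
    under observation through the interval end.  The weight is the inverse
    probability of that completeness, 1/G(min(T, end_j)-): deaths carry
    their death-time weight (before death, a partial-interval accrual; after
    it, a retained zero-accrual record), survivors carry 1/G(end_j-), and a
    patient censored alive inside interval j drops out from j onward.  Each
    included patient-interval contribution then has exactly mean one under
    independent censoring, which is what makes the partitioned estimator
    unbiased even when censoring falls strictly inside an interval.
    """
    ends = grid.start_days + grid.interval_length_days
    death_time = np.where(is_death, X, np.inf)
    include = is_death[:, None] | (X[:, None] > ends[None, :])
    req_time = np.minimum(death_time[:, None], ends[None, :])
    g_req = np.asarray(ghat.at_left(req_time))
    W = np.zeros_like(include, dtype=float)
    bad = include & (g_req <= 0.0)
    if np.any(bad):
        raise ValueError("G-hat reached 0 while patients remain under "
                         "observation; IPCW weights undefined")
    W[include] = 1.0 / g_req[include]
    return W, include


def ipcw_weights(df_arm: pd.DataFrame, grid: IntervalGrid,
                 ghat: StepSurvival | None = None):
    """Weights for one (matched) arm; fits the reverse KM if not supplied."""
    _, _, X, is_death = accrual_arrays(df_arm, grid)
    if ghat is None:
        ghat = reverse_km_censoring(X, np.where(is_death, "death",
                                                "censored"))
    return ipcw_weight_matrix(X, is_death, grid, ghat)


def arm_estimate_arrays(costs: np.ndarray, alive_days: np.ndarray,
                        X: np.ndarray, is_death: np.ndarray,
                        grid: IntervalGrid,
                        ghat: StepSurvival | None = None,
                        warn_truncate: bool = True) -> ArmTotals:
    """Partitioned IPCW estimate for one arm from raw arrays."""
    if ghat is None:
        ghat = reverse_km_censoring(X, is_death)
    W, include = ipcw_weight_matrix(X, is_death, grid, ghat)
    Wm = W * include
    wsum = Wm.sum(axis=0)
    empty = wsum <= 0
    if np.any(empty):
        if warn_truncate:
            warnings.warn("empty risk set before horizon; truncating "
                          f"{int(empty.sum())} interval(s)", stacklevel=2)
        wsum = np.where(empty, 1.0, wsum)
    cost_means = np.where(empty, 0.0, (Wm * costs).sum(axis=0) / wsum)
    ly_means = np.where(empty, 0.0,
                        (Wm * alive_days).sum(axis=0) / wsum) / DAYS_PER_YEAR
    wpos = W[include & (W > 0)]
    summary = {"min": float(wpos.min()) if wpos.size else np.nan,
               "max": float(wpos.max()) if wpos.size else np.nan,
               "mean": float(wpos.mean()) if wpos.size else np.nan}
    return ArmTotals(
        mean_cost=float((grid.discount_factors * cost_means).sum()),
        mean_ly=float((grid.discount_factors * ly_means).sum()),
        interval_cost_means=cost_means,
        interval_ly_means=ly_means,
        weights_summary=summary,
        n=len(X))


def weighted_totals(df_arm: pd.DataFrame, grid: IntervalGrid,
                    ghat: StepSurvival | None = None,
                    societal: bool = False) -> ArmTotals:
    """Partitioned IPCW estimate for one (matched) arm."""
    costs, alive, X, is_death = accrual_arrays(df_arm, grid,
                                               societal=societal)
    return arm_estimate_arrays(costs, alive, X, is_death, grid, ghat)


# ---------------------------------------------------------------------------
# incremental estimates

def incremental_estimates(totals_treated: ArmTotals,
                          totals_control: ArmTotals) -> IPCWEstimates:
    """Incremental cost and life-years: treated minus control."""
    return IPCWEstimates(
        mean_cost_by_arm={"treated": totals_treated.mean_cost,
                          "control": totals_control.mean_cost},
        mean_ly_by_arm={"treated": totals_treated.mean_ly,
                        "control": totals_control.mean_ly},
        delta_c=totals_treated.mean_cost - totals_control.mean_cost,
        delta_e=totals_treated.mean_ly - totals_control.mean_ly,
        weights_summary={"treated": totals_treated.weights_summary,
                         "control": totals_control.weights_summary})


def wls_incremental(df_t: pd.DataFrame, df_c: pd.DataFrame,
                    grid: IntervalGrid, societal: bool = False):
    """IPCW weighted linear regression path for (delta_c, delta_e).

    For each interval, regresses the interval accrual on the arm indicator
    by WLS with the IPCW weights; the treatment coefficients, discounted and
    summed over intervals, are algebraically identical to the
    difference-of-weighted-means path.
    """
    parts = []
    for df in (df_t, df_c):
        costs, alive, X, is_death = accrual_arrays(df, grid,
                                                   societal=societal)
        ghat = reverse_km_censoring(X, is_death)
        W, include = ipcw_weight_matrix(X, is_death, grid, ghat)
        parts.append((costs, alive, W * include, include))
    delta_c = delta_e = 0.0
    for j in range(grid.n_intervals):
        y_c, y_e, w, arm = [], [], [], []
        for a, (costs, alive, Wm, include) in enumerate(parts):
            m = include[:, j] & (Wm[:, j] > 0)
            y_c.append(costs[m, j])
            y_e.append(alive[m, j] / DAYS_PER_YEAR)
            w.append(Wm[m, j])
            arm.append(np.full(int(m.sum()), 1.0 - a))  # parts[0]=treated
        y_c, y_e = np.concatenate(y_c), np.concatenate(y_e)
        w, arm = np.concatenate(w), np.concatenate(arm)
        if len(np.unique(arm)) < 2:
            continue
        Xd = sm.add_constant(arm)
        d = grid.discount_factors[j]
        delta_c += d * float(sm.WLS(y_c, Xd, weights=w).fit().params[1])
        delta_e += d * float(sm.WLS(y_e, Xd, weights=w).fit().params[1])
    return delta_c, delta_e


def estimate_matched(cohort: CohortTable, match: MatchResult,
                     grid: IntervalGrid, societal: bool = False,
                     check_regression_path: bool = False) -> IPCWEstimates:
    """Full IPCW incremental estimate on a matched cohort.

    The censoring distribution is estimated per arm (the two arms may censor
    at different rates).  When ``check_regression_path`` is set, the
    weighted-regression formulation is also computed and asserted equal to
    the difference-of-weighted-means path.
    """
    df_t, df_c = matched_arm_frames(cohort, match)
    tot_t = weighted_totals(df_t, grid, societal=societal)
    tot_c = weighted_totals(df_c, grid, societal=societal)
    est = incremental_estimates(tot_t, tot_c)
    if check_regression_path:
        dc, de = wls_incremental(df_t, df_c, grid, societal=societal)
        scale_c = max(abs(est.delta_c), 1.0)
        if (abs(dc - est.delta_c) > 1e-8 * scale_c
                or abs(de - est.delta_e) > 1e-10):
            raise AssertionError(
                "regression and weighted-means paths disagree: "
                f"{dc} vs {est.delta_c}, {de} vs {est.delta_e}")
    return est


# ---------------------------------------------------------------------------
# seemingly unrelated regression variant

def sur_estimates(cohort: CohortTable, match: MatchResult,
                  grid: IntervalGrid, societal: bool = False) -> IPCWEstimates:
    """Joint cost/survival estimation with cross-equation residual correlation.

    Both equations share the same regressors (intercept + arm indicator) and
    the same IPCW weights, so the feasible-GLS point estimates coincide with
    the equation-by-equation results (Kruskal's theorem); they are computed
    that way, and the cross-equation residual correlation is estimated from
    patients with complete follow-up within the horizon (death observed or
    followed to the horizon), as the informative summary the joint model
    adds.
    """
    est = estimate_matched(cohort, match, grid, societal=societal)
    df_t, df_c = matched_arm_frames(cohort, match)
    resid_c, resid_e = [], []
    for df in (df_t, df_c):
        costs, alive, X, is_death = accrual_arrays(df, grid,
                                                   societal=societal)
        complete = is_death | (X >= grid.horizon_days)
        if complete.sum() < 3:
            continue
        y_c = (costs[complete] * grid.discount_factors).sum(axis=1)
        y_e = (alive[complete] * grid.discount_factors).sum(axis=1) \
            / DAYS_PER_YEAR
        resid_c.append(y_c - y_c.mean())
        resid_e.append(y_e - y_e.mean())
    rho = None
    if resid_c:
        rc = np.concatenate(resid_c)
        re = np.concatenate(resid_e)
        if rc.std() > 0 and re.std() > 0:
            rho = float(np.corrcoef(rc, re)[0, 1])
    est.residual_correlation = rho
    return est
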