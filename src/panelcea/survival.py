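"""Survival estimation: Kaplan-Meier (forward and reverse), log-rank test,
and Weibull proportional-hazards regression.

The product-limit estimator is implemented explicitly because the IPCW
weights downstream need (a) a deaths-before-censorings tie convention --
patients dying at t remain in the censoring risk set through t -- and (b)
left-limit evaluation G(t-).  Both conventions follow from computing risk
sets as {X_i >= t} and treating the configured event type as occurring
first at tied times.  The log-rank test and the Weibull fit are delegated
to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import WeibullAFTFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from panelcea.grid import DAYS_PER_YEAR

EVENT_DEATH = "death"
EVENT_CENSORED = "censored"


@dataclass
class StepSurvival:
    """Right-continuous product-limit step function.

    ``times`` are the distinct event times (ascending); ``surv`` the value of
    the step function at those times; ``greenwood_var`` the Greenwood
    variance of S at each time.
    """

    times: np.ndarray
    surv: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    greenwood_var: np.ndarray

    def at(self, t) -> np.ndarray | float:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right")
        vals = np.concatenate([[1.0], self.surv])[idx]
        return vals if np.ndim(t) else float(vals)

    def at_left(self, t) -> np.ndarray | float:
        """S(t-), the left limit (excludes events exactly at t)."""
        idx = np.searchsorted(self.times, np.asarray(t, float), side="left")
        vals = np.concatenate([[1.0], self.surv])[idx]
        return vals if np.ndim(t) else float(vals)

    def restricted_mean(self, horizon_days: float) -> float:
        """Area under the step function on [0, horizon]."""
        t = np.concatenate([[0.0], self.times, [np.inf]])
        s = np.concatenate([[1.0], self.surv])
        area = 0.0
        for k in range(len(s)):
            lo = min(t[k], horizon_days)
            hi = min(t[k + 1], horizon_days)
            area += s[k] * (hi - lo)
        return area

    def restricted_mean_ci(self, horizon_days: float,
                           alpha: float = 0.05) -> tuple:
        """Restricted mean with its standard large-sample 95% CI."""
        rmst = self.restricted_mean(horizon_days)
        mask = (self.times <= horizon_days) & (self.n_event > 0)
        var = 0.0
        for tk, nk, dk in zip(self.times[mask], self.n_risk[mask],
                              self.n_event[mask]):
            if nk > dk:
                tail = self._tail_area(tk, horizon_days)
                var += tail ** 2 * dk / (nk * (nk - dk))
        z = stats.norm.ppf(1 - alpha / 2)
        se = np.sqrt(var)
        return rmst, (rmst - z * se, rmst + z * se)

    def _tail_area(self, t0: float, horizon: float) -> float:
        t = np.concatenate([[0.0], self.times, [np.inf]])
        s = np.concatenate([[1.0], self.surv])
        area = 0.0
        for k in range(len(s)):
            lo = max(min(t[k], horizon), t0)
            hi = max(min(t[k + 1], horizon), t0)
            area += s[k] * (hi - lo)
        return area

    def median(self, alpha: float = 0.05) -> tuple:
        """Median survival with a log(-log) transformed CI."""
        z = stats.norm.ppf(1 - alpha / 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.log(self.surv)
            se_theta = np.where(
                (self.surv > 0) & (self.surv < 1),
                np.sqrt(self.greenwood_var) / (np.abs(logs) * self.surv),
                np.inf)
            lower = self.surv ** np.exp(z * se_theta)
            upper = self.surv ** np.exp(-z * se_theta)

        def first_crossing(vals):
            idx = np.flatnonzero(vals <= 0.5)
            return float(self.times[idx[0]]) if len(idx) else np.nan

        return first_crossing(self.surv), (first_crossing(upper),
                                           first_crossing(lower))


def _product_limit(times: np.ndarray, is_event: np.ndarray) -> StepSurvival:
    times = np.asarray(times, dtype=float)
    is_event = np.asarray(is_event, dtype=bool)
    if len(times) == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    uniq = np.unique(times[is_event])
    n_risk = np.array([(times >= t).sum() for t in uniq], dtype=float)
    n_event = np.array([((times == t) & is_event).sum() for t in uniq],
                       dtype=float)
    frac = 1.0 - n_event / n_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n_risk > n_event,
                       n_event / (n_risk * (n_risk - n_event)), np.inf)
        gvar = surv ** 2 * np.cumsum(inc)
    gvar = np.where(np.isfinite(gvar), gvar, 0.0)
    return StepSurvival(times=uniq, surv=surv, n_risk=n_risk,
                        n_event=n_event, greenwood_var=gvar)


def kaplan_meier(times, events) -> StepSurvival:
    """Product-limit estimate of overall survival with Greenwood variance.

    ``events`` is an array of 'death' / 'censored' (or booleans, True =
    death).  At tied times deaths are processed before censorings.
    """
    is_death = _event_bool(events)
    return _product_limit(times, is_death)


def reverse_km_censoring(times, events) -> StepSurvival:
    """Product-limit estimate G(t) of remaining uncensored.

    Censoring is the event; deaths at t remain in the censoring risk set
    through t (deaths-first tie convention), which the {X_i >= t} risk-set
    definition provides automatically.
    """
    is_death = _event_bool(events)
    return _product_limit(times, ~is_death)


def _event_bool(events) -> np.ndarray:
    ev = np.asarray(events)
    if ev.dtype == bool:
        return ev
    out = np.zeros(len(ev), dtype=bool)
    for k, e in enumerate(ev):
        if e == EVENT_DEATH:
            out[k] = True
        elif e != EVENT_CENSORED:
            raise ValueError(f"unknown event code {e!r}")
    return out


def log_rank_test(times, events, arm) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square statistic, p-value)."""
    is_death = _event_bool(events)
    arm = np.asarray(arm)
    groups = np.unique(arm)
    if len(groups) != 2:
        raise ValueError("log-rank test needs exactly two arms")
    a = arm == groups[0]
    if is_death[a].sum() == 0 or is_death[~a].sum() == 0:
        raise ValueError("each arm needs at least one event")
    res = _ll_logrank(np.asarray(times)[a], np.asarray(times)[~a],
                      event_observed_A=is_death[a],
                      event_observed_B=is_death[~a])
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class WeibullFit:
    """Weibull PH fit: hr < 1 favours the treated arm."""

    shape: float
    scale: float
    log_hr_treatment: float
    hr: float
    hr_ci_95: tuple
    loglik: float


def weibull_ph_fit(times, events, treatment_indicator) -> WeibullFit:
    """Weibull regression of survival on the treatment indicator.

    Fits the AFT parametrisation by maximum likelihood (lifelines) and
    converts to proportional hazards: log HR = -shape * beta_AFT, with a
    delta-method Wald 95% CI accounting for the (beta, log shape)
    covariance.
    """
    is_death = _event_bool(events)
    z = np.asarray(treatment_indicator, dtype=float)
    for g in (0.0, 1.0):
        if is_death[z == g].sum() < 10:
            raise ValueError("need >= 10 events per arm for a stable fit")
    df = pd.DataFrame({"T": np.asarray(times, float), "E": is_death.astype(int),
                       "treatment": z})
    aft = WeibullAFTFitter()
    aft.fit(df, duration_col="T", event_col="E")   # ConvergenceError surfaces
    beta = float(aft.params_[("lambda_", "treatment")])
    beta0 = float(aft.params_[("lambda_", "Intercept")])
    log_rho = float(aft.params_[("rho_", "Intercept")])
    rho = np.exp(log_rho)
    log_hr = -rho * beta
    V = aft.variance_matrix_
    vb = float(V.loc[("lambda_", "treatment"), ("lambda_", "treatment")])
    vs = float(V.loc[("rho_", "Intercept"), ("rho_", "Intercept")])
    cbs = float(V.loc[("lambda_", "treatment"), ("rho_", "Intercept")])
    # gradient of -exp(s)*beta wrt (beta, s=log rho)
    g_b, g_s = -rho, -rho * beta
    se = np.sqrt(g_b * g_b * vb + g_s * g_s * vs + 2 * g_b * g_s * cbs)
    zq = stats.norm.ppf(0.975)
    return WeibullFit(
        shape=rho,
        scale=float(np.exp(beta0)),
        log_hr_treatment=log_hr,
        hr=float(np.exp(log_hr)),
        hr_ci_95=(float(np.exp(log_hr - zq * se)),
                  float(np.exp(log_hr + zq * se))),
        loglik=float(aft.log_likelihood_),
    )


def censoring_fraction(events) -> float:
    return float((~_event_bool(events)).mean())


def mean_survival_restricted(times, events,
                             horizon_days: float = 3 * DAYS_PER_YEAR) -> tuple:
    """KM restricted mean survival (days) with 95% CI over [0, horizon]."""
    km = kaplan_meier(times, events)
    return km.restricted_mean_ci(horizon_days)
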