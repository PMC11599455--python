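"""Synthetic administrative cohort generator with a known-truth oracle.

Emulates a two-arm observational cohort of advanced-NSCLC patients in which
the treated arm received multi-gene panel sequencing and the control arm
single-gene EGFR testing: confounded treatment assignment (logistic model on
baseline covariates), Weibull proportional-hazards survival with a small
treatment effect, censoring from staggered accrual + an administrative cutoff
+ exponential dropout, and monthly cost accrual with systemic-therapy
dominance, an end-of-life spike attached to the death date, and a per-test
cost charged in month 1 ($1200 treated vs $228 control).

Because assignment, survival and costs are all known functions of the same
configuration, :func:`true_estimands` can compute the censoring-free truth by
brute-force simulation, giving every downstream estimator an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from panelcea.grid import DAYS_PER_MONTH, DAYS_PER_YEAR, build_grid

N_COST_MONTHS = 36


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate.

    kind is 'continuous', 'binary' or 'categorical'; params hold the
    distribution parameters:

    - continuous: {'dist': 'normal', 'mean', 'sd'} or
      {'dist': 'lognormal', 'mean_log', 'sd_log'}
    - binary: {'p': ...}
    - categorical: {'levels': [...], 'probs': [...]}

    exact_match marks covariates on which matching is constrained to be exact.
    """

    name: str
    kind: str
    params: dict
    exact_match: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "binary" and not 0.0 <= self.params["p"] <= 1.0:
            raise ValueError(f"{self.name}: p must be in [0,1]")
        if self.kind == "categorical":
            if len(self.params["levels"]) < 2:
                raise ValueError(f"{self.name}: categorical needs >= 2 levels")
            probs = np.asarray(self.params["probs"], dtype=float)
            if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"{self.name}: probs must sum to 1")


@dataclass(frozen=True)
class CensoringModel:
    """Staggered accrual, administrative cutoff and random dropout.

    Patients enter uniformly over ``accrual_window_days``; follow-up ends at
    ``admin_cutoff_days`` after the start of accrual, capped at
    ``max_followup_days`` per patient; independent dropout is exponential
    with rate ``dropout_rate_per_year``.
    """

    accrual_window_days: float = 852.0
    admin_cutoff_days: float = 1217.0
    dropout_rate_per_year: float = 0.12
    max_followup_days: float = 36 * DAYS_PER_MONTH  # 3 years

    def __post_init__(self) -> None:
        if self.admin_cutoff_days < self.accrual_window_days:
            raise ValueError("admin_cutoff_days must be >= accrual_window_days")
        if self.dropout_rate_per_year < 0:
            raise ValueError("dropout_rate_per_year must be >= 0")


@dataclass(frozen=True)
class CostModel:
    """Monthly cost accrual model (2021 CAD).

    Baseline monthly costs are lognormal with a patient-level random effect
    tied to the observed baseline-cost covariate; systemic therapy adds a
    fixed monthly amount for patients on therapy (arm-specific uptake); a
    terminal-care spike of ``eol_spike_cost`` is spread over the last
    ``eol_spike_months`` months before death; the per-test cost enters
    month 1 unprorated.  Out-of-pocket drug costs are generated separately
    for the societal-perspective sensitivity analysis.
    """

    baseline_monthly_mean_log: float = 7.4      # exp(7.4) ~ $1636/month
    baseline_monthly_sd_log: float = 0.9
    systemic_therapy_monthly_cost: float = 4000.0
    systemic_therapy_uptake_by_arm: dict = field(
        default_factory=lambda: {"treated": 0.55, "control": 0.50})
    eol_spike_cost: float = 15000.0
    eol_spike_months: int = 2
    test_cost_treated: float = 1200.0
    test_cost_control: float = 228.0
    oop_monthly_mean_log: float = 5.0           # exp(5) ~ $148/month
    oop_monthly_sd_log: float = 1.0

    def __post_init__(self) -> None:
        if self.eol_spike_months < 1:
            raise ValueError("eol_spike_months must be >= 1")
        for p in self.systemic_therapy_uptake_by_arm.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("uptake probabilities must be in [0,1]")


@dataclass(frozen=True)
class CohortConfig:
    """Full data-generating configuration for one synthetic cohort."""

    n_patients: int
    treated_fraction_target: float
    covariate_specs: tuple
    assignment_coefficients: dict
    survival_coefficients: dict
    weibull_shape: float
    weibull_scale_control: float
    treatment_log_hazard_ratio: float
    censoring: CensoringModel
    cost_model: CostModel
    egfr_result_probs_by_arm: dict
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.treated_fraction_target < 1.0:
            raise ValueError("treated_fraction_target must be in (0,1)")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be > 0")
        if self.weibull_scale_control <= 0:
            raise ValueError("weibull_scale_control must be > 0")
        for arm, probs in self.egfr_result_probs_by_arm.items():
            if not math.isclose(sum(probs.values()), 1.0, abs_tol=1e-9):
                raise ValueError(f"egfr result probs for {arm} must sum to 1")

    def exact_match_names(self) -> list:
        return [s.name for s in self.covariate_specs if s.exact_match]


def default_config(n_patients: int = 2172, seed: int = 0,
                   **overrides) -> CohortConfig:
    """Default configuration emulating the study cohort.

    2172 patients, 43.2% treated, covariates with the structure of the
    study's baseline table (age ~ N(69, 10), binary sex, long-tailed days
    since diagnosis, categorical cancer sites and prior therapy lines,
    binary prior surgery and health-authority residence, skewed baseline
    costs), confounded assignment producing pre-match imbalance
    concentrated on prior surgery, region and prior therapy lines, Weibull
    survival with HR 0.932 favouring the treated arm, and 26-32% censoring.
    """
    specs = (
        CovariateSpec("age", "continuous", {"dist": "normal",
                                            "mean": 69.0, "sd": 10.0}),
        CovariateSpec("sex_male", "binary", {"p": 0.45}),
        CovariateSpec("days_since_diagnosis", "continuous",
                      {"dist": "lognormal", "mean_log": 4.35, "sd_log": 1.2}),
        CovariateSpec("n_cancer_sites", "categorical",
                      {"levels": ["1", "2", "3plus"],
                       "probs": [0.69, 0.22, 0.09]}),
        CovariateSpec("prior_lines", "categorical",
                      {"levels": ["0", "1", "2plus"],
                       "probs": [0.84, 0.14, 0.02]},
                      exact_match=True),
        CovariateSpec("prior_surgery", "binary", {"p": 0.085},
                      exact_match=True),
        CovariateSpec("region_vch", "binary", {"p": 0.20}, exact_match=True),
        CovariateSpec("baseline_cost", "continuous",
                      {"dist": "lognormal", "mean_log": 7.9, "sd_log": 1.3}),
    )
    assignment = {
        "age": -0.016,
        "days_since_diagnosis_log": 0.15,
        "prior_lines=1": 0.45,
        "prior_lines=2plus": 0.55,
        "prior_surgery": 0.95,
        "region_vch": 0.62,
    }
    survival = {
        "age": 0.02,             # per year above 69
        "prior_lines=1": 0.20,
        "prior_lines=2plus": 0.35,
        "prior_surgery": -0.25,
        "baseline_cost_log": 0.15,   # per unit of centred log baseline cost
    }
    egfr = {
        "treated": {"positive": 0.209, "negative": 0.749,
                    "inconclusive": 0.042},
        "control": {"positive": 0.205, "negative": 0.646,
                    "inconclusive": 0.149},
    }
    cfg = dict(
        n_patients=n_patients,
        treated_fraction_target=0.432,
        covariate_specs=specs,
        assignment_coefficients=assignment,
        survival_coefficients=survival,
        weibull_shape=0.8,
        weibull_scale_control=390.0,
        treatment_log_hazard_ratio=math.log(0.932),
        censoring=CensoringModel(),
        cost_model=CostModel(),
        egfr_result_probs_by_arm=egfr,
        seed=seed,
    )
    cfg.update(overrides)
    return CohortConfig(**cfg)


@dataclass
class CohortTable:
    """One simulated (or loaded) cohort.

    ``data`` has one row per patient with columns: id, arm ('treated' /
    'control'), the covariates, survival_time_days, censor_time_days,
    observed_time_days, event ('death' / 'censored'), egfr_result and wide
    monthly cost columns cost_m01..cost_m36 (payer perspective, accrued over
    observed months only) and oop_m01..oop_m36 (out-of-pocket drug costs for
    the societal perspective).
    """

    data: pd.DataFrame
    covariate_specs: tuple
    config: CohortConfig | None = None

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def arm_bool(self) -> np.ndarray:
        return (self.data["arm"] == "treated").to_numpy()

    def covariate_names(self) -> list:
        return [s.name for s in self.covariate_specs]

    def cost_matrix(self, societal: bool = False) -> np.ndarray:
        cols = [f"cost_m{j:02d}" for j in range(1, N_COST_MONTHS + 1)]
        c = self.data[cols].to_numpy(dtype=float)
        if societal:
            oop = [f"oop_m{j:02d}" for j in range(1, N_COST_MONTHS + 1)]
            c = c + self.data[oop].to_numpy(dtype=float)
        return c


@dataclass(frozen=True)
class TrueEstimands:
    """Censoring-free truth from oracle simulation."""

    true_mean_discounted_cost_by_arm: dict
    true_mean_discounted_ly_by_arm: dict
    true_delta_c: float
    true_delta_e: float
    true_hazard_ratio: float


# ---------------------------------------------------------------------------
# covariate drawing and design matrices

def _draw_covariates(specs, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for s in specs:
        if s.kind == "continuous":
            p = s.params
            if p["dist"] == "normal":
                cols[s.name] = rng.normal(p["mean"], p["sd"], n)
            elif p["dist"] == "lognormal":
                cols[s.name] = rng.lognormal(p["mean_log"], p["sd_log"], n)
            else:
                raise ValueError(f"unknown distribution {p['dist']!r}")
        elif s.kind == "binary":
            cols[s.name] = (rng.random(n) < s.params["p"]).astype(float)
        else:
            cols[s.name] = rng.choice(s.params["levels"], size=n,
                                      p=s.params["probs"])
    return pd.DataFrame(cols)


def design_matrix(cov: pd.DataFrame, specs) -> tuple[np.ndarray, list]:
    """One-hot expand covariates (categoricals drop the reference level).

    Dummy columns are named ``<name>=<level>``; continuous and binary
    covariates keep their own names.  Returns (matrix, column names).
    """
    cols, names = [], []
    for s in specs:
        if s.kind == "categorical":
            levels = s.params["levels"]
            for lev in levels[1:]:
                cols.append((cov[s.name].to_numpy() == lev).astype(float))
                names.append(f"{s.name}={lev}")
        else:
            cols.append(cov[s.name].to_numpy(dtype=float))
            names.append(s.name)
    return np.column_stack(cols), names


def _linear_predictor(cov: pd.DataFrame, specs, coefficients: dict,
                      centre: bool = False) -> np.ndarray:
    """Sum of coefficient * design column, plus optional derived terms.

    A key ``<name>_log`` refers to the centred log of a positive covariate
    (confounding on the quantile scale of a skewed covariate, preserving
    tail overlap between arms); ``age`` is centred at its sample mean when
    ``centre`` is True (survival model) and used raw otherwise (assignment
    model, whose intercept is solved for separately anyway).
    """
    X, names = design_matrix(cov, specs)
    lp = np.zeros(len(cov))
    for key, beta in coefficients.items():
        if key.endswith("_log") and key[:-4] in cov.columns:
            x = np.log(cov[key[:-4]].to_numpy(dtype=float))
            lp += beta * (x - x.mean())
            continue
        if key not in names:
            raise KeyError(f"coefficient for unknown design column {key!r}")
        x = X[:, names.index(key)]
        if centre:
            x = x - x.mean()
        lp += beta * x
    return lp


# ---------------------------------------------------------------------------
# simulation pieces

def _assign_treatment(cov, specs, config, rng) -> np.ndarray:
    lp = _linear_predictor(cov, specs, config.assignment_coefficients)
    target = config.treated_fraction_target
    if np.allclose(lp, lp[0]):
        intercept = math.log(target / (1 - target)) - lp[0]
    else:
        intercept = brentq(lambda a: expit(a + lp).mean() - target, -30, 30)
    return rng.random(len(cov)) < expit(intercept + lp)


def _draw_survival(cov, specs, config, treated, rng) -> np.ndarray:
    """Weibull PH: S(t|x) = exp(-(t/scale)^shape * exp(lp))."""
    lp = _linear_predictor(cov, specs, config.survival_coefficients,
                           centre=True)
    lp = lp + config.treatment_log_hazard_ratio * treated.astype(float)
    e = rng.exponential(1.0, len(cov))
    k = config.weibull_shape
    return config.weibull_scale_control * (e / np.exp(lp)) ** (1.0 / k)


def _draw_censoring(config, n, rng) -> np.ndarray:
    cm = config.censoring
    entry = rng.uniform(0.0, cm.accrual_window_days, n)
    admin = np.minimum(cm.admin_cutoff_days - entry, cm.max_followup_days)
    if cm.dropout_rate_per_year > 0:
        dropout = rng.exponential(
            DAYS_PER_YEAR / cm.dropout_rate_per_year, n)
    else:
        dropout = np.full(n, np.inf)
    return np.minimum(admin, dropout)


def _interval_fraction(upper: np.ndarray) -> np.ndarray:
    """Fraction of each of the 36 months covered by [0, upper_i]."""
    starts = np.arange(N_COST_MONTHS) * DAYS_PER_MONTH
    return np.clip((upper[:, None] - starts[None, :]) / DAYS_PER_MONTH,
                   0.0, 1.0)


def _window_overlap(w0: np.ndarray, w1: np.ndarray) -> np.ndarray:
    """Per-month overlap fraction of the patient windows [w0_i, w1_i]."""
    starts = np.arange(N_COST_MONTHS) * DAYS_PER_MONTH
    ends = starts + DAYS_PER_MONTH
    lo = np.maximum(starts[None, :], w0[:, None])
    hi = np.minimum(ends[None, :], w1[:, None])
    return np.clip(hi - lo, 0.0, None) / DAYS_PER_MONTH


def _draw_costs(cov, config, treated, death_time, observed_time, rng):
    """Payer-perspective and out-of-pocket monthly cost matrices (n, 36).

    Costs accrue only over observed months; the month containing the event
    contributes a prorated fraction.  The end-of-life spike attaches to the
    death date, so a patient censored before death has the (remaining) spike
    unobserved -- inducing a positive cost-censoring correlation.
    """
    cm = config.cost_model
    n = len(cov)

    if "baseline_cost" in cov.columns:
        lx = np.log(cov["baseline_cost"].to_numpy(dtype=float))
        patient_effect = 0.5 * (lx - lx.mean())
    else:
        patient_effect = np.zeros(n)
    eps = rng.normal(0.0, 1.0, (n, N_COST_MONTHS))
    base = np.exp(cm.baseline_monthly_mean_log + patient_effect[:, None]
                  + cm.baseline_monthly_sd_log * eps)

    p_uptake = np.where(treated,
                        cm.systemic_therapy_uptake_by_arm["treated"],
                        cm.systemic_therapy_uptake_by_arm["control"])
    on_therapy = rng.random(n) < p_uptake
    monthly = base + on_therapy[:, None] * cm.systemic_therapy_monthly_cost

    obs_frac = _interval_fraction(observed_time)
    costs = monthly * obs_frac

    # end-of-life spike: window of eol_spike_months ending at death,
    # truncated to the observed period
    w0 = np.maximum(death_time - cm.eol_spike_months * DAYS_PER_MONTH, 0.0)
    w1 = np.minimum(death_time, observed_time)
    spike_rate = cm.eol_spike_cost / (cm.eol_spike_months * DAYS_PER_MONTH)
    costs += spike_rate * _window_overlap(w0, w1) * DAYS_PER_MONTH

    costs[:, 0] += np.where(treated, cm.test_cost_treated,
                            cm.test_cost_control)

    oop_eps = rng.normal(0.0, 1.0, (n, N_COST_MONTHS))
    oop = np.exp(cm.oop_monthly_mean_log
                 + cm.oop_monthly_sd_log * oop_eps) * obs_frac
    return costs, oop


def _draw_egfr(config, treated, rng) -> np.ndarray:
    out = np.empty(len(treated), dtype=object)
    for arm, mask in (("treated", treated), ("control", ~treated)):
        probs = config.egfr_result_probs_by_arm[arm]
        levels = list(probs.keys())
        out[mask] = rng.choice(levels, size=int(mask.sum()),
                               p=[probs[k] for k in levels])
    return out


def _simulate(config: CohortConfig, rng: np.random.Generator,
              forced_arm: bool | None = None,
              censoring_enabled: bool = True) -> pd.DataFrame:
    n = config.n_patients
    cov = _draw_covariates(config.covariate_specs, n, rng)
    if forced_arm is None:
        treated = _assign_treatment(cov, config.covariate_specs, config, rng)
    else:
        treated = np.full(n, bool(forced_arm))
    death = _draw_survival(cov, config.covariate_specs, config, treated, rng)
    if censoring_enabled:
        censor = _draw_censoring(config, n, rng)
    else:
        censor = np.full(n, np.inf)
    observed = np.minimum(death, censor)
    is_death = death <= censor
    costs, oop = _draw_costs(cov, config, treated, death, observed, rng)
    egfr = _draw_egfr(config, treated, rng)

    df = cov.copy()
    df.insert(0, "id", np.arange(n))
    df.insert(1, "arm", np.where(treated, "treated", "control"))
    df["survival_time_days"] = death
    df["censor_time_days"] = censor
    df["observed_time_days"] = observed
    df["event"] = np.where(is_death, "death", "censored")
    df["egfr_result"] = egfr
    for j in range(N_COST_MONTHS):
        df[f"cost_m{j + 1:02d}"] = costs[:, j]
    for j in range(N_COST_MONTHS):
        df[f"oop_m{j + 1:02d}"] = oop[:, j]
    return df


# ---------------------------------------------------------------------------
# public API

def generate_cohort(config: CohortConfig) -> CohortTable:
    """Simulate one cohort; deterministic given ``config.seed``."""
    if config.n_patients < 20:
        raise ValueError("n_patients must be >= 20 (too small to match)")
    rng = np.random.default_rng(config.seed)
    df = _simulate(config, rng)
    n_treated = int((df["arm"] == "treated").sum())
    if min(n_treated, config.n_patients - n_treated) < 10:
        raise ValueError(
            "degenerate cohort: assignment model left an arm with < 10 "
            f"patients (treated={n_treated})")
    return CohortTable(data=df, covariate_specs=config.covariate_specs,
                       config=config)


def true_estimands(config: CohortConfig, n_oracle: int = 100_000,
                   horizon_years: int = 3,
                   annual_discount_rate: float = 0.015) -> TrueEstimands:
    """Censoring-free truth by brute-force simulation of each arm.

    Simulates ``n_oracle`` patients per arm with treatment forced and
    censoring disabled, and accumulates discounted costs and life-years on
    the same monthly grid and with the same interval-start discounting used
    by the IPCW estimator.
    """
    if n_oracle < 10_000:
        raise ValueError("n_oracle must be >= 10^4 for a usable oracle")
    g = build_grid(horizon_years, annual_discount_rate)
    rng = np.random.default_rng([config.seed, 918273])
    oracle_cfg = replace(config, n_patients=n_oracle)
    cost_by_arm, ly_by_arm = {}, {}
    for arm, forced in (("control", False), ("treated", True)):
        df = _simulate(oracle_cfg, rng, forced_arm=forced,
                       censoring_enabled=False)
        cols = [f"cost_m{j:02d}" for j in range(1, g.n_intervals + 1)]
        costs = df[cols].to_numpy(dtype=float)
        t = df["survival_time_days"].to_numpy()
        alive = np.clip((t[:, None] - g.start_days[None, :]), 0.0,
                        g.interval_length_days)
        cost_by_arm[arm] = float(
            (costs * g.discount_factors[None, :]).sum(axis=1).mean())
        ly_by_arm[arm] = float(
            (alive * g.discount_factors[None, :]).sum(axis=1).mean()
            / DAYS_PER_YEAR)
    return TrueEstimands(
        true_mean_discounted_cost_by_arm=cost_by_arm,
        true_mean_discounted_ly_by_arm=ly_by_arm,
        true_delta_c=cost_by_arm["treated"] - cost_by_arm["control"],
        true_delta_e=ly_by_arm["treated"] - ly_by_arm["control"],
        true_hazard_ratio=math.exp(config.treatment_log_hazard_ratio),
    )
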