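"""Covariate balance diagnostics for matched two-arm cohorts.

Reports absolute standardized mean differences (SMD), matched variance
ratios and Kolmogorov-Smirnov statistics per covariate (plus squared-age and
age x sex interaction terms), before and after matching.  The reference SD
for the SMD is the pooled pre-match standard deviation, held fixed
post-match so pre/post values are comparable; binary covariates use
sqrt(p(1-p)) from the pooled pre-match proportion.  The conventional
adequacy thresholds are SMD < 0.1 and variance ratio < 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from panelcea.matching import MatchingConfig, MatchingData, MatchResult, ks_boot
from panelcea.synthetic import CohortTable

SMD_THRESHOLD = 0.1
VR_THRESHOLD = 2.0


def standardized_mean_difference(x_t: np.ndarray, x_c: np.ndarray,
                                 sd_ref: float) -> float:
    """|mean(x_t) - mean(x_c)| / sd_ref with a fixed reference SD."""
    x_t = np.asarray(x_t, dtype=float)
    x_c = np.asarray(x_c, dtype=float)
    delta = abs(x_t.mean() - x_c.mean())
    if sd_ref == 0:
        if delta == 0:
            return 0.0
        raise ValueError("sd_ref is 0 with unequal means: incomparable")
    if sd_ref < 0:
        raise ValueError("sd_ref must be positive")
    return delta / sd_ref


def variance_ratio(x_t: np.ndarray, x_c: np.ndarray) -> float:
    """Orientation-free variance ratio max(r, 1/r), r = var_t / var_c."""
    vt = np.asarray(x_t, dtype=float).var(ddof=1)
    vc = np.asarray(x_c, dtype=float).var(ddof=1)
    if vt == 0 or vc == 0:
        raise ValueError("variance ratio undefined with zero variance")
    r = vt / vc
    return max(r, 1.0 / r)


def pooled_reference_sd(x_t: np.ndarray, x_c: np.ndarray,
                        binary: bool = False) -> float:
    """Pooled pre-match reference SD (binary: sqrt(p(1-p)) of pooled p)."""
    pooled = np.concatenate([np.asarray(x_t, float), np.asarray(x_c, float)])
    if binary:
        p = pooled.mean()
        return float(np.sqrt(p * (1 - p)))
    return float(pooled.std(ddof=1))


def balance_report(cohort: CohortTable, match: MatchResult,
                   config: MatchingConfig | None = None,
                   ks_boot_reps: int = 300) -> pd.DataFrame:
    """Balance table over covariates and polynomial/interaction terms.

    One row per balance term with columns: kind, smd_unmatched, smd_matched,
    variance_ratio_matched (continuous only), ks_stat / ks_p_matched
    (continuous only), and a ``flag`` marking SMD >= 0.1 or variance
    ratio >= 2 after matching.
    """
    if match.n_matched == 0:
        raise ValueError("empty match")
    if config is None:
        config = MatchingConfig()
    data = MatchingData(cohort, config)
    id_pos = {int(i): k for k, i in enumerate(data.ids)}
    ti = np.array([id_pos[t] for t, _ in match.pairs])
    ci = np.array([id_pos[c] for _, c in match.pairs])
    tr_mask = data.treated_mask
    rng = np.random.default_rng([config.seed, 7_003])

    rows = []
    for k, (name, kind) in enumerate(zip(data.balance_names,
                                         data.balance_kinds)):
        col = data.balance_matrix[:, k]
        x_t_pre, x_c_pre = col[tr_mask], col[~tr_mask]
        x_t, x_c = col[ti], col[ci]
        sd_ref = pooled_reference_sd(x_t_pre, x_c_pre,
                                     binary=(kind == "binary"))
        smd_un = standardized_mean_difference(x_t_pre, x_c_pre, sd_ref) \
            if sd_ref > 0 else 0.0
        smd_m = standardized_mean_difference(x_t, x_c, sd_ref) \
            if sd_ref > 0 else 0.0
        row = {"covariate": name, "kind": kind,
               "smd_unmatched": smd_un, "smd_matched": smd_m,
               "variance_ratio_matched": np.nan,
               "ks_stat": np.nan, "ks_p_matched": np.nan}
        if kind == "continuous":
            if x_t.var(ddof=1) > 0 and x_c.var(ddof=1) > 0:
                row["variance_ratio_matched"] = variance_ratio(x_t, x_c)
            stat, p = ks_boot(x_t, x_c, ks_boot_reps, rng)
            row["ks_stat"] = stat
            row["ks_p_matched"] = p
        vr = row["variance_ratio_matched"]
        row["flag"] = bool(smd_m >= SMD_THRESHOLD
                           or (np.isfinite(vr) and vr >= VR_THRESHOLD))
        rows.append(row)
    table = pd.DataFrame(rows)
    exact_terms = set()
    for name in data.exact_names:
        exact_terms.update(b for b in data.balance_names
                           if b == name or b.startswith(name + "="))
    table["exact"] = table["covariate"].isin(exact_terms)
    return table
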