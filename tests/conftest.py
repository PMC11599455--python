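import numpy as np
import pandas as pd
import pytest

import panelcea as pc


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort small enough for fast matching tests."""
    return pc.generate_cohort(pc.default_config(n_patients=600, seed=11))


@pytest.fixture(scope="session")
def tiny_match_config():
    return pc.MatchingConfig(population_size=8, max_generations=2,
                             stall_generations=2, ks_boot_reps=60, seed=12)


@pytest.fixture(scope="session")
def small_match(small_cohort, tiny_match_config):
    return pc.genetic_search(small_cohort, tiny_match_config)


@pytest.fixture(scope="session")
def toy_survival():
    """Four-patient toy data with one censoring event.

    Patients observed at days 100 (death), 200 (censored), 300 (death),
    400 (death).  Hand product-limit computations:

    forward KM (deaths):  S(100)=3/4, S(300)=3/4*1/2=3/8, S(400)=0
    reverse KM (censorings): G(200)=2/3 (risk set at 200 = {200,300,400}),
    G elsewhere 1 before 200.
    """
    times = np.array([100.0, 200.0, 300.0, 400.0])
    events = np.array(["death", "censored", "death", "death"])
    return times, events


def make_arm_frame(observed_days, event, monthly_cost=1000.0):
    """Minimal single-arm data frame with constant observed monthly costs."""
    observed_days = np.asarray(observed_days, dtype=float)
    n = len(observed_days)
    df = pd.DataFrame({
        "id": np.arange(n),
        "arm": "treated",
        "observed_time_days": observed_days,
        "survival_time_days": observed_days,
        "censor_time_days": np.inf,
        "event": event,
        "egfr_result": "negative",
    })
    starts = np.arange(36) * pc.DAYS_PER_MONTH
    frac = np.clip((observed_days[:, None] - starts) / pc.DAYS_PER_MONTH,
                   0.0, 1.0)
    costs = monthly_cost * frac
    for j in range(36):
        df[f"cost_m{j + 1:02d}"] = costs[:, j]
        df[f"oop_m{j + 1:02d}"] = 0.0
    return df
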