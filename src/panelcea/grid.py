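"""Monthly interval grid with annual discounting.

Follow-up is partitioned into contiguous "months" of 365.25/12 days.  Costs
and survival time accrued in interval j are discounted with the factor
(1+r)^(-start_j/365.25), i.e. discounting is applied at interval start for
both costs and life-years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0  # 30.4375


@dataclass(frozen=True)
class IntervalGrid:
    """Contiguous monthly partition of the analysis horizon."""

    n_intervals: int
    interval_length_days: float
    annual_discount_rate: float
    start_days: np.ndarray = field(repr=False)
    discount_factors: np.ndarray = field(repr=False)

    @property
    def end_days(self) -> np.ndarray:
        return self.start_days + self.interval_length_days

    @property
    def horizon_days(self) -> float:
        return self.n_intervals * self.interval_length_days

    @property
    def horizon_years(self) -> float:
        return self.horizon_days / DAYS_PER_YEAR


def build_grid(horizon_years: int = 3,
               annual_discount_rate: float = 0.015) -> IntervalGrid:
    """Build the monthly grid for a 1-, 2- or 3-year horizon.

    Parameters
    ----------
    horizon_years : int
        Analysis horizon; 12 intervals per year.
    annual_discount_rate : float
        Annual discount rate r >= 0 applied to costs and life-years.
    """
    if horizon_years not in (1, 2, 3):
        raise ValueError("horizon_years must be 1, 2 or 3")
    if annual_discount_rate < 0:
        raise ValueError("annual_discount_rate must be >= 0")
    n = 12 * horizon_years
    starts = np.arange(n) * DAYS_PER_MONTH
    factors = (1.0 + annual_discount_rate) ** (-(starts / DAYS_PER_YEAR))
    return IntervalGrid(
        n_intervals=n,
        interval_length_days=DAYS_PER_MONTH,
        annual_discount_rate=annual_discount_rate,
        start_days=starts,
        discount_factors=factors,
    )
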