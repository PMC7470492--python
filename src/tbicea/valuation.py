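"""Valuation of a cohort trace: discounted life-years, QALYs and costs.

Discounting is continuous-time, ``(1 + r)^{-t}`` evaluated at each cycle's
start time (daily cycles use ``t = day/365``); no half-cycle correction is
applied.  Utility is the count-weighted GOS utility at entry, adjusted by
an age multiplier normalised to 1 at the entry age, with individuals who
die during the 28-day trial window accruing zero utility between injury
and death.  Costs comprise a time-0 lump (treatment components in the
treated arm plus the hospital stay) and survivor-conditioned monitoring:
the first-year amount spread uniformly over days 29–365 and an annual
amount at each later cycle until death or the configured duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from .markov import TRIAL_DAYS, CohortTrace, NumericInputs

__all__ = [
    "DiscountSpec",
    "AgeUtilityMultiplier",
    "UtilityModel",
    "StrategyResult",
    "discount_factor",
    "life_years",
    "qalys",
    "arm_costs",
    "value_strategy",
    "bundled_age_multiplier",
]


@dataclass(frozen=True)
class DiscountSpec:
    rate: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 0.10):
            raise ValueError(f"discount rate out of range [0, 0.10]: {self.rate}")

    def factor(self, t) -> np.ndarray:
        return discount_factor(self, t)


def discount_factor(d: Union[DiscountSpec, float], t) -> np.ndarray:
    """Continuous-time discount factor ``(1 + rate)^(-t)`` for ``t`` in years."""
    rate = d.rate if isinstance(d, DiscountSpec) else float(d)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return (1.0 + rate) ** (-t)


class AgeUtilityMultiplier:
    """Age → utility multiplier, table-backed with floor-age lookup.

    Normalised so the multiplier is 1 at the cohort entry age; ages past
    the table's end carry the last value forward.
    """

    def __init__(self, ages, multipliers, *, entry_age: float = 42.0):
        ages = np.asarray(ages, dtype=int)
        mult = np.asarray(multipliers, dtype=float)
        if ages.shape != mult.shape or ages.ndim != 1 or ages.size == 0:
            raise ValueError("ages and multipliers must be equal-length 1-D arrays")
        if not np.array_equal(ages, np.arange(ages[0], ages[0] + ages.size)):
            raise ValueError("ages must be contiguous and ascending")
        if np.any(mult <= 0):
            raise ValueError("multipliers must be positive")
        if np.any(np.diff(mult) > 1e-12):
            raise ValueError("multipliers must be non-increasing with age")
        anchor = mult[np.clip(int(math.floor(entry_age)) - ages[0], 0, ages.size - 1)]
        self.ages = ages
        self.multipliers = mult / anchor
        self.entry_age = entry_age

    def __call__(self, age) -> np.ndarray:
        idx = np.clip(
            np.floor(np.asarray(age, dtype=float)).astype(int) - self.ages[0],
            0,
            self.ages.size - 1,
        )
        return self.multipliers[idx]

    @classmethod
    def from_csv(cls, path, *, entry_age: float = 42.0) -> "AgeUtilityMultiplier":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), entry_age=entry_age)


def bundled_age_multiplier(entry_age: float = 42.0) -> AgeUtilityMultiplier:
    """The bundled population-norms-shaped multiplier table.

    A linear utility decline of 0.004 per year of age beyond the entry
    age (flat below it), the package's stand-in for published population
    utility norms.
    """
    with resources.files("tbicea.data").joinpath("age_utility_multipliers.csv").open(
        "r"
    ) as fh:
        return AgeUtilityMultiplier.from_csv(fh, entry_age=entry_age)


@dataclass(frozen=True)
class UtilityModel:
    """Base utility at entry plus age adjustment and the trial-decedent rule."""

    base_utility: float
    age_multiplier: Optional[Callable] = None
    decedent_rule: bool = True

    def __post_init__(self) -> None:
        if not (-1.0 <= self.base_utility <= 1.0):
            raise ValueError("base utility must lie in [-1, 1]")

    def weights(self, ages) -> np.ndarray:
        if self.age_multiplier is None:
            return np.full(np.asarray(ages).shape, self.base_utility)
        return self.base_utility * np.asarray(self.age_multiplier(ages), dtype=float)


@dataclass(frozen=True)
class StrategyResult:
    """Discounted totals for one strategy arm."""

    total_cost: float
    life_years: float
    qalys: float

    def __post_init__(self) -> None:
        for v in (self.total_cost, self.life_years, self.qalys):
            if not math.isfinite(v):
                raise ValueError("strategy results must be finite")


def life_years(trace: CohortTrace, d: DiscountSpec) -> float:
    """Discounted life-years: sum of end-of-cycle occupancy times cycle length."""
    df = discount_factor(d, trace.time_at_cycle_start)
    return float(np.sum(trace.alive_end * trace.cycle_length_years * df))


def qalys(trace: CohortTrace, u: UtilityModel, d: DiscountSpec) -> float:
    """Discounted QALYs with age-adjusted utility and the decedent rule.

    During days 1–28 utility accrues only to the fraction of the cohort
    that survives the trial window (decedents score zero from injury to
    death); afterwards it follows end-of-cycle occupancy.
    """
    occupancy = trace.alive_end.copy()
    if u.decedent_rule:
        occupancy[:TRIAL_DAYS] = trace.alive_end[TRIAL_DAYS - 1]
    weights = u.weights(trace.age_at_cycle)
    df = discount_factor(d, trace.time_at_cycle_start)
    return float(np.sum(occupancy * weights * trace.cycle_length_years * df))


def arm_costs(
    trace: CohortTrace,
    inputs: NumericInputs,
    d: DiscountSpec,
    arm: str,
) -> float:
    """Discounted per-patient costs for one arm.

    Time-0 lump: treatment components (treated arm only) plus the hospital
    stay (per-day cost times the arm's length of stay).  Monitoring costs
    are survivor-conditioned: the first-year amount accrues uniformly over
    days 29–365 in proportion to the cohort alive, and the annual amount
    accrues at each annual cycle while the cohort is alive, until the
    configured monitoring duration.
    """
    if arm not in ("treated", "control"):
        raise ValueError(f"arm must be 'treated' or 'control', got {arm!r}")
    los = inputs.los_treated if arm == "treated" else inputs.los_control
    total = inputs.hospital_cost_per_day * los
    if arm == "treated":
        total += inputs.treatment_cost

    df = discount_factor(d, trace.time_at_cycle_start)
    n_daily = trace.n_daily

    if inputs.monitoring_year1 > 0:
        daily = slice(TRIAL_DAYS, n_daily)
        per_day = inputs.monitoring_year1 / (n_daily - TRIAL_DAYS)
        total += per_day * float(np.sum(trace.alive_end[daily] * df[daily]))

    if inputs.monitoring_annual > 0:
        t_ann = trace.time_at_cycle_start[n_daily:]
        # The annual cycle starting at t covers years (t, t+1]; include it
        # while the cycle end stays within the monitoring duration.
        keep = (t_ann + 1.0) <= inputs.monitoring_duration_years
        total += inputs.monitoring_annual * float(
            np.sum(trace.alive_end[n_daily:][keep] * df[n_daily:][keep])
        )
    return total


def value_strategy(
    trace: CohortTrace,
    u: UtilityModel,
    inputs: NumericInputs,
    d: DiscountSpec,
    arm: str,
) -> StrategyResult:
    """Assemble discounted cost, life-years and QALYs for one arm."""
    return StrategyResult(
        total_cost=arm_costs(trace, inputs, d, arm),
        life_years=life_years(trace, d),
        qalys=qalys(trace, u, d),
    )
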