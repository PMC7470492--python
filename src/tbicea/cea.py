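"""Cost-effectiveness analysis: ICERs, net monetary benefit, probabilistic
sensitivity analysis with acceptability curves, one-way deterministic
scenarios (tornado) and the time-to-treatment scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .life_tables import LifeTable
from .markov import NumericInputs, build_schedule, point_inputs, run_cohort, sampled_inputs
from .parameters import ParameterSet
from .valuation import (
    AgeUtilityMultiplier,
    DiscountSpec,
    StrategyResult,
    UtilityModel,
    bundled_age_multiplier,
    value_strategy,
)

__all__ = [
    "CEAResult",
    "PSAResult",
    "TornadoEntry",
    "DelayEffectTable",
    "DEFAULT_DELAY_TABLE",
    "icer",
    "nmb",
    "evaluate_arm",
    "run_from_inputs",
    "run_deterministic",
    "run_psa",
    "ceac",
    "one_way_scenarios",
    "tornado_entries",
    "time_to_treatment",
    "SCENARIO_NAMES",
]


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of the treated vs control strategies."""

    control: StrategyResult
    treated: StrategyResult
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_qaly: Optional[float]
    icer_per_ly: Optional[float]
    dominance_flag: str  # none | treated_dominates | treated_dominated | undefined

    def nmb_incremental(self, threshold: float) -> float:
        return threshold * self.delta_qaly - self.delta_cost


def icer(control: StrategyResult, treated: StrategyResult) -> CEAResult:
    """Incremental cost-effectiveness ratios with dominance handling.

    The ICER is reported only when the treated arm costs more and gains
    more (or costs less and loses — the other trade-off quadrant); when
    the signs of the deltas disagree, a dominance flag is set instead, and
    a zero effect difference yields an undefined ratio rather than an
    exception.
    """
    d_cost = treated.total_cost - control.total_cost
    d_ly = treated.life_years - control.life_years
    d_qaly = treated.qalys - control.qalys

    flag = "none"
    if d_qaly == 0.0:
        flag = "undefined" if d_cost != 0.0 else "none"
    elif d_cost <= 0.0 and d_qaly > 0.0:
        flag = "treated_dominates"
    elif d_cost >= 0.0 and d_qaly < 0.0:
        flag = "treated_dominated"

    per_qaly = d_cost / d_qaly if flag == "none" and d_qaly != 0.0 else None
    per_ly = d_cost / d_ly if d_ly != 0.0 else None
    return CEAResult(
        control=control,
        treated=treated,
        delta_cost=d_cost,
        delta_ly=d_ly,
        delta_qaly=d_qaly,
        icer_per_qaly=per_qaly,
        icer_per_ly=per_ly,
        dominance_flag=flag,
    )


def nmb(result: StrategyResult, threshold: float) -> float:
    """Net monetary benefit ``threshold * QALYs - cost``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return threshold * result.qalys - result.total_cost


def evaluate_arm(
    inputs: NumericInputs,
    table: LifeTable,
    arm: str,
    age_multiplier=None,
) -> StrategyResult:
    """Schedule → cohort trace → discounted valuation for one arm."""
    trace = run_cohort(build_schedule(inputs, table, arm))
    base_u = inputs.utility_treated if arm == "treated" else inputs.utility_control
    u = UtilityModel(base_utility=base_u, age_multiplier=age_multiplier)
    return value_strategy(trace, u, inputs, DiscountSpec(inputs.discount_rate), arm)


def run_from_inputs(
    inputs: NumericInputs, table: LifeTable, age_multiplier=None
) -> CEAResult:
    """Run both arms from a numeric realisation and compare them."""
    if age_multiplier is None:
        age_multiplier = bundled_age_multiplier(inputs.entry_age)
    control = evaluate_arm(inputs, table, "control", age_multiplier)
    treated = evaluate_arm(inputs, table, "treated", age_multiplier)
    return icer(control, treated)


def run_deterministic(
    params: ParameterSet, table: LifeTable, age_multiplier=None
) -> CEAResult:
    """Base-case (point-estimate) cost-effectiveness comparison."""
    return run_from_inputs(point_inputs(params), table, age_multiplier)


@dataclass
class PSAResult:
    """Per-simulation incremental outcomes from the probabilistic analysis.

    ``mean_icer`` is the ratio of mean incremental cost to mean incremental
    QALYs (the expected-value ICER); the mean of per-simulation ratios is
    also recorded for reference but is not the headline statistic, since it
    is unstable when a simulation's QALY gain approaches zero.
    """

    n_sims: int
    seed: int
    threshold: float
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    delta_ly: np.ndarray
    mean_icer: float = field(init=False)
    mean_of_ratio_icer: float = field(init=False)
    prob_ce_at_threshold: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        self.mean_icer = float(np.mean(self.delta_cost) / np.mean(self.delta_qaly))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = self.delta_cost / self.delta_qaly
        self.mean_of_ratio_icer = float(np.mean(ratios[np.isfinite(ratios)]))
        self.prob_ce_at_threshold = self.prob_cost_effective(self.threshold)

    def prob_cost_effective(self, threshold: float) -> float:
        """Fraction of simulations with positive incremental NMB at ``threshold``."""
        return float(np.mean(threshold * self.delta_qaly - self.delta_cost > 0.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sim": np.arange(self.n_sims),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
                "delta_ly": self.delta_ly,
            }
        )


def run_psa(
    params: ParameterSet,
    table: LifeTable,
    n_sims: int = 1000,
    seed: int = 0,
    age_multiplier=None,
) -> PSAResult:
    """Probabilistic sensitivity analysis.

    Every uncertain parameter is drawn independently from its
    specification, once per simulation, and both arms are run with the
    shared draw (treatment effect applied in the treated arm only).
    Reproducible: the same seed yields bit-identical results.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    if age_multiplier is None:
        age_multiplier = bundled_age_multiplier(params.entry_age)
    d_cost = np.empty(n_sims)
    d_qaly = np.empty(n_sims)
    d_ly = np.empty(n_sims)
    for i in range(n_sims):
        res = run_from_inputs(sampled_inputs(params, rng), table, age_multiplier)
        d_cost[i] = res.delta_cost
        d_qaly[i] = res.delta_qaly
        d_ly[i] = res.delta_ly
    return PSAResult(
        n_sims=n_sims,
        seed=seed,
        threshold=params.threshold,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        delta_ly=d_ly,
    )


def ceac(psa: PSAResult, thresholds: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a threshold grid."""
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid must be non-empty")
    probs = [psa.prob_cost_effective(lam) for lam in thresholds]
    return pd.DataFrame({"threshold": thresholds, "probability": probs})


def default_threshold_grid(threshold: float, n: int = 100) -> np.ndarray:
    """0 to twice the country threshold in ``n`` steps."""
    return np.linspace(0.0, 2.0 * threshold, n + 1)


# ---------------------------------------------------------------------------
# One-way deterministic scenarios
# ---------------------------------------------------------------------------

#: Arm-specific deterministic length-of-stay scenario values (days).
_ARM_LOS = {"UK": (14.0, 13.3), "Pakistan": (7.3, 7.4)}  # (treated, control)

SCENARIO_NAMES = (
    "base_case",
    "rr_0.64",
    "rr_0.95",
    "utility_by_arm_0.74_0.75",
    "utility_both_0.63",
    "utility_both_0.79",
    "monitoring_first_year_only",
    "monitoring_5_years",
    "discount_0pct",
    "discount_6pct",
    "no_long_term_excess_mortality",
    "arm_specific_los",
    "horizon_5_years",
)


def _scenario_inputs(name: str, base: NumericInputs, country: str) -> NumericInputs:
    if name == "base_case":
        return base
    if name == "rr_0.64":
        return base.replace(rr_head=0.64)
    if name == "rr_0.95":
        return base.replace(rr_head=0.95)
    if name == "utility_by_arm_0.74_0.75":
        return base.replace(utility_treated=0.74, utility_control=0.75)
    if name == "utility_both_0.63":
        return base.replace(utility_treated=0.63, utility_control=0.63)
    if name == "utility_both_0.79":
        return base.replace(utility_treated=0.79, utility_control=0.79)
    if name == "monitoring_first_year_only":
        return base.replace(monitoring_duration_years=1.0)
    if name == "monitoring_5_years":
        return base.replace(monitoring_duration_years=5.0)
    if name == "discount_0pct":
        return base.replace(discount_rate=0.0)
    if name == "discount_6pct":
        return base.replace(discount_rate=0.06)
    if name == "no_long_term_excess_mortality":
        return base.replace(smr_year1=1.0, smr_later=1.0)
    if name == "arm_specific_los":
        t, c = _ARM_LOS[country]
        return base.replace(los_treated=t, los_control=c)
    if name == "horizon_5_years":
        return base.replace(horizon_years=5.0)
    raise KeyError(f"unknown scenario {name!r}")


def one_way_scenarios(
    params: ParameterSet,
    table: LifeTable,
    names: Sequence[str] = SCENARIO_NAMES,
    age_multiplier=None,
) -> dict[str, CEAResult]:
    """Run each named deterministic scenario from an unchanged base case."""
    base = point_inputs(params)
    if age_multiplier is None:
        age_multiplier = bundled_age_multiplier(params.entry_age)
    out: dict[str, CEAResult] = {}
    for name in names:
        inputs = _scenario_inputs(name, base, params.country_label)
        out[name] = run_from_inputs(inputs, table, age_multiplier)
    return out


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of the tornado diagram: the ICER at the scenario's extremes."""

    scenario_name: str
    icer_low: Optional[float]
    icer_high: Optional[float]


#: Tornado bars: (label, scenario at the low end, scenario at the high end).
_TORNADO_PAIRS = (
    ("treatment_effect_rr", "rr_0.64", "rr_0.95"),
    ("utility_both_arms", "utility_both_0.79", "utility_both_0.63"),
    ("utility_by_arm", "base_case", "utility_by_arm_0.74_0.75"),
    ("monitoring_duration", "monitoring_first_year_only", "monitoring_5_years"),
    ("discount_rate", "discount_0pct", "discount_6pct"),
    ("long_term_excess_mortality", "base_case", "no_long_term_excess_mortality"),
    ("arm_specific_los", "base_case", "arm_specific_los"),
    ("time_horizon_5_years", "base_case", "horizon_5_years"),
)


def tornado_entries(scenarios: dict[str, CEAResult]) -> list[TornadoEntry]:
    """Pair the one-way scenarios into tornado bars."""
    entries = []
    for label, lo, hi in _TORNADO_PAIRS:
        entries.append(
            TornadoEntry(
                scenario_name=label,
                icer_low=scenarios[lo].icer_per_qaly,
                icer_high=scenarios[hi].icer_per_qaly,
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Time to treatment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DelayEffectTable:
    """Head-injury risk ratio as a function of injury-to-treatment delay."""

    rows: tuple[tuple[float, float], ...]  # (delay_minutes, rr_head)

    def __post_init__(self) -> None:
        delays = [r[0] for r in self.rows]
        if delays != sorted(delays):
            raise ValueError("delays must be ascending")
        if any(r[1] <= 0 for r in self.rows):
            raise ValueError("risk ratios must be positive")


#: Only the 30-minute point estimate is published outside supplementary
#: material; further rows can be supplied by the user.
DEFAULT_DELAY_TABLE = DelayEffectTable(rows=((30.0, 0.62),))


def time_to_treatment(
    params: ParameterSet,
    table: LifeTable,
    delays: DelayEffectTable = DEFAULT_DELAY_TABLE,
    age_multiplier=None,
) -> list[tuple[float, CEAResult]]:
    """Re-run the deterministic model with the delay-specific risk ratio."""
    base = point_inputs(params)
    if age_multiplier is None:
        age_multiplier = bundled_age_multiplier(params.entry_age)
    return [
        (delay, run_from_inputs(base.replace(rr_head=rr), table, age_multiplier))
        for delay, rr in delays.rows
    ]
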