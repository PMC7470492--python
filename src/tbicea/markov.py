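"""Two-state (alive/dead) Markov cohort engine.

The cohort enters alive at the mean trial age and is followed with daily
cycles for the first year — so the 28-day trial mortality is resolved at
the resolution it was observed — and annual cycles thereafter.  Three
competing exits are tracked: head-injury death and non-head-injury death
during the 28-day trial window, and background mortality (life-table qx
scaled by a standardised mortality ratio) from day 29 onward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Union

import numpy as np
import pandas as pd

from .life_tables import LifeTable, annual_mortality
from .parameters import ParameterSet

__all__ = [
    "NumericInputs",
    "TransitionSchedule",
    "CohortTrace",
    "per_cycle_hazard",
    "apply_treatment_effect",
    "point_inputs",
    "sampled_inputs",
    "build_schedule",
    "run_cohort",
]

DAYS_PER_YEAR = 365
TRIAL_DAYS = 28


@dataclass(frozen=True)
class NumericInputs:
    """A fully numeric realisation of a :class:`~tbicea.parameters.ParameterSet`.

    The engine and valuation layers consume plain numbers; the point
    estimates (deterministic run) and per-simulation draws (probabilistic
    run) are both expressed as instances of this type, and deterministic
    scenarios are `replace()`d copies of the point realisation.
    """

    p28_head: float
    p28_nonhead: float
    rr_head: float
    smr_year1: float
    smr_later: float
    utility_control: float
    utility_treated: float
    treatment_cost: float
    hospital_cost_per_day: float
    los_control: float
    los_treated: float
    monitoring_year1: float
    monitoring_annual: float
    monitoring_duration_years: float  # math.inf means lifetime
    discount_rate: float
    threshold: float
    entry_age: float
    max_age: int
    horizon_years: float  # math.inf means lifetime

    def replace(self, **kwargs) -> "NumericInputs":
        return replace(self, **kwargs)


def _duration_to_float(value: Union[int, str]) -> float:
    return math.inf if value == "lifetime" else float(value)


def point_inputs(params: ParameterSet) -> NumericInputs:
    """Deterministic realisation: every distribution at its point estimate."""
    u = params.utilities.weighted_utility()
    c = params.costs
    return NumericInputs(
        p28_head=params.p28_head.mean,
        p28_nonhead=params.p28_nonhead.mean,
        rr_head=params.rr_head.point,
        smr_year1=params.smr_year1.mean,
        smr_later=params.smr_later.mean,
        utility_control=u,
        utility_treated=u,
        treatment_cost=c.treatment_component_total,
        hospital_cost_per_day=c.hospital_cost_per_day,
        los_control=c.los_days_point,
        los_treated=c.los_days_point,
        monitoring_year1=c.monitoring_year1,
        monitoring_annual=c.monitoring_annual,
        monitoring_duration_years=_duration_to_float(c.monitoring_duration_years),
        discount_rate=params.discount_rate,
        threshold=params.threshold,
        entry_age=params.entry_age,
        max_age=params.max_age,
        horizon_years=_duration_to_float(params.horizon_years),
    )


def sampled_inputs(params: ParameterSet, rng: np.random.Generator) -> NumericInputs:
    """One probabilistic realisation: a joint independent draw of every
    uncertain parameter.  Length of stay is drawn once and shared by both
    arms (the base case assumes equal stay, so hospital cost cancels in the
    increment); the weighted utility is rebuilt from the drawn GOS
    component utilities.
    """
    u = params.utilities.sample_weighted(rng)
    c = params.costs
    los = float(c.los_days.sample(rng))
    p_head = float(params.p28_head.sample(rng))
    rr = float(params.rr_head.sample(rng))
    if rr * p_head > 1.0:  # not reachable at trial-scale risks, but keep the contract
        rr = 1.0 / p_head
    return NumericInputs(
        p28_head=p_head,
        p28_nonhead=float(params.p28_nonhead.sample(rng)),
        rr_head=rr,
        smr_year1=max(float(params.smr_year1.sample(rng)), 0.0),
        smr_later=max(float(params.smr_later.sample(rng)), 0.0),
        utility_control=u,
        utility_treated=u,
        treatment_cost=c.treatment_component_total,
        hospital_cost_per_day=c.hospital_cost_per_day,
        los_control=los,
        los_treated=los,
        monitoring_year1=c.monitoring_year1,
        monitoring_annual=c.monitoring_annual,
        monitoring_duration_years=_duration_to_float(c.monitoring_duration_years),
        discount_rate=params.discount_rate,
        threshold=params.threshold,
        entry_age=params.entry_age,
        max_age=params.max_age,
        horizon_years=_duration_to_float(params.horizon_years),
    )


def per_cycle_hazard(p_cum: float, n_cycles: int) -> float:
    """Constant per-cycle probability whose compounding over ``n_cycles``
    recovers the cumulative probability ``p_cum``:
    ``1 - (1 - p_cum)**(1/n_cycles)``.
    """
    if not 0.0 <= p_cum < 1.0:
        raise ValueError(f"cumulative probability must lie in [0, 1), got {p_cum}")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    return 1.0 - (1.0 - p_cum) ** (1.0 / n_cycles)


def apply_treatment_effect(p28_head: float, rr: float) -> float:
    """Apply the risk ratio to the 28-day cumulative head-injury risk, capped at 1."""
    if not 0.0 <= p28_head <= 1.0:
        raise ValueError("p28_head must be a probability")
    if rr <= 0:
        raise ValueError("risk ratio must be positive")
    return min(rr * p28_head, 1.0)


@dataclass(frozen=True)
class TransitionSchedule:
    """Per-cycle death probabilities plus cycle timing and cohort age.

    The first ``n_daily`` cycles are daily; the remainder are annual.
    """

    time_at_cycle_start: np.ndarray  # years since model entry
    cycle_length_years: np.ndarray
    age_at_cycle: np.ndarray
    p_death_head: np.ndarray
    p_death_nonhead: np.ndarray
    p_death_background: np.ndarray
    n_daily: int

    def __post_init__(self) -> None:
        for p in (self.p_death_head, self.p_death_nonhead, self.p_death_background):
            if np.any((p < 0) | (p > 1)):
                raise ValueError("cycle probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return self.time_at_cycle_start.size


def build_schedule(
    inputs: Union[NumericInputs, ParameterSet],
    table: LifeTable,
    arm: str,
) -> TransitionSchedule:
    """Build the transition schedule for one treatment arm.

    Days 1–28 carry constant daily hazards derived from the 28-day
    cumulative trial risks (head-injury risk multiplied by the risk ratio
    in the treated arm).  Days 29–365 carry the daily conversion of the
    first-year SMR times the entry-age ``qx`` — trial deaths already count
    all causes, so background mortality starts only after the trial
    window.  Annual cycles then apply ``min(1, SMR_later * qx(age))``,
    ageing the cohort one year per cycle, until the horizon or the
    terminal age.
    """
    if isinstance(inputs, ParameterSet):
        inputs = point_inputs(inputs)
    if arm not in ("treated", "control"):
        raise ValueError(f"arm must be 'treated' or 'control', got {arm!r}")
    if inputs.horizon_years < 1:
        raise ValueError("the model horizon must cover at least the first year")

    p28_head = inputs.p28_head
    if arm == "treated":
        p28_head = apply_treatment_effect(p28_head, inputs.rr_head)
    d_head = per_cycle_hazard(p28_head, TRIAL_DAYS)
    d_nonhead = per_cycle_hazard(inputs.p28_nonhead, TRIAL_DAYS)

    entry_age = inputs.entry_age
    q_entry = annual_mortality(table, entry_age)
    p_bg_year1 = min(1.0, inputs.smr_year1 * q_entry)
    if p_bg_year1 < 1.0:
        d_bg = per_cycle_hazard(p_bg_year1, DAYS_PER_YEAR)
    else:
        d_bg = 1.0

    # Daily cycles: days 1..365.
    t_daily = np.arange(DAYS_PER_YEAR) / DAYS_PER_YEAR
    ph = np.where(np.arange(DAYS_PER_YEAR) < TRIAL_DAYS, d_head, 0.0)
    pnh = np.where(np.arange(DAYS_PER_YEAR) < TRIAL_DAYS, d_nonhead, 0.0)
    pbg = np.where(np.arange(DAYS_PER_YEAR) < TRIAL_DAYS, 0.0, d_bg)

    # Annual cycles: ages entry+1, entry+2, ... up to the terminal age.
    ages_annual = np.arange(math.floor(entry_age) + 1, table.max_age + 1)
    t_annual = 1.0 + np.arange(ages_annual.size, dtype=float)
    if math.isfinite(inputs.horizon_years):
        keep = t_annual < inputs.horizon_years
        ages_annual = ages_annual[keep]
        t_annual = t_annual[keep]
    q_annual = np.array([annual_mortality(table, a) for a in ages_annual])
    p_bg_annual = np.minimum(1.0, inputs.smr_later * q_annual)

    return TransitionSchedule(
        time_at_cycle_start=np.concatenate([t_daily, t_annual]),
        cycle_length_years=np.concatenate(
            [np.full(DAYS_PER_YEAR, 1.0 / DAYS_PER_YEAR), np.ones(ages_annual.size)]
        ),
        age_at_cycle=np.concatenate(
            [np.full(DAYS_PER_YEAR, math.floor(entry_age)), ages_annual]
        ),
        p_death_head=np.concatenate([ph, np.zeros(ages_annual.size)]),
        p_death_nonhead=np.concatenate([pnh, np.zeros(ages_annual.size)]),
        p_death_background=np.concatenate([pbg, p_bg_annual]),
        n_daily=DAYS_PER_YEAR,
    )


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle cohort occupancy (proportions of the entering cohort).

    ``alive_start``/``alive_end`` bracket each cycle; cumulative deaths by
    cause are recorded at cycle end and satisfy
    ``alive_end + died_head + died_nonhead + died_background == 1``.
    """

    time_at_cycle_start: np.ndarray
    cycle_length_years: np.ndarray
    age_at_cycle: np.ndarray
    alive_start: np.ndarray
    alive_end: np.ndarray
    died_head: np.ndarray  # cumulative
    died_nonhead: np.ndarray  # cumulative
    died_background: np.ndarray  # cumulative
    n_daily: int

    def __len__(self) -> int:
        return self.alive_end.size

    @property
    def alive_at_trial_end(self) -> float:
        """Proportion alive at the end of day 28."""
        return float(self.alive_end[TRIAL_DAYS - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_years": self.time_at_cycle_start,
                "age": self.age_at_cycle,
                "alive": self.alive_end,
                "died_head_cum": self.died_head,
                "died_nonhead_cum": self.died_nonhead,
                "died_background_cum": self.died_background,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_cohort(schedule: TransitionSchedule) -> CohortTrace:
    """Run the cohort through the schedule.

    Competing exits within a cycle combine as independent risks,
    ``p_total = 1 - prod(1 - p_cause)``, and the cycle's deaths are
    attributed to causes in proportion to their hazards
    ``-log(1 - p_cause)``; the background share is taken as the remainder
    so that mass is conserved exactly.
    """
    ph, pnh, pbg = (
        schedule.p_death_head,
        schedule.p_death_nonhead,
        schedule.p_death_background,
    )
    surv = (1.0 - ph) * (1.0 - pnh) * (1.0 - pbg)
    p_total = 1.0 - surv

    alive_end = np.cumprod(surv)
    alive_start = np.concatenate([[1.0], alive_end[:-1]])
    d_total = alive_start * p_total

    # Hazard-proportional attribution (clip to keep log finite at qx = 1).
    clip = 1.0 - 1e-12
    hz_h = -np.log1p(-np.minimum(ph, clip))
    hz_nh = -np.log1p(-np.minimum(pnh, clip))
    hz_bg = -np.log1p(-np.minimum(pbg, clip))
    hz_sum = hz_h + hz_nh + hz_bg
    with np.errstate(invalid="ignore"):
        share_h = np.where(hz_sum > 0, hz_h / hz_sum, 0.0)
        share_nh = np.where(hz_sum > 0, hz_nh / hz_sum, 0.0)

    d_head = d_total * share_h
    d_nonhead = d_total * share_nh
    d_background = d_total - d_head - d_nonhead

    return CohortTrace(
        time_at_cycle_start=schedule.time_at_cycle_start,
        cycle_length_years=schedule.cycle_length_years,
        age_at_cycle=schedule.age_at_cycle,
        alive_start=alive_start,
        alive_end=alive_end,
        died_head=np.cumsum(d_head),
        died_nonhead=np.cumsum(d_nonhead),
        died_background=np.cumsum(d_background),
        n_daily=schedule.n_daily,
    )
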