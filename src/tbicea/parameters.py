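"""Model parameters and their sampling distributions.

Every quantity the decision model consumes is represented as a tagged
distribution specification: beta for probabilities and utilities (with
``(alpha, beta)`` interpreted as pseudo-(events, non-events) so that
``alpha + beta`` equals the trial arm size), gamma for hospital length of
stay, lognormal for the treatment-effect risk ratio, normal for the
standardised mortality ratios, and fixed for point values without
uncertainty.  The base-case parameterisation for each country ships as a
bundled YAML catalogue and is assembled by :func:`build_base_case`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Union

import numpy as np
import yaml

__all__ = [
    "BetaSpec",
    "GammaSpec",
    "LogNormalSpec",
    "NormalSpec",
    "FixedSpec",
    "DistributionSpec",
    "GosUtilitySet",
    "CostInputs",
    "ParameterSet",
    "normal_from_ci",
    "sample_parameter",
    "build_base_case",
    "load_parameter_catalogue",
    "COUNTRIES",
]

#: z quantile used to convert a printed 95% CI into a normal SD.
_Z975 = 1.959964

COUNTRIES = ("UK", "Pakistan")


class InvalidSpecError(ValueError):
    """Raised when a distribution specification violates its constraints."""


@dataclass(frozen=True)
class BetaSpec:
    """Beta distribution parameterised as pseudo-events / pseudo-non-events."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise InvalidSpecError(
                f"beta parameters must be positive, got ({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def point(self) -> float:
        return self.mean

    def sample(self, rng: np.random.Generator, size=None):
        return rng.beta(self.alpha, self.beta, size=size)


@dataclass(frozen=True)
class GammaSpec:
    """Gamma distribution with shape ``k`` and scale ``theta`` (days)."""

    shape_k: float
    scale_theta: float

    def __post_init__(self) -> None:
        if not (self.shape_k > 0 and self.scale_theta > 0):
            raise InvalidSpecError(
                f"gamma parameters must be positive, got ({self.shape_k}, {self.scale_theta})"
            )

    @property
    def mean(self) -> float:
        return self.shape_k * self.scale_theta

    @property
    def point(self) -> float:
        return self.mean

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape_k, self.scale_theta, size=size)


@dataclass(frozen=True)
class LogNormalSpec:
    """Lognormal distribution on a ratio scale; ``mu`` is the log point estimate."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise InvalidSpecError(f"lognormal sigma must be positive, got {self.sigma}")

    @property
    def point(self) -> float:
        """exp(mu): the median on the natural scale."""
        return math.exp(self.mu)

    def ci95(self) -> tuple[float, float]:
        return (
            math.exp(self.mu - _Z975 * self.sigma),
            math.exp(self.mu + _Z975 * self.sigma),
        )

    def sample(self, rng: np.random.Generator, size=None):
        return rng.lognormal(self.mu, self.sigma, size=size)


@dataclass(frozen=True)
class NormalSpec:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise InvalidSpecError(f"normal sd must be positive, got {self.sd}")

    @property
    def point(self) -> float:
        return self.mean

    def sample(self, rng: np.random.Generator, size=None):
        return rng.normal(self.mean, self.sd, size=size)


@dataclass(frozen=True)
class FixedSpec:
    """Degenerate distribution: sampling always returns ``value``."""

    value: float

    @property
    def point(self) -> float:
        return self.value

    @property
    def mean(self) -> float:
        return self.value

    def sample(self, rng: np.random.Generator, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


DistributionSpec = Union[BetaSpec, GammaSpec, LogNormalSpec, NormalSpec, FixedSpec]


def normal_from_ci(mean: float, lo: float, hi: float) -> NormalSpec:
    """Build a symmetric NormalSpec from a mean and a printed 95% CI.

    ``sd = (hi - lo) / (2 * 1.959964)``.  The printed intervals for the
    standardised mortality ratios are slightly asymmetric; a symmetric
    normal is used deliberately because that is how the distribution is
    declared in the source parameter table.
    """
    if not (lo < mean < hi):
        raise InvalidSpecError(f"need lo < mean < hi, got ({mean}, {lo}, {hi})")
    return NormalSpec(mean=mean, sd=(hi - lo) / (2.0 * _Z975))


def beta_mean(spec: BetaSpec) -> float:
    """Mean alpha/(alpha+beta) of a beta specification."""
    return spec.mean


def lognormal_point(spec: LogNormalSpec) -> float:
    """Natural-scale point estimate exp(mu)."""
    return spec.point


def gamma_mean(spec: GammaSpec) -> float:
    """Mean k*theta of a gamma specification (days)."""
    return spec.mean


def sample_parameter(spec: DistributionSpec, rng: np.random.Generator, size=None):
    """Draw from any distribution specification with a seeded generator."""
    return spec.sample(rng, size=size)


@dataclass(frozen=True)
class GosUtilitySet:
    """Glasgow Outcome Scale utilities and the survivor mix that weights them.

    The vegetative-state utility is below zero (a state judged worse than
    death) and is held fixed in probabilistic analyses: no valid beta
    distribution exists for a negative value, and its weight in the cohort
    is small.
    """

    utility_good: BetaSpec
    utility_moderate: BetaSpec
    utility_severe: BetaSpec
    utility_vegetative: FixedSpec
    counts_good: int
    counts_moderate: int
    counts_severe: int
    counts_vegetative: int

    def __post_init__(self) -> None:
        counts = self.counts
        if any(c < 0 for c in counts):
            raise InvalidSpecError(f"GOS counts must be non-negative, got {counts}")
        if sum(counts) <= 0:
            raise InvalidSpecError("GOS counts must sum to a positive total")
        if not (-1.0 <= self.utility_vegetative.value <= 1.0):
            raise InvalidSpecError("vegetative utility must lie in [-1, 1]")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (
            self.counts_good,
            self.counts_moderate,
            self.counts_severe,
            self.counts_vegetative,
        )

    def weighted_utility(self) -> float:
        """Count-weighted mean of the four point utilities."""
        utils = (
            self.utility_good.point,
            self.utility_moderate.point,
            self.utility_severe.point,
            self.utility_vegetative.point,
        )
        total = sum(self.counts)
        return sum(u * c for u, c in zip(utils, self.counts)) / total

    def sample_weighted(self, rng: np.random.Generator) -> float:
        """Draw the three beta utilities and return the count-weighted mean."""
        utils = (
            self.utility_good.sample(rng),
            self.utility_moderate.sample(rng),
            self.utility_severe.sample(rng),
            self.utility_vegetative.value,
        )
        total = sum(self.counts)
        return sum(u * c for u, c in zip(utils, self.counts)) / total


def weighted_utility(u: GosUtilitySet) -> float:
    return u.weighted_utility()


@dataclass(frozen=True)
class CostInputs:
    """Per-patient cost components in the country currency (2018 prices).

    Hospital cost is carried as a per-day cost times a length of stay so
    that arm-specific stay scenarios rescale it; ``los_days_point`` is the
    deterministic stay while ``los_days`` is the sampling distribution.
    """

    drug_cost: float
    fluid_cost: float
    consumables_cost: float
    admin_cost: float
    hospital_cost_per_day: float
    los_days: GammaSpec
    los_days_point: float
    monitoring_year1: float
    monitoring_annual: float
    monitoring_duration_years: Union[int, str] = "lifetime"
    currency: str = ""

    def __post_init__(self) -> None:
        money = (
            self.drug_cost,
            self.fluid_cost,
            self.consumables_cost,
            self.admin_cost,
            self.hospital_cost_per_day,
            self.monitoring_year1,
            self.monitoring_annual,
        )
        if any(m < 0 for m in money):
            raise InvalidSpecError("cost components must be non-negative")
        dur = self.monitoring_duration_years
        if not (dur == "lifetime" or (isinstance(dur, int) and dur >= 1)):
            raise InvalidSpecError(
                f"monitoring_duration_years must be a positive integer or 'lifetime', got {dur!r}"
            )

    @property
    def treatment_component_total(self) -> float:
        """Drug + fluids + consumables + administration (intervention arm only)."""
        return self.drug_cost + self.fluid_cost + self.consumables_cost + self.admin_cost


@dataclass(frozen=True)
class ParameterSet:
    """Full country/population parameterisation of the decision model."""

    country_label: str
    p28_head: BetaSpec
    p28_nonhead: BetaSpec
    rr_head: LogNormalSpec
    smr_year1: NormalSpec
    smr_later: NormalSpec
    utilities: GosUtilitySet
    costs: CostInputs
    discount_rate: float
    threshold: float
    entry_age: float = 42.0
    max_age: int = 100
    horizon_years: Union[int, str] = "lifetime"

    def __post_init__(self) -> None:
        if not (0.0 <= self.discount_rate <= 0.10):
            raise InvalidSpecError(f"discount rate out of range: {self.discount_rate}")
        if not self.entry_age < self.max_age:
            raise InvalidSpecError("entry_age must be below max_age")
        hz = self.horizon_years
        if not (hz == "lifetime" or (isinstance(hz, int) and hz >= 1)):
            raise InvalidSpecError(
                f"horizon_years must be a positive integer or 'lifetime', got {hz!r}"
            )

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["_format"] = "tbicea-parameter-set/1"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        d = dict(d)
        d.pop("_format", None)
        d["p28_head"] = BetaSpec(**d["p28_head"])
        d["p28_nonhead"] = BetaSpec(**d["p28_nonhead"])
        d["rr_head"] = LogNormalSpec(**d["rr_head"])
        d["smr_year1"] = NormalSpec(**d["smr_year1"])
        d["smr_later"] = NormalSpec(**d["smr_later"])
        u = dict(d["utilities"])
        for k in ("utility_good", "utility_moderate", "utility_severe"):
            u[k] = BetaSpec(**u[k])
        u["utility_vegetative"] = FixedSpec(**u["utility_vegetative"])
        d["utilities"] = GosUtilitySet(**u)
        c = dict(d["costs"])
        c["los_days"] = GammaSpec(**c["los_days"])
        d["costs"] = CostInputs(**c)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Built-in base cases
# ---------------------------------------------------------------------------


def load_parameter_catalogue() -> dict:
    """Load the bundled parameter catalogue (one record per model parameter)."""
    text = (
        resources.files("tbicea.data").joinpath("base_case_parameters.yaml").read_text()
    )
    return yaml.safe_load(text)


def _utilities_from_catalogue(shared: dict) -> GosUtilitySet:
    counts = shared["gos_counts"]["value"]
    return GosUtilitySet(
        utility_good=BetaSpec(**shared["utility_good"]["params"]),
        utility_moderate=BetaSpec(**shared["utility_moderate"]["params"]),
        utility_severe=BetaSpec(**shared["utility_severe"]["params"]),
        utility_vegetative=FixedSpec(**shared["utility_vegetative"]["params"]),
        counts_good=counts[0],
        counts_moderate=counts[1],
        counts_severe=counts[2],
        counts_vegetative=counts[3],
    )


def build_base_case(country: str, *, admin_hourly_rate: float | None = None) -> ParameterSet:
    """Assemble the full base-case :class:`ParameterSet` for ``UK`` or ``Pakistan``.

    Parameters
    ----------
    country:
        One of ``"UK"`` or ``"Pakistan"``.
    admin_hourly_rate:
        Optional override of the hourly staff cost used for the 21-minute
        administration of the treatment dose.  The bundled defaults are
        £37/hour (UK, hospital nurse) and US$5.20/hour (Pakistan,
        postgraduate doctor).
    """
    cat = load_parameter_catalogue()
    if country not in cat["countries"]:
        raise KeyError(f"unknown country {country!r}; expected one of {COUNTRIES}")
    shared = cat["shared"]
    cc = cat["countries"][country]
    costs_cat = cc["costs"]

    rate = (
        admin_hourly_rate
        if admin_hourly_rate is not None
        else costs_cat["admin_hourly_rate"]["value"]
    )
    admin_cost = costs_cat["admin_minutes"]["value"] / 60.0 * rate
    los_point = costs_cat["los_days"]["value"]
    los_gamma = costs_cat["los_days"]["params"]
    costs = CostInputs(
        drug_cost=costs_cat["drug_cost"]["value"],
        fluid_cost=costs_cat["fluid_cost"]["value"],
        consumables_cost=costs_cat["consumables_cost"]["value"],
        admin_cost=admin_cost,
        hospital_cost_per_day=costs_cat["hospital_cost_total"]["value"] / los_point,
        los_days=GammaSpec(shape_k=los_gamma["shape"], scale_theta=los_gamma["scale"]),
        los_days_point=los_point,
        monitoring_year1=costs_cat["monitoring_year1"]["value"],
        monitoring_annual=costs_cat["monitoring_annual"]["value"],
        monitoring_duration_years=costs_cat["monitoring_duration_years"]["value"],
        currency=cc["currency"],
    )

    smr1 = shared["smr_year1"]["params"]
    smr2 = shared["smr_later"]["params"]
    return ParameterSet(
        country_label=country,
        p28_head=BetaSpec(**cc["p28_head"]["params"]),
        p28_nonhead=BetaSpec(**cc["p28_nonhead"]["params"]),
        rr_head=LogNormalSpec(**shared["rr_head"]["params"]),
        smr_year1=normal_from_ci(smr1["mean"], smr1["lo"], smr1["hi"]),
        smr_later=normal_from_ci(smr2["mean"], smr2["lo"], smr2["hi"]),
        utilities=_utilities_from_catalogue(shared),
        costs=costs,
        discount_rate=cc["discount_rate"]["value"],
        threshold=cc["threshold_per_qaly"]["value"],
        entry_age=float(shared["entry_age"]["value"]),
        max_age=int(shared["max_age"]["value"]),
        horizon_years="lifetime",
    )
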