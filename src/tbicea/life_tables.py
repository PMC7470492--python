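"""General-population background mortality.

The model multiplies age-specific annual death probabilities ``qx`` from a
life table by standardised mortality ratios to extrapolate survival after
the trial period.  Tables can be read from a two-column CSV (``age,qx``) or
generated parametrically from a Gompertz–Makeham hazard
``h(age) = c + a * exp(b * age)``.  Two synthetic tables calibrated to
UK-like and Pakistan-like adult mortality are bundled with the package;
they are deliberate approximations of the national tables, anchored to
published life-expectancy and adult-death-probability levels, not copies
of official statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "GompertzMakehamParams",
    "make_synthetic_life_table",
    "read_life_table",
    "write_life_table",
    "annual_mortality",
    "life_expectancy",
    "bundled_life_table",
    "UK_SYNTHETIC_PARAMS",
    "PAKISTAN_SYNTHETIC_PARAMS",
]


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Gompertz–Makeham hazard parameters, all per year of age."""

    makeham_c: float
    gompertz_a: float
    gompertz_b: float

    def __post_init__(self) -> None:
        if self.makeham_c < 0:
            raise ValueError("makeham_c must be >= 0")
        if not (self.gompertz_a > 0 and self.gompertz_b > 0):
            raise ValueError("gompertz_a and gompertz_b must be > 0")

    def hazard(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return self.makeham_c + self.gompertz_a * np.exp(self.gompertz_b * age)


#: Synthetic UK-like adult mortality, anchored to 2018-level demographic
#: facts: q(42) ~ 0.0016, period life expectancy ~81.5 at birth and ~41
#: remaining years at age 42.
UK_SYNTHETIC_PARAMS = GompertzMakehamParams(
    makeham_c=3.0e-4, gompertz_a=1.45e-5, gompertz_b=0.100
)

#: Synthetic Pakistan-like adult mortality: q(42) ~ 0.005, life expectancy
#: ~68 at birth and ~32 remaining years at age 42.
PAKISTAN_SYNTHETIC_PARAMS = GompertzMakehamParams(
    makeham_c=2.0e-3, gompertz_a=8.0e-5, gompertz_b=0.087
)


class LifeTable:
    """Annual death probabilities ``qx`` indexed by contiguous integer age.

    The terminal age carries ``qx = 1`` so that a lifetime horizon closes.
    """

    def __init__(self, ages, qx):
        ages = np.asarray(ages, dtype=int)
        qx = np.asarray(qx, dtype=float)
        if ages.ndim != 1 or ages.shape != qx.shape or ages.size == 0:
            raise ValueError("ages and qx must be equal-length 1-D arrays")
        if not np.array_equal(ages, np.arange(ages[0], ages[0] + ages.size)):
            raise ValueError("ages must be contiguous and ascending")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("qx values must lie in [0, 1]")
        if qx[-1] != 1.0:
            raise ValueError("qx at the terminal age must equal 1")
        self.ages = ages
        self.qx = qx

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def __len__(self) -> int:
        return self.ages.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LifeTable)
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.qx, other.qx)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})


def make_synthetic_life_table(
    params: GompertzMakehamParams, max_age: int = 100
) -> LifeTable:
    """Build a life table from a Gompertz–Makeham hazard.

    ``qx(age) = 1 - exp(-h(age))`` for ages ``0..max_age-1`` with the
    terminal age forced to ``qx = 1``.  The construction is deterministic.
    """
    if max_age < 1:
        raise ValueError("max_age must be >= 1")
    ages = np.arange(0, max_age + 1)
    qx = 1.0 - np.exp(-params.hazard(ages))
    qx[-1] = 1.0
    return LifeTable(ages, qx)


def read_life_table(path) -> LifeTable:
    """Read a two-column CSV life table (columns ``age,qx``; header optional)."""
    import io

    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    first_field = text.lstrip().split(",", 1)[0].split("\n", 1)[0].strip()
    has_header = not first_field.lstrip("-").isdigit()
    df = pd.read_csv(io.StringIO(text), header=0 if has_header else None)
    if df.shape[1] < 2:
        raise ValueError("life-table file must have two columns: age, qx")
    df = df.iloc[:, :2]
    df.columns = ["age", "qx"]
    return LifeTable(df["age"].to_numpy(), df["qx"].to_numpy())


def write_life_table(table: LifeTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def annual_mortality(table: LifeTable, age: float) -> float:
    """Annual death probability at ``floor(age)``; ages beyond the table return 1."""
    if age < 0:
        raise ValueError("age must be non-negative")
    idx = int(math.floor(age))
    if idx > table.max_age:
        return 1.0
    if idx < table.min_age:
        raise ValueError(f"age {age} below the table's first age {table.min_age}")
    return float(table.qx[idx - table.min_age])


def life_expectancy(table: LifeTable, from_age: float) -> float:
    """Discrete remaining life expectancy with end-of-year deaths.

    ``LE = sum_k prod_{j<k} (1 - qx(from_age + j))`` — each whole year is
    credited only if survived to its end, so a constant hazard ``q`` gives
    the geometric-series value ``(1 - q) / q``.
    """
    start = int(math.floor(from_age))
    if start > table.max_age:
        raise ValueError("from_age beyond the terminal age")
    q = table.qx[start - table.min_age :]
    surv = np.cumprod(1.0 - q)
    return float(surv.sum())


def bundled_life_table(country: str) -> LifeTable:
    """Load the bundled synthetic life table for ``UK`` or ``Pakistan``."""
    fname = {
        "UK": "life_table_uk_synthetic.csv",
        "Pakistan": "life_table_pakistan_synthetic.csv",
    }.get(country)
    if fname is None:
        raise KeyError(f"no bundled life table for {country!r}")
    with resources.files("tbicea.data").joinpath(fname).open("r") as fh:
        return read_life_table(fh)
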