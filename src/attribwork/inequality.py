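"""Inequality and trend metrics for attributable burden.

Burden counts are converted to rates per 100 000 working-age (>=15 years)
population.  Inequality between groups (regions, sexes, age groups) is
summarised against the global working-age reference rate by the rate
difference (absolute) and the rate ratio (relative).  Reported values use
half-up rounding to one decimal; all arithmetic is done at full precision
first.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "InequalityRecord",
    "rate_per_100k",
    "rate_difference",
    "rate_ratio",
    "trend_change",
    "round_half_up",
    "is_working_age",
    "inequality_report",
]

WORKING_AGE_MIN = 15


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 0.25 -> 0.3 at one decimal, -30.05 -> -30.1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def rate_per_100k(count: float, population: float) -> float:
    """Burden count per 100 000 population."""
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    if count < 0:
        raise ValueError("count must be non-negative")
    return 100_000.0 * count / population


def rate_difference(group_rate: float, reference_rate: float) -> float:
    """Absolute inequality: group rate minus reference rate (signed)."""
    if group_rate < 0 or reference_rate < 0:
        raise ValueError("rates must be non-negative")
    return group_rate - reference_rate


def rate_ratio(group_rate: float, reference_rate: float) -> float:
    """Relative inequality: group rate divided by reference rate."""
    if reference_rate <= 0:
        raise ValueError(f"reference rate must be positive, got {reference_rate}")
    if group_rate < 0:
        raise ValueError("group rate must be non-negative")
    return group_rate / reference_rate


def trend_change(value_start: float, value_end: float) -> tuple[float, float]:
    """Absolute and percent change between two periods.

    Returns (end - start, 100 * (end - start) / start); the percent change
    requires a non-zero start value.
    """
    if value_start == 0:
        raise ValueError("percent change undefined for a zero start value")
    absolute = value_end - value_start
    return absolute, 100.0 * absolute / value_start


@dataclass(frozen=True)
class InequalityRecord:
    """One group's rate against the reference, with both inequality measures."""

    dimension: str
    group: str
    group_rate: float
    reference_rate: float

    @property
    def rate_difference(self) -> float:
        return rate_difference(self.group_rate, self.reference_rate)

    @property
    def rate_ratio(self) -> float:
        return rate_ratio(self.group_rate, self.reference_rate)

    def rounded(self, ndigits: int = 1) -> dict:
        return {
            "dimension": self.dimension,
            "group": self.group,
            "rate": round_half_up(self.group_rate, ndigits),
            "reference_rate": round_half_up(self.reference_rate, ndigits),
            "rate_difference": round_half_up(self.rate_difference, ndigits),
            "rate_ratio": round_half_up(self.rate_ratio, ndigits),
        }


_AGE_RE = re.compile(r"^(\d+)")


def is_working_age(age_group: str) -> bool:
    """True when the age band's lower bound is >= 15 ('15-19' ... '90+')."""
    m = _AGE_RE.match(str(age_group))
    if not m:
        raise ValueError(f"cannot parse age group label {age_group!r}")
    return int(m.group(1)) >= WORKING_AGE_MIN


def _working_age_population(population: pd.DataFrame) -> pd.DataFrame:
    mask = population["age_group"].map(is_working_age)
    return population[mask]


def inequality_report(
    burden: pd.DataFrame,
    population: pd.DataFrame,
    dimension: str,
    measure: str,
    year: int,
    region_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Rates, rate differences and rate ratios for one stratification dimension.

    ``dimension`` is one of 'region', 'sex', 'age_group'.  The reference is
    the global burden per 100 000 working-age population for the same measure
    and year.  Burden rows must carry iso3/sex/age_group columns compatible
    with the requested dimension; population rows are restricted to working
    age for the denominator.
    """
    if dimension not in ("region", "sex", "age_group"):
        raise KeyError(f"dimension must be region, sex or age_group, got {dimension!r}")
    b = burden[(burden["measure"] == measure) & (burden["year"] == year)].copy()
    if b.empty:
        raise ValueError(f"no burden rows for measure={measure!r}, year={year}")
    pop = _working_age_population(population[population["year"] == year].copy())
    if pop.empty:
        raise ValueError(f"no working-age population rows for year {year}")

    reference_rate = rate_per_100k(b["value"].sum(), pop["pop"].sum())

    if dimension == "region":
        if region_map is None:
            raise KeyError("dimension='region' needs a country->region map")
        b["region"] = b["iso3"].map(region_map)
        pop = pop.assign(region=pop["iso3"].map(region_map))
    group_burden = b.groupby(dimension)["value"].sum()
    group_pop = pop.groupby(dimension)["pop"].sum()

    records = []
    for group, count in group_burden.items():
        denom = float(group_pop.get(group, 0.0))
        rec = InequalityRecord(
            dimension=dimension,
            group=str(group),
            group_rate=rate_per_100k(float(count), denom),
            reference_rate=reference_rate,
        )
        records.append(rec.rounded())
    return pd.DataFrame.from_records(records)
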