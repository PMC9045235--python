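"""Population attributable fractions and attributable burden.

Two routes produce a PAF for a risk-outcome pair:

* ``levin_paf`` -- Levin's single-exposed-category formula
  PAF = P(RR-1) / (P(RR-1) + 1) from an exposure prevalence P and a pooled
  relative risk RR (used for the long-working-hours pairs);
* ``transfer_paf`` -- the ratio attributable/total imported from an external
  burden study (used for the established pairs).

Attributable burden is then PAF x envelope, where the envelope is the total
deaths or DALYs of the outcome in a population stratum; totals across pairs
are plain sums (co-attribution overlap between risk factors is not removed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MEASURES = ("deaths", "daly")

#: Stratum columns an attributable-burden table may carry, in canonical order.
STRATUM_COLUMNS = ("iso3", "year", "sex", "age_group")

#: Keys accepted by :func:`aggregate`.
GROUPING_KEYS = ("pair_id", "risk_factor", "outcome", "region", "iso3", "sex", "age_group", "year", "measure")


@dataclass(frozen=True)
class RelativeRisk:
    """Pooled relative risk with its 95% confidence interval."""

    point: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"require 0 < ci_low <= point <= ci_high, got ({self.ci_low}, {self.point}, {self.ci_high})"
            )


@dataclass(frozen=True)
class RiskOutcomePair:
    """One occupational risk factor bound to one health outcome."""

    pair_id: str
    risk_factor: str
    outcome: str
    paf_mode: str  # "levin" | "transfer"
    rr: RelativeRisk | None = None
    measures: tuple[str, ...] = MEASURES

    def __post_init__(self) -> None:
        if self.paf_mode not in ("levin", "transfer"):
            raise ValueError(f"paf_mode must be 'levin' or 'transfer', got {self.paf_mode!r}")
        if self.paf_mode == "levin" and self.rr is None:
            raise ValueError(f"pair {self.pair_id!r} uses the Levin formula and needs a RelativeRisk")
        bad = set(self.measures) - set(MEASURES)
        if bad:
            raise ValueError(f"unknown measures {sorted(bad)}")


def levin_paf(prevalence, rr):
    """Levin PAF for a single exposed category: P(RR-1) / (P(RR-1) + 1).

    Accepts scalars or arrays (broadcast together).  For RR >= 1 the result
    lies in [0, 1); RR in (0, 1) yields a negative (protective) fraction.
    """
    p = np.asarray(prevalence, dtype=float)
    r = np.asarray(rr, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("prevalence must be in [0, 1]")
    if np.any(r <= 0):
        raise ValueError("relative risk must be > 0")
    excess = p * (r - 1.0)
    out = excess / (excess + 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def transfer_paf(attributable: float, total: float) -> float:
    """PAF transferred from an external burden study: attributable / total.

    An empty stratum (total == 0 with attributable == 0) returns 0 with a
    logged warning rather than an error.
    """
    if attributable < 0 or total < 0:
        raise ValueError("counts must be non-negative")
    if total == 0:
        if attributable == 0:
            logger.warning("transfer_paf: empty stratum (total = 0); returning PAF = 0")
            return 0.0
        raise ValueError("attributable > 0 with total = 0")
    if attributable > total:
        raise ValueError(f"attributable ({attributable}) exceeds total ({total})")
    return attributable / total


def simulate_cohort_paf(
    prevalence: float,
    rr: float,
    n_individuals: int = 1_000_000,
    baseline_risk: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Empirical PAF from an individual-level cohort simulation.

    Independent oracle for the Levin formula: each individual is exposed with
    probability ``prevalence`` and becomes a case with probability
    ``baseline_risk`` (unexposed) or ``baseline_risk * rr`` (exposed).  The
    PAF is (cases - counterfactual cases) / cases against the expected
    unexposed-world case count.  Returns (paf_hat, monte_carlo_se) with the SE
    from the binomial variance of the case count via the delta method.
    """
    if rng is None:
        rng = np.random.default_rng()
    risk_exposed = baseline_risk * rr
    if risk_exposed > 1.0:
        raise ValueError("baseline_risk * rr exceeds 1; lower the baseline risk")
    exposed = rng.random(n_individuals) < prevalence
    case_prob = np.where(exposed, risk_exposed, baseline_risk)
    cases = float(np.sum(rng.random(n_individuals) < case_prob))
    if cases == 0:
        raise ValueError("no cases simulated; increase n_individuals or baseline_risk")
    counterfactual = baseline_risk * n_individuals
    paf_hat = (cases - counterfactual) / cases
    var_cases = float(np.sum(case_prob * (1.0 - case_prob)))
    se = counterfactual / cases**2 * np.sqrt(var_cases)
    return paf_hat, se


def _validate_paf_table(paf_table: pd.DataFrame) -> pd.DataFrame:
    required = {"pair_id", "paf"}
    missing = required - set(paf_table.columns)
    if missing:
        raise ValueError(f"PAF table missing columns: {sorted(missing)}")
    vals = paf_table["paf"].to_numpy(dtype=float)
    if np.any((vals < 0) | (vals >= 1)):
        raise ValueError("PAF values must lie in [0, 1)")
    return paf_table


def attributable_burden(
    paf_table: pd.DataFrame,
    envelope: pd.DataFrame,
    pairs: dict[str, RiskOutcomePair] | list[RiskOutcomePair],
) -> pd.DataFrame:
    """Apply per-stratum PAFs to total-burden envelopes.

    ``paf_table`` has columns pair_id, paf and any subset of the stratum
    columns (iso3, year, sex, age_group); a PAF is broadcast across stratum
    dimensions it does not carry.  ``envelope`` has columns cause, iso3, year,
    sex, age_group, measure, value.  Output rows are PAF x envelope value per
    resolvable cell; envelope cells with no matching PAF row are dropped with
    a log message, but an outcome entirely absent from the envelope raises.
    """
    if isinstance(pairs, list):
        pairs = {p.pair_id: p for p in pairs}
    _validate_paf_table(paf_table)
    if np.any(envelope["value"].to_numpy(dtype=float) < 0):
        raise ValueError("envelope values must be non-negative")

    results = []
    for pair_id, sub in paf_table.groupby("pair_id", sort=True):
        if pair_id not in pairs:
            raise KeyError(f"pair {pair_id!r} not in the pair registry")
        pair = pairs[pair_id]
        env = envelope[envelope["cause"] == pair.outcome]
        if env.empty:
            raise KeyError(f"outcome {pair.outcome!r} (pair {pair_id}) absent from the envelope")
        env = env[env["measure"].isin(pair.measures)]
        join_cols = [c for c in STRATUM_COLUMNS if c in sub.columns and c in env.columns]
        merged = env.merge(sub[join_cols + ["paf"]], on=join_cols, how="inner") if join_cols else env.assign(
            paf=float(sub["paf"].iloc[0])
        )
        dropped = len(env) - len(merged)
        if dropped:
            logger.info("pair %s: %d envelope cells had no matching PAF stratum", pair_id, dropped)
        merged = merged.assign(
            pair_id=pair_id,
            risk_factor=pair.risk_factor,
            outcome=pair.outcome,
            value=merged["paf"] * merged["value"],
        )
        results.append(merged)
    cols = ["pair_id", "risk_factor", "outcome", "iso3", "year", "sex", "age_group", "measure", "value"]
    out = pd.concat(results, ignore_index=True)
    return out[[c for c in cols if c in out.columns]]


def aggregate(
    burden: pd.DataFrame,
    by,
    region_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Sum attributable burden over the requested grouping keys.

    ``by`` is an iterable over :data:`GROUPING_KEYS`; grouping by ``region``
    requires either a region column in the table or a country->region map.
    """
    if isinstance(by, str):
        by = [by]
    by = list(by)
    unknown = sorted(set(by) - set(GROUPING_KEYS))
    if unknown:
        raise KeyError(f"unknown grouping keys: {unknown}; allowed: {list(GROUPING_KEYS)}")
    df = burden.copy()
    if "pair_id" in by and "pair_id" not in df.columns:
        raise KeyError("table has no pair_id column")
    if "region" in by and "region" not in df.columns:
        if region_map is None:
            raise KeyError("grouping by region needs a region column or a region_map")
        df["region"] = df["iso3"].map(region_map)
    missing = sorted(set(by) - set(df.columns))
    if missing:
        raise KeyError(f"grouping keys not present in the table: {missing}")
    return df.groupby(by, as_index=False, sort=True)["value"].sum()


def top_pair(table: pd.DataFrame, measure: str, year: int) -> tuple[str, float]:
    """Pair with the largest attributable burden for a measure and year.

    Ties are broken by lexicographically smallest pair_id (logged).
    """
    sub = table[(table["measure"] == measure) & (table["year"] == year)]
    if sub.empty:
        raise ValueError(f"no rows for measure={measure!r}, year={year}")
    totals = sub.groupby("pair_id")["value"].sum().sort_index()
    best = totals.max()
    winners = totals[totals == best].index.tolist()
    if len(winners) > 1:
        logger.warning("top_pair tie between %s; returning %s", winners, winners[0])
    return winners[0], float(best)
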