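"""Synthetic study scenarios with known ground truth.

Generates internally consistent input bundles -- survey observations of
exposure prevalence, total-burden envelopes, populations, transfer-PAF tables
and a risk-outcome pair registry -- from a known logit-linear prevalence
hierarchy, so that every downstream stage (model fitting, attribution,
aggregation, uncertainty) can be tested by parameter recovery without any
external data.

The default configuration emulates a miniature multi-country programme of
labour-force surveys measuring the share of workers on >=55-hour weeks:
3 regions x 5 countries observed 1985-2016, 15 surveys per country of 2000
respondents each, exposure near 10% with modest between-region and
between-country spread and a slow secular decline, and burden envelopes for
the years 2000/2010/2016.  Survey noise is binomial: a survey of size n in a
country-year with true prevalence p reports Binomial(n, p)/n.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from attribwork.attribution import RelativeRisk, RiskOutcomePair, aggregate, levin_paf
from attribwork.exposure import ExposureSurface, LagWindow, expit, window_years

__all__ = ["ScenarioConfig", "ScenarioInputs", "ScenarioTruth", "generate_scenario", "true_burden"]

DEFAULT_AGE_GROUPS = tuple(f"{a}-{a + 4}" for a in range(15, 90, 5)) + ("90+",)

_WHO_REGION_CODES = ("AFR", "AMR", "EMR", "EUR", "SEA", "WPR")


class ConfigurationError(ValueError):
    """A scenario configuration field is invalid."""


def _default_rr() -> dict[str, float]:
    return {"long_hours_ihd": 1.17, "long_hours_stroke": 1.35}


def _default_rr_ci() -> dict[str, tuple[float, float]]:
    return {"long_hours_ihd": (1.05, 1.31), "long_hours_stroke": (1.13, 1.61)}


_PAIR_META = {
    "long_hours_ihd": ("Exposure to long working hours", "Ischemic heart disease", "levin"),
    "long_hours_stroke": ("Exposure to long working hours", "Stroke", "levin"),
    "particulates_copd": (
        "Occupational particulate matter, gases and fumes",
        "Chronic obstructive pulmonary disease",
        "transfer",
    ),
}


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario."""

    n_regions: int = 3
    countries_per_region: int = 5
    years: tuple[int, int] = (1985, 2016)
    age_groups: tuple[str, ...] = DEFAULT_AGE_GROUPS
    sexes: tuple[str, ...] = ("male", "female")
    true_global_logit_prevalence: float = -2.2  # ~10% exposed
    region_sd: float = 0.3
    country_sd: float = 0.3
    annual_trend: float = -0.01  # logit units per year
    survey_sample_size: int = 2000
    surveys_per_country: int = 15
    true_rr_by_pair: dict[str, float] = field(default_factory=_default_rr)
    rr_ci_by_pair: dict[str, tuple[float, float]] = field(default_factory=_default_rr_ci)
    transfer_pairs: tuple[str, ...] = ("particulates_copd",)
    envelope_scale: float = 5000.0
    population_scale: float = 500_000.0
    burden_years: tuple[int, ...] = (2000, 2010, 2016)
    window: LagWindow = field(default_factory=LagWindow)
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        if self.countries_per_region < 1:
            raise ConfigurationError("countries_per_region must be >= 1")
        if len(self.years) != 2 or self.years[1] < self.years[0]:
            raise ConfigurationError("years must be a non-empty inclusive (start, end) range")
        if self.region_sd < 0:
            raise ConfigurationError("region_sd must be >= 0")
        if self.country_sd < 0:
            raise ConfigurationError("country_sd must be >= 0")
        if self.survey_sample_size < 1:
            raise ConfigurationError("survey_sample_size must be >= 1")
        if self.surveys_per_country < 1:
            raise ConfigurationError("surveys_per_country must be >= 1")
        if self.envelope_scale < 0:
            raise ConfigurationError("envelope_scale must be >= 0")
        if self.population_scale <= 0:
            raise ConfigurationError("population_scale must be > 0")
        if not self.burden_years:
            raise ConfigurationError("burden_years must be non-empty")
        for rr_pair, rr in self.true_rr_by_pair.items():
            if rr <= 0:
                raise ConfigurationError(f"true_rr_by_pair[{rr_pair!r}] must be > 0")
        for by in self.burden_years:
            w = window_years(by, self.window)
            if w[0] < self.years[0] or w[-1] > self.years[1]:
                raise ConfigurationError(
                    f"exposure window {w[0]}-{w[-1]} for burden year {by} falls outside the year range"
                )
        for pid in tuple(self.true_rr_by_pair) + tuple(self.transfer_pairs):
            if pid not in _PAIR_META:
                raise ConfigurationError(f"unknown pair id {pid!r}; known: {sorted(_PAIR_META)}")


@dataclass
class ScenarioInputs:
    """The tables a real estimation run would consume."""

    surveys: pd.DataFrame
    envelopes: pd.DataFrame
    population: pd.DataFrame
    transfer_paf: pd.DataFrame
    pairs: pd.DataFrame
    hierarchy: pd.DataFrame  # iso3 -> region

    def hierarchy_map(self) -> dict[str, str]:
        return dict(zip(self.hierarchy["iso3"], self.hierarchy["region"]))

    def pair_registry(self) -> dict[str, RiskOutcomePair]:
        out = {}
        for row in self.pairs.itertuples(index=False):
            rr = None
            if row.paf_mode == "levin":
                rr = RelativeRisk(row.rr_point, row.rr_lo, row.rr_hi)
            out[row.pair_id] = RiskOutcomePair(
                pair_id=row.pair_id,
                risk_factor=row.risk_factor,
                outcome=row.outcome,
                paf_mode=row.paf_mode,
                rr=rr,
            )
        return out


@dataclass
class ScenarioTruth:
    """Ground truth behind a generated scenario."""

    surface: ExposureSurface
    windowed_prevalence: pd.DataFrame  # iso3, burden_year, prevalence
    paf: pd.DataFrame  # pair_id, iso3, year, paf
    burden: pd.DataFrame  # pair_id, risk_factor, outcome, iso3, year, sex, age_group, measure, value
    region_effects: dict[str, float]
    country_effects: dict[str, float]


def _country_codes(n: int) -> list[str]:
    letters = string.ascii_uppercase
    codes = []
    for i in range(n):
        codes.append("X" + letters[i // 26] + letters[i % 26])
    return codes


def _region_codes(n: int) -> list[str]:
    codes = list(_WHO_REGION_CODES[:n])
    codes += [f"R{i:02d}" for i in range(7, n + 1)]
    return codes[:n]


def generate_scenario(config: ScenarioConfig) -> tuple[ScenarioInputs, ScenarioTruth]:
    """Draw one complete scenario: inputs plus matching ground truth.

    Identical config and seed give identical tables (single deterministic
    generator, fixed construction order).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.years
    all_years = list(range(y0, y1 + 1))
    ref_year = 0.5 * (y0 + y1)

    regions = _region_codes(config.n_regions)
    countries = _country_codes(config.n_regions * config.countries_per_region)
    hierarchy = pd.DataFrame(
        {
            "iso3": countries,
            "region": [regions[i // config.countries_per_region] for i in range(len(countries))],
        }
    )
    region_of = dict(zip(hierarchy["iso3"], hierarchy["region"]))

    u_region = {r: float(rng.normal(0.0, config.region_sd)) for r in regions}
    u_country = {c: float(rng.normal(0.0, config.country_sd)) for c in countries}

    # True country x year surface on the logit-linear hierarchy.
    surf_rows = []
    for c in countries:
        base = config.true_global_logit_prevalence + u_region[region_of[c]] + u_country[c]
        for yr in all_years:
            surf_rows.append(
                {
                    "iso3": c,
                    "year": yr,
                    "prevalence": float(expit(base + config.annual_trend * (yr - ref_year))),
                }
            )
    surface = ExposureSurface(pd.DataFrame(surf_rows).assign(se_logit=0.0, extrapolated=False))
    surf_lookup = {(r["iso3"], r["year"]): r["prevalence"] for r in surf_rows}

    # Binomial survey observations at random years.
    survey_rows = []
    for c in countries:
        yrs = rng.integers(y0, y1 + 1, size=config.surveys_per_country)
        for yr in sorted(int(v) for v in yrs):
            p = surf_lookup[(c, yr)]
            k = rng.binomial(config.survey_sample_size, p)
            survey_rows.append(
                {
                    "iso3": c,
                    "year": yr,
                    "prevalence": k / config.survey_sample_size,
                    "sample_size": config.survey_sample_size,
                }
            )
    surveys = pd.DataFrame(survey_rows)

    # Pair registry.
    pair_rows = []
    for pid in sorted(set(config.true_rr_by_pair) | set(config.transfer_pairs)):
        risk_factor, outcome, mode = _PAIR_META[pid]
        if mode == "levin":
            lo, hi = config.rr_ci_by_pair.get(pid, (config.true_rr_by_pair[pid],) * 2)
            pair_rows.append((pid, risk_factor, outcome, mode, config.true_rr_by_pair[pid], lo, hi))
        else:
            pair_rows.append((pid, risk_factor, outcome, mode, np.nan, np.nan, np.nan))
    pairs = pd.DataFrame(
        pair_rows, columns=["pair_id", "risk_factor", "outcome", "paf_mode", "rr_point", "rr_lo", "rr_hi"]
    )
    causes = sorted(pairs["outcome"].unique())

    # Envelopes and population: age profile rises (burden) / falls (population)
    # linearly across age bands, Poisson noise around the stratum mean.
    n_ages = len(config.age_groups)
    age_w = np.linspace(0.5, 1.5, n_ages) if n_ages > 1 else np.ones(1)
    env_rows, pop_rows = [], []
    for c in countries:
        for yr in config.burden_years:
            for sex in config.sexes:
                for ai, ag in enumerate(config.age_groups):
                    pop = int(rng.poisson(config.population_scale * age_w[n_ages - 1 - ai]))
                    pop_rows.append({"iso3": c, "year": yr, "sex": sex, "age_group": ag, "pop": pop})
                    for cause in causes:
                        deaths = int(rng.poisson(config.envelope_scale * age_w[ai]))
                        daly = int(rng.poisson(config.envelope_scale * age_w[ai] * 25.0))
                        env_rows.append(
                            {"cause": cause, "iso3": c, "year": yr, "sex": sex, "age_group": ag,
                             "measure": "deaths", "value": deaths}
                        )
                        env_rows.append(
                            {"cause": cause, "iso3": c, "year": yr, "sex": sex, "age_group": ag,
                             "measure": "daly", "value": daly}
                        )
    envelopes = pd.DataFrame(env_rows)
    population = pd.DataFrame(pop_rows)

    # True windowed prevalence and PAFs per pair/country/burden-year.
    win_rows, paf_rows = [], []
    for c in countries:
        for by in config.burden_years:
            wp = float(np.mean([surf_lookup[(c, yr)] for yr in window_years(by, config.window)]))
            win_rows.append({"iso3": c, "burden_year": by, "prevalence": wp})
            for pid, rr in sorted(config.true_rr_by_pair.items()):
                paf_rows.append({"pair_id": pid, "iso3": c, "year": by, "paf": float(levin_paf(wp, rr))})
    for pid in sorted(config.transfer_pairs):
        for c in countries:
            for by in config.burden_years:
                paf_rows.append(
                    {"pair_id": pid, "iso3": c, "year": by, "paf": float(rng.uniform(0.05, 0.25))}
                )
    truth_paf = pd.DataFrame(paf_rows)
    transfer = truth_paf[truth_paf["pair_id"].isin(config.transfer_pairs)].reset_index(drop=True)

    # True attributable burden = true PAF x envelope, per stratum.
    burden = envelopes.merge(
        truth_paf.rename(columns={"paf": "true_paf"}), on=["iso3", "year"], how="inner"
    )
    outcome_of = dict(zip(pairs["pair_id"], pairs["outcome"]))
    rf_of = dict(zip(pairs["pair_id"], pairs["risk_factor"]))
    burden = burden[burden.apply(lambda r: outcome_of[r["pair_id"]] == r["cause"], axis=1)]
    burden = burden.assign(
        risk_factor=burden["pair_id"].map(rf_of),
        outcome=burden["cause"],
        value=burden["true_paf"] * burden["value"],
    )[["pair_id", "risk_factor", "outcome", "iso3", "year", "sex", "age_group", "measure", "value"]]
    burden = burden.sort_values(["pair_id", "iso3", "year", "sex", "age_group", "measure"]).reset_index(
        drop=True
    )

    inputs = ScenarioInputs(
        surveys=surveys,
        envelopes=envelopes,
        population=population,
        transfer_paf=transfer,
        pairs=pairs,
        hierarchy=hierarchy,
    )
    truth = ScenarioTruth(
        surface=surface,
        windowed_prevalence=pd.DataFrame(win_rows),
        paf=truth_paf,
        burden=burden,
        region_effects=u_region,
        country_effects=u_country,
    )
    return inputs, truth


def true_burden(truth: ScenarioTruth, by) -> pd.DataFrame:
    """Aggregate the ground-truth attributable burden to a grouping.

    Thin wrapper over :func:`attribwork.attribution.aggregate`; the result is
    the recovery target for end-to-end tests.
    """
    return aggregate(truth.burden, by)


def write_scenario(inputs: ScenarioInputs, truth: ScenarioTruth, out_dir) -> dict[str, str]:
    """Write the scenario bundle as tidy CSVs; returns name -> path."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "surveys.csv": inputs.surveys,
        "envelopes.csv": inputs.envelopes,
        "population.csv": inputs.population,
        "transfer_paf.csv": inputs.transfer_paf,
        "pairs.csv": inputs.pairs,
        "regions.csv": inputs.hierarchy,
        "truth_surface.csv": truth.surface.data,
        "truth_windowed_prevalence.csv": truth.windowed_prevalence,
        "truth_paf.csv": truth.paf,
        "truth_burden.csv": truth.burden,
    }
    paths = {}
    for name, df in tables.items():
        path = out / name
        df.to_csv(path, index=False)
        paths[name] = str(path)
    return paths
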