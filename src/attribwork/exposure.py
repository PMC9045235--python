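"""Exposure-prevalence modelling for occupational risk factors.

The prevalence of exposure (e.g. the share of the workforce working >=55 hours
per week) is estimated from national survey observations with a hierarchical
logit-linear model,

    logit(p) = beta0 + u_region + u_country + beta1 * (year - ref_year),

predicted onto a full country x year surface, and then averaged over a lagged
exposure window: attribution of chronic outcomes in burden year Y uses mean
prevalence over a block of `width` consecutive calendar years centred on
Y - lag (default ten years centred on a ten-year lag, so burden year 2016
draws on exposure in 2001-2010).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from attribwork.lmm import LMMFit, fit_lmm

__all__ = [
    "SurveyObservation",
    "LagWindow",
    "ExposureSurface",
    "PrevalenceFit",
    "fit_prevalence_model",
    "predict_prevalence",
    "window_years",
    "windowed_prevalence",
]


def logit(p):
    return np.log(p) - np.log1p(-p)


def expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class SurveyObservation:
    """One survey estimate of exposure prevalence in one country-year."""

    iso3: str
    year: int
    prevalence: float
    sample_size: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if self.sample_size <= 0:
            raise ValueError(f"sample_size must be positive, got {self.sample_size}")


@dataclass(frozen=True)
class LagWindow:
    """Exposure window: `width` consecutive years centred on burden_year - lag."""

    lag: int = 10
    width: int = 10

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError(f"lag must be >= 0, got {self.lag}")
        if self.width < 1:
            raise ValueError(f"width must be >= 1, got {self.width}")


def window_years(burden_year: int, window: LagWindow) -> range:
    """Inclusive calendar years of the lagged exposure window.

    The window is ``window.width`` consecutive years centred on
    ``burden_year - window.lag``; for even widths the centre falls between the
    two middle years so the window ends at ``burden_year - lag + width/2 - 1``
    (2016 with lag 10, width 10 -> 2001..2010).
    """
    centre = burden_year - window.lag
    start = centre - window.width // 2
    return range(start, start + window.width)


@dataclass
class ExposureSurface:
    """Country x year prevalence surface with per-cell logit-scale SEs.

    ``data`` columns: iso3, year, prevalence, se_logit, extrapolated.
    """

    data: pd.DataFrame

    REQUIRED = ("iso3", "year", "prevalence")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"exposure surface missing columns: {missing}")
        p = self.data["prevalence"].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("surface prevalence outside [0, 1]")
        if "se_logit" not in self.data.columns:
            self.data = self.data.assign(se_logit=np.nan)
        if "extrapolated" not in self.data.columns:
            self.data = self.data.assign(extrapolated=False)

    def lookup(self, iso3: str, year: int) -> float:
        rows = self.data[(self.data.iso3 == iso3) & (self.data.year == year)]
        if rows.empty:
            raise KeyError(f"no surface cell for ({iso3}, {year})")
        return float(rows["prevalence"].iloc[0])

    @property
    def countries(self) -> list[str]:
        return sorted(self.data["iso3"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())


@dataclass
class PrevalenceFit:
    """Fitted hierarchical prevalence model (logit scale)."""

    lmm: LMMFit
    hierarchy: dict[str, str]
    ref_year: float
    year_min: int
    year_max: int

    @property
    def intercept(self) -> float:
        return float(self.lmm.beta[0])

    @property
    def trend(self) -> float:
        return float(self.lmm.beta[1])

    @property
    def intercept_se(self) -> float:
        return float(self.lmm.beta_se[0])

    @property
    def trend_se(self) -> float:
        return float(self.lmm.beta_se[1])

    @property
    def region_effects(self) -> dict[str, float]:
        return dict(self.lmm.u_region)

    @property
    def country_effects(self) -> dict[str, float]:
        return dict(self.lmm.u_country)

    def cell_logit(self, iso3: str, year: int) -> tuple[float, float]:
        """Predicted logit prevalence and its SE for one country-year."""
        if iso3 not in self.hierarchy:
            raise KeyError(f"country {iso3!r} absent from the region hierarchy")
        region = self.hierarchy[iso3]
        x = np.array([1.0, year - self.ref_year])
        mean, var = self.lmm.predict_cell(x, region, iso3)
        return mean, math.sqrt(var)


def _observations_frame(observations) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        df = observations.copy()
    else:
        df = pd.DataFrame([vars(o) if isinstance(o, SurveyObservation) else o for o in observations])
    required = ["iso3", "year", "prevalence", "sample_size"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"survey observations missing columns: {missing}")
    if df.empty:
        raise ValueError("no survey observations provided")
    p = df["prevalence"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("survey prevalence outside [0, 1]")
    if np.any(df["sample_size"].to_numpy(dtype=float) <= 0):
        raise ValueError("survey sample_size must be positive")
    return df


def fit_prevalence_model(
    observations,
    hierarchy: dict[str, str] | pd.DataFrame,
    ref_year: float | None = None,
) -> PrevalenceFit:
    """Fit the hierarchical logit-linear prevalence model.

    Observations are weighted by sample size (inverse-variance weighting of
    the logit-transformed proportions up to a common factor).  Survey
    proportions of exactly 0 or 1 are clamped to 1/(4n) from the boundary
    before the logit transform.
    """
    df = _observations_frame(observations)
    if isinstance(hierarchy, pd.DataFrame):
        hierarchy = dict(zip(hierarchy["iso3"], hierarchy["region"]))
    unknown = sorted(set(df["iso3"]) - set(hierarchy))
    if unknown:
        raise KeyError(f"countries missing from the region hierarchy: {unknown}")

    n_s = df["sample_size"].to_numpy(dtype=float)
    p = np.clip(df["prevalence"].to_numpy(dtype=float), 1.0 / (4.0 * n_s), 1.0 - 1.0 / (4.0 * n_s))
    y = logit(p)

    country_levels = sorted(df["iso3"].unique())
    region_levels = sorted({hierarchy[c] for c in country_levels})
    c_idx = np.array([country_levels.index(c) for c in df["iso3"]])
    r_idx = np.array([region_levels.index(hierarchy[c]) for c in df["iso3"]])

    years = df["year"].to_numpy(dtype=float)
    if ref_year is None:
        ref_year = 0.5 * (years.min() + years.max())
    X = np.column_stack([np.ones(len(df)), years - ref_year])

    lmm = fit_lmm(y, X, r_idx, c_idx, n_s, region_levels, country_levels)
    return PrevalenceFit(
        lmm=lmm,
        hierarchy=dict(hierarchy),
        ref_year=float(ref_year),
        year_min=int(years.min()),
        year_max=int(years.max()),
    )


def predict_prevalence(
    fit: PrevalenceFit,
    countries: list[str] | None = None,
    years: list[int] | range | None = None,
) -> ExposureSurface:
    """Predict the prevalence surface for the requested countries and years.

    Years outside the observed range are linear extrapolations on the logit
    scale and are flagged in the output.  Countries never observed must still
    appear in the hierarchy; they receive the region-level prediction with the
    between-country variance added to the SE.
    """
    if countries is None:
        countries = sorted(fit.lmm.country_levels)
    if years is None:
        years = range(fit.year_min, fit.year_max + 1)
    rows = []
    for iso3 in countries:
        for year in years:
            mu, se = fit.cell_logit(iso3, int(year))
            rows.append(
                {
                    "iso3": iso3,
                    "year": int(year),
                    "prevalence": float(expit(mu)),
                    "se_logit": se,
                    "extrapolated": bool(year < fit.year_min or year > fit.year_max),
                }
            )
    return ExposureSurface(pd.DataFrame(rows))


def windowed_prevalence(
    surface: ExposureSurface,
    burden_year: int,
    window: LagWindow,
    allow_extrapolated: bool = True,
) -> pd.DataFrame:
    """Arithmetic mean of annual prevalence over the lagged exposure window.

    Returns one row per country with the window-mean prevalence, the
    logit-scale SE of the mean treating window years as one country-level
    signal (mean of cell SEs, conservative for correlated cells), and a flag
    marking windows that touched extrapolated cells.
    """
    yrs = list(window_years(burden_year, window))
    cells = surface.data[surface.data["year"].isin(yrs)]
    if not allow_extrapolated:
        cells = cells[~cells["extrapolated"].astype(bool)]
    if cells.empty:
        raise ValueError(
            f"exposure surface has no overlap with window {yrs[0]}-{yrs[-1]} for burden year {burden_year}"
        )
    out = (
        cells.groupby("iso3", as_index=False)
        .agg(
            prevalence=("prevalence", "mean"),
            se_logit=("se_logit", "mean"),
            n_years=("year", "nunique"),
            extrapolated=("extrapolated", "any"),
        )
        .assign(burden_year=burden_year)
    )
    return out
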