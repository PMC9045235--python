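"""End-to-end estimation run: exposure fit -> PAF -> attribution -> reports.

`run_pipeline` executes the full chain on tidy-CSV inputs and writes every
documented output table plus a machine-readable run log.  With fixed inputs
and seed the run is byte-reproducible; the log therefore records versions,
the seed and a config echo but no wall-clock timestamps.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import attribwork
from attribwork import io as awio
from attribwork.attribution import aggregate, attributable_burden, levin_paf
from attribwork.exposure import ExposureSurface, LagWindow, fit_prevalence_model, predict_prevalence, window_years, windowed_prevalence
from attribwork.inequality import inequality_report, trend_change
from attribwork.uncertainty import DrawSet, prevalence_draws, propagate, rr_draws, summarize_ur

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Declarative description of one estimation run."""

    surveys: str | None
    envelopes: str
    population: str
    pairs: str
    regions: str
    transfer_paf: str | None = None
    out_dir: str = "results"
    burden_years: tuple[int, ...] = (2000, 2010, 2016)
    lag: int = 10
    width: int = 10
    n_draws: int = 2000
    seed: int = 0
    groupings: tuple[tuple[str, ...], ...] = (("pair_id", "year", "measure"),)
    inequality_dimensions: tuple[str, ...] = ("sex", "age_group")
    round_digits: int = 1

    def __post_init__(self) -> None:
        if not self.burden_years:
            raise ValueError("burden_years must be non-empty")
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")
        if self.seed is None:
            raise ValueError("seed must be set explicitly")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("burden_years", "groupings", "inequality_dimensions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(tuple(g) if isinstance(g, list) else g for g in raw[key])
        return cls(**raw)

    @property
    def window(self) -> LagWindow:
        return LagWindow(lag=self.lag, width=self.width)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("fit-exposure")
def _fit_exposure(config: RunConfig, hierarchy: dict[str, str]) -> ExposureSurface:
    surveys = awio.read_table(config.surveys, "surveys")
    fit = fit_prevalence_model(surveys, hierarchy)
    years_needed = set()
    for by in config.burden_years:
        years_needed.update(window_years(by, config.window))
    years = range(min(years_needed), max(years_needed) + 1)
    return predict_prevalence(fit, years=years)


@_stage("paf")
def _levin_paf_table(config: RunConfig, surface: ExposureSurface, pairs_df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    levin = pairs_df[pairs_df["paf_mode"] == "levin"]
    for by in config.burden_years:
        wp = windowed_prevalence(surface, by, config.window)
        for pr in levin.itertuples(index=False):
            for cell in wp.itertuples(index=False):
                rows.append(
                    {
                        "pair_id": pr.pair_id,
                        "iso3": cell.iso3,
                        "year": by,
                        "paf": float(levin_paf(cell.prevalence, pr.rr_point)),
                    }
                )
    return pd.DataFrame(rows, columns=["pair_id", "iso3", "year", "paf"])


@_stage("bootstrap")
def _bootstrap_ur(
    config: RunConfig,
    surface: ExposureSurface,
    pairs_df: pd.DataFrame,
    envelopes: pd.DataFrame,
    point_burden: pd.DataFrame,
) -> pd.DataFrame:
    """Global 95% URs per levin pair/year/measure from seeded draws."""
    levin = pairs_df[pairs_df["paf_mode"] == "levin"].reset_index(drop=True)
    out = []
    for by in config.burden_years:
        wp = windowed_prevalence(surface, by, config.window)
        wp_surface = ExposureSurface(
            wp.assign(year=by)[["iso3", "year", "prevalence", "se_logit"]].assign(extrapolated=False)
        )
        pdraws = prevalence_draws(wp_surface, config.n_draws, seed=config.seed + by)
        order = pdraws.labels["iso3"].tolist()
        for k, pr in enumerate(levin.itertuples(index=False)):
            rr = attribwork.RelativeRisk(pr.rr_point, pr.rr_lo, pr.rr_hi)
            rdraws = rr_draws(rr, config.n_draws, seed=config.seed * 1009 + 17 * by + k)
            env = envelopes[(envelopes["cause"] == pr.outcome) & (envelopes["year"] == by)]
            for measure in ("deaths", "daly"):
                env_by_country = (
                    env[env["measure"] == measure].groupby("iso3")["value"].sum().reindex(order).fillna(0.0)
                )
                burden_draws = propagate(pdraws, rdraws, env_by_country.to_numpy())
                global_draws = DrawSet(values=burden_draws.values.sum(axis=1), seed=pdraws.seed)
                pt = point_burden[
                    (point_burden["pair_id"] == pr.pair_id)
                    & (point_burden["year"] == by)
                    & (point_burden["measure"] == measure)
                ]["value"].sum()
                ur = summarize_ur(global_draws, float(pt))
                out.append(
                    {
                        "pair_id": pr.pair_id,
                        "year": by,
                        "measure": measure,
                        "value": ur.point,
                        "ur_lower": ur.lower,
                        "ur_upper": ur.upper,
                    }
                )
    return pd.DataFrame(out, columns=["pair_id", "year", "measure", "value", "ur_lower", "ur_upper"])


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full estimation chain; returns name -> written path."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    try:
        pairs_df = awio.read_table(config.pairs, "pairs")
        envelopes = awio.read_table(config.envelopes, "envelopes")
        population = awio.read_table(config.population, "population")
        regions_df = awio.read_table(config.regions, "regions")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'read-inputs' failed: {exc}") from exc
    hierarchy = dict(zip(regions_df["iso3"], regions_df["region"]))

    has_levin = bool((pairs_df["paf_mode"] == "levin").any())
    paf_frames = []
    surface = None
    if has_levin:
        if config.surveys is None:
            raise PipelineError("stage 'fit-exposure' failed: levin pairs present but no surveys file")
        surface = _fit_exposure(config, hierarchy)
        written["exposure_surface"] = awio.write_table(
            surface.data, out_dir / "exposure_surface.csv", "exposure_surface"
        )
        paf_frames.append(_levin_paf_table(config, surface, pairs_df))
    else:
        logger.info("no levin pairs: skipping exposure fitting")

    if config.transfer_paf is not None:
        paf_frames.append(awio.read_table(config.transfer_paf, "transfer_paf")[["pair_id", "iso3", "year", "paf"]])
    if not paf_frames:
        raise PipelineError("stage 'paf' failed: no PAF source (no levin pairs and no transfer table)")
    paf_table = pd.concat(paf_frames, ignore_index=True)

    try:
        registry = {}
        for row in pairs_df.itertuples(index=False):
            rr = None
            if row.paf_mode == "levin":
                rr = attribwork.RelativeRisk(row.rr_point, row.rr_lo, row.rr_hi)
            registry[row.pair_id] = attribwork.RiskOutcomePair(
                pair_id=row.pair_id,
                risk_factor=row.risk_factor,
                outcome=row.outcome,
                paf_mode=row.paf_mode,
                rr=rr,
            )
        burden = attributable_burden(paf_table, envelopes, registry)
        burden = burden.sort_values(list(burden.columns[:-1])).reset_index(drop=True)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'attribute' failed: {exc}") from exc
    written["attributable_burden"] = awio.write_table(burden, out_dir / "attributable_burden.csv", "burden")

    try:
        for by_keys in config.groupings:
            agg = aggregate(burden, list(by_keys), region_map=hierarchy)
            name = "aggregate_" + "_".join(by_keys)
            path = out_dir / f"{name}.csv"
            agg.to_csv(path, index=False)
            written[name] = path
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'aggregate' failed: {exc}") from exc

    try:
        reports = []
        for dim in config.inequality_dimensions:
            for measure in ("deaths", "daly"):
                year = max(config.burden_years)
                rep = inequality_report(burden, population, dim, measure, year, region_map=hierarchy)
                reports.append(rep.assign(measure=measure, year=year))
        ineq = pd.concat(reports, ignore_index=True)
        path = out_dir / "inequality_report.csv"
        ineq.to_csv(path, index=False)
        written["inequality_report"] = path

        trends = []
        y_first, y_last = min(config.burden_years), max(config.burden_years)
        if y_first != y_last:
            totals = burden.groupby(["measure", "year"])["value"].sum()
            for measure in ("deaths", "daly"):
                if (measure, y_first) in totals.index and (measure, y_last) in totals.index:
                    absolute, percent = trend_change(totals[(measure, y_first)], totals[(measure, y_last)])
                    trends.append(
                        {
                            "measure": measure,
                            "year_start": y_first,
                            "year_end": y_last,
                            "value_start": totals[(measure, y_first)],
                            "value_end": totals[(measure, y_last)],
                            "absolute_change": absolute,
                            "percent_change": percent,
                        }
                    )
        path = out_dir / "trends.csv"
        pd.DataFrame(trends).to_csv(path, index=False)
        written["trends"] = path
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'inequality' failed: {exc}") from exc

    if has_levin and surface is not None:
        ur = _bootstrap_ur(config, surface, pairs_df, envelopes, burden)
        written["burden_with_ur"] = awio.write_table(ur, out_dir / "burden_with_ur.csv", "burden_with_ur")

    log = {
        "package": "attribwork",
        "version": attribwork.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "outputs": {k: str(v) for k, v in sorted(written.items())},
    }
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True, default=str) + "\n", encoding="utf-8")
    written["run_log"] = log_path
    return written
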