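"""Bootstrap uncertainty ranges for PAFs and attributable burden.

Uncertainty from the pooled relative risks (lognormal draws parameterised by
the published 95% CI) and from the exposure surface (normal draws on the logit
scale using the model's per-cell SEs) is propagated draw-by-draw through the
Levin PAF and the envelope multiplication.  The 95% uncertainty range (UR) is
the 2.5%/97.5% empirical quantile pair of the draws (linear-interpolation
quantiles); the point estimate is always the computation at the point inputs,
not the draw mean.  Envelope (total burden) uncertainty is not propagated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from attribwork.attribution import RelativeRisk, levin_paf
from attribwork.exposure import ExposureSurface, expit, logit

__all__ = [
    "DrawSet",
    "UncertaintyInterval",
    "rr_draws",
    "prevalence_draws",
    "propagate",
    "summarize_ur",
]

Z975 = 1.959964  # normal 97.5% quantile; CI half-width in sigma units


@dataclass
class DrawSet:
    """Bootstrap realizations: first axis indexes draws."""

    values: np.ndarray
    seed: int | None = None
    labels: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.n_draws < 2:
            raise ValueError("a DrawSet needs at least 2 draws")

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class UncertaintyInterval:
    """95% uncertainty range around a point estimate."""

    point: float
    lower: float
    upper: float
    level: float = 95.0

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"lower ({self.lower}) exceeds upper ({self.upper})")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def rr_draws(rr: RelativeRisk, n_draws: int, seed: int) -> DrawSet:
    """Lognormal relative-risk draws with median rr.point.

    sigma = (ln ci_high - ln ci_low) / (2 * 1.959964); a degenerate CI yields
    constant draws at the point value.
    """
    if rr.ci_low <= 0:
        raise ValueError("ci_low must be positive for lognormal sampling")
    sigma = (np.log(rr.ci_high) - np.log(rr.ci_low)) / (2.0 * Z975)
    rng = np.random.default_rng(seed)
    draws = np.exp(rng.normal(np.log(rr.point), sigma, size=n_draws))
    return DrawSet(values=draws, seed=seed)


def prevalence_draws(surface: ExposureSurface, n_draws: int, seed: int) -> DrawSet:
    """Per-cell normal draws on the logit scale, back-transformed to (0, 1).

    Cells are drawn independently; the labels frame preserves the (iso3,
    year) cell order so draws can be window-averaged per country.
    """
    cells = surface.data.reset_index(drop=True)
    se = cells["se_logit"].to_numpy(dtype=float)
    if np.any(~np.isfinite(se)):
        raise ValueError("every surface cell needs a finite se_logit for bootstrap draws")
    p = np.clip(cells["prevalence"].to_numpy(dtype=float), 1e-12, 1.0 - 1e-12)
    mu = logit(p)
    rng = np.random.default_rng(seed)
    draws = expit(mu[None, :] + rng.normal(size=(n_draws, len(cells))) * se[None, :])
    return DrawSet(values=draws, seed=seed, labels=cells[["iso3", "year"]].copy())


def propagate(prev_draws: DrawSet, rr_drawset: DrawSet, envelope) -> DrawSet:
    """Per-draw Levin PAF times envelope, aligned draw-by-draw.

    ``envelope`` is a scalar or an array broadcastable against the prevalence
    cells (one total-burden value per cell).  Draw i of the prevalence pairs
    with draw i of the RR (independence between the two sources is assumed).
    """
    if prev_draws.n_draws != rr_drawset.n_draws:
        raise ValueError(
            f"draw-count mismatch: prevalence has {prev_draws.n_draws}, RR has {rr_drawset.n_draws}"
        )
    env = np.asarray(envelope, dtype=float)
    if np.any(env < 0):
        raise ValueError("envelope values must be non-negative")
    p = prev_draws.values
    rr = rr_drawset.values.reshape((-1,) + (1,) * (p.ndim - 1))
    paf = levin_paf(p, rr)
    return DrawSet(values=paf * env, seed=prev_draws.seed, labels=prev_draws.labels)


def summarize_ur(draws: DrawSet | np.ndarray, point: float) -> UncertaintyInterval:
    """95% UR from the 2.5% and 97.5% empirical quantiles of the draws.

    Uses the linear-interpolation quantile definition.  The point estimate is
    passed through unchanged.  Fewer than 40 draws triggers a warning because
    the tail quantiles are then poorly determined.
    """
    values = draws.values if isinstance(draws, DrawSet) else np.asarray(draws, dtype=float)
    values = np.ravel(values)
    if values.size == 0:
        raise ValueError("cannot summarise an empty draw set")
    if values.size < 40:
        warnings.warn("fewer than 40 draws: 95% UR quantiles are unstable", stacklevel=2)
    lower, upper = np.quantile(values, [0.025, 0.975], method="linear")
    return UncertaintyInterval(point=float(point), lower=float(lower), upper=float(upper))
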