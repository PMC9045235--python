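# Methods

## Scope and model chain

The package implements the comparative-risk-assessment chain for
occupational risk factors: exposure prevalence is estimated from surveys,
converted into a population attributable fraction (PAF) per risk–outcome
pair, multiplied against the outcome's total-burden envelope (deaths or
DALYs per country/year/sex/age stratum), summed to the reporting level, and
accompanied by bootstrap 95% uncertainty ranges (URs) plus inequality and
trend metrics. Pairs are of two kinds: *levin* pairs, whose PAF is computed
from prevalence and a pooled relative risk, and *transfer* pairs, whose PAF
is imported from an external burden study as `attributable / total`.

## Exposure prevalence model

Survey observations (country, year, observed proportion, sample size) are
modelled on the logit scale as

    logit(p_i) = β₀ + u_region(i) + u_country(i) + β₁ (year_i − ref_year) + ε_i

with `u_region ~ N(0, τ²_r)`, `u_country ~ N(0, τ²_c)` and
`ε_i ~ N(0, σ²/w_i)`, where the weight `w_i` is the survey sample size:
the delta-method variance of a logit-transformed proportion is
`1/(n p (1−p))`, so sample-size weighting is inverse-variance weighting up
to the common factor `1/(p(1−p))` absorbed by σ². Proportions of exactly 0
or 1 are clamped to `1/(4n)` from the boundary before the transform
(continuity correction). The reference year is the midpoint of the observed
range, purely for numerical conditioning.

Fitting is by restricted maximum likelihood, profiling β and σ² so the
search runs over the two variance ratios `τ²/σ²` (Nelder–Mead on the log
scale). REML rather than ML matters here: with a handful of regions, ML
noticeably underestimates the variance components and the resulting
prediction intervals undercover (we observed ≈87% empirical coverage under
ML versus ≈95% under REML at the default scenario scale). Random effects
are empirical-Bayes BLUPs from Henderson's mixed-model equations, and the
inverse MME coefficient matrix supplies the *joint* covariance of
`(β̂ − β, û − u)`, so a cell prediction `β̂₀ + û_r + û_c + β̂₁ t` carries an
SE that correctly accounts for the negative correlation between fixed and
random estimation errors. This joint covariance is the reason the solver is
written in-house (numpy/scipy, dense Cholesky — comfortable to a few
thousand observations) rather than delegated; the identical model fitted
with an established mixed-model package serves as an independent
cross-check in the test suite.

Degenerate inputs: a single region drops the region term; a single country
collapses to weighted least squares with between-group variances reported
as 0. Variance ratios below 1e-8 are treated as structural zeros; noise-free
data drive the ratios to a cap of 1e8, at which point predictions
interpolate the data (recovery to ~1e-6). Predictions for years outside the
observed range are linear logit-scale extrapolations and are flagged;
countries in the hierarchy but never observed receive the region prediction
with the between-country variance added to their SE.

## Lagged exposure window

Chronic outcomes in burden year `Y` are attributed to exposure averaged
over a window of `width` consecutive calendar years centred on `Y − lag`
(defaults: lag 10, width 10, hence 2016 → 2001–2010; for even widths the
window ends at `Y − lag + width/2 − 1`). The windowed prevalence is the
arithmetic mean of the annual values. Changing lag or width changes only
which years are selected, never the fitted surface, which makes sensitivity
analysis on the window a pure re-selection.

## PAF and attribution

Levin's single-exposed-category formula `PAF = P(RR−1)/(P(RR−1)+1)` is used
with the exposed category "≥55 working hours per week" versus all shorter
weeks; multi-category exposure–response is out of scope. The formula is
validated against an independent cohort simulation (individuals exposed
with probability P, case risk `r₀` vs `r₀·RR`, PAF measured as excess cases
over the counterfactual expectation), which agrees within Monte-Carlo
error by construction of the estimand rather than by shared code.

One PAF per (pair, country, year) is broadcast across sex and age strata
unless a stratum-resolved PAF table is supplied. Attributable burden never
exceeds its envelope because PAFs lie in [0, 1); non-fatal outcomes simply
carry all-zero deaths envelopes and propagate zeros without special-casing.
Totals across pairs are plain sums — overlap between risk factors (one
death attributable to two exposures) is deliberately not removed, matching
the convention of the published global totals this package reproduces.

## Inequality and trends

Rates are crude counts per 100 000 working-age (≥15 years) population; no
age standardisation. A group's inequality is summarised by the rate
difference (group − reference) and rate ratio (group / reference), with the
global working-age rate as reference. All arithmetic is done at full
precision; presentation rounding is decimal half-up to one decimal, which
is what reproduces the published rounded values. Trend change is reported
as an absolute difference and a percent change on the start value.

## Uncertainty

Bootstrap draws are seeded and reproducible. Relative risks are drawn
lognormal with median at the point estimate and
`σ = (ln CI_hi − ln CI_lo)/(2 × 1.959964)` — the standard model for ratio
measures. Prevalence cells are drawn normal on the logit scale with the
model's per-cell SE and back-transformed, which keeps every draw in (0, 1).
RR and prevalence draws are independent (the source methods do not state a
joint scheme); cells are also drawn independently of one another, which
understates the within-country correlation of estimation errors across
window years — conservative users can treat per-country URs as slightly
narrow, though in the default conditions RR uncertainty dominates the UR
width by an order of magnitude. Envelope (total-burden) uncertainty is not
propagated. The UR is the 2.5%/97.5% empirical quantile pair under the
linear-interpolation quantile definition (pinned for reproducibility), and
the reported point estimate is the computation at point inputs, not the
draw mean. Scaling an envelope by k > 0 scales draws and both UR limits by
exactly k.

## Synthetic scenarios

The generator emulates a miniature multi-country labour-force-survey
programme: 3 regions × 5 countries observed 1985–2016; true prevalence on
the same logit-linear hierarchy the model assumes (global level −2.2 ≈ 10%
exposed, region and country SDs 0.3, trend −0.01/year — a slow secular
decline in long-hours work); 15 surveys per country (30 in the recovery
scenario) of 2 000 respondents, reporting `Binomial(n, p)/n`; envelopes and
populations drawn Poisson around age-profiled stratum means for burden
years 2000/2010/2016; and a transfer pair with PAFs drawn once per stratum.
The year range 1985–2016 exactly covers the default exposure windows of
those burden years. Truth objects carry the surface, windowed prevalence,
PAFs and stratum-level attributable burden, so recovery is checkable at any
aggregation level.

What the generator does *not* emulate: survey design effects, nonresponse
and weighting; reporting heterogeneity between survey instruments;
sex/age-specific exposure (prevalence is shared across strata by default —
offsets are not part of the default conditions because no published values
exist to calibrate them); spatially correlated envelope errors. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated noise model, not robustness to real-world survey
pathologies.

## Numerical and design choices

- Quantiles: numpy linear interpolation, pinned.
- Rounding: decimal half-up, applied only at report formatting.
- Ties in arg-max queries: lexicographically smallest pair id, logged.
- `transfer_paf(0, 0)` returns 0 with a warning (empty stratum), while
  `attributable > total` is an error.
- Country codes are ISO3 throughout; a packaged lookup maps member states
  to the six WHO regions (AFR, AMR, SEA, EUR, EMR, WPR).
- The packaged per-pair reference table is checksum-pinned; the loader
  validates 41 rows, non-negativity and zero deaths for non-fatal outcomes.
- Pipeline runs are byte-reproducible given config + seed; the run log
  records versions, seed and a config echo, and deliberately no timestamps.
- Experiment sizes (100 end-to-end replicates with 500 draws; 20 Levin
  oracle pairs of 10⁶ individuals) were chosen to keep the whole
  verification run in tens of seconds on one core while leaving
  Monte-Carlo error well inside the decision margins.

## Known limitations

- The hierarchical model is a stated stand-in for the (unpublished in
  detail) production exposure model: logit-linear trend, no
  covariates, no survey-instrument effects; it is validated by recovery on
  synthetic data only.
- Region-level absolute rates require population denominators that are not
  part of the packaged reference table, so regional inequality is exercised
  on synthetic data, not reproduced against published regional figures.
- Published percent-rate-trends derived from unrounded internal totals
  (e.g. a quoted 14.2% decline versus 14.0% from the printed rounded rates)
  are not reproducible from printed inputs and are not targeted.
- The degenerate published lower UR bound equal to the point estimate for
  one subtotal is not modelled; URs here are plain quantile intervals.
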