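"""Two-level random-intercept linear mixed model.

Fits  y_i = x_i'beta + u_{region(i)} + u_{country(i)} + e_i,  with
u_region ~ N(0, tau2_r), u_country ~ N(0, tau2_c) and e_i ~ N(0, sigma2 / w_i),
by restricted maximum likelihood (REML), profiling the fixed effects and the
residual variance so the numerical search runs over the two variance ratios
only.  Random effects
are recovered as BLUPs from Henderson's mixed-model equations, whose inverse
coefficient matrix is the joint covariance of (beta_hat - beta, u_hat - u) and
therefore gives calibrated standard errors for cell-level predictions that
combine fixed and random components.

Desk-scale solver: the marginal covariance is factored densely, which is
comfortable up to a few thousand observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular

# Variance ratios below the floor are treated as structural zeros (the random
# term is dropped); the cap keeps the profiled likelihood finite when the data
# are noise-free and the ratio is unbounded above.
_LAMBDA_FLOOR = 1e-8
_LAMBDA_CAP = 1e8
_SIGMA2_FLOOR = 1e-12


@dataclass
class LMMFit:
    """Fitted model state; all effects on the scale of the response."""

    beta: np.ndarray
    beta_se: np.ndarray
    u_region: dict[str, float]
    u_country: dict[str, float]
    tau2_region: float
    tau2_country: float
    sigma2: float
    region_levels: list[str]
    country_levels: list[str]
    coef: np.ndarray  # stacked [beta, u_region, u_country] solution
    coef_cov: np.ndarray  # joint covariance of estimation errors (same order)
    n_obs: int
    loglik: float

    @property
    def n_fixed(self) -> int:
        return len(self.beta)

    def predict_cell(self, x: np.ndarray, region: str | None, country: str | None) -> tuple[float, float]:
        """Point prediction and variance for x'beta + u_region + u_country.

        Unseen countries (or regions) get a zero effect and an extra variance
        term equal to the corresponding between-group variance, i.e. the
        prediction is for a fresh draw from that level of the hierarchy.
        """
        p, nr = self.n_fixed, len(self.region_levels)
        a = np.zeros(len(self.coef))
        a[:p] = x
        extra = 0.0
        if self.tau2_region > 0.0:
            if region in self.region_levels:
                a[p + self.region_levels.index(region)] = 1.0
            else:
                extra += self.tau2_region
        if self.tau2_country > 0.0:
            if country in self.country_levels:
                a[p + nr + self.country_levels.index(country)] = 1.0
            else:
                extra += self.tau2_country
        mean = float(a @ self.coef)
        var = float(a @ self.coef_cov @ a) + extra
        return mean, max(var, 0.0)


def _profile_neg2ll(
    phi: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    Zr: np.ndarray | None,
    Zc: np.ndarray,
    winv: np.ndarray,
) -> float:
    lam = np.minimum(np.exp(phi), _LAMBDA_CAP)
    n = len(y)
    V0 = np.diag(winv).astype(float)
    k = 0
    if Zr is not None:
        V0 += lam[k] * (Zr @ Zr.T)
        k += 1
    V0 += lam[k] * (Zc @ Zc.T)
    try:
        L = np.linalg.cholesky(V0)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    Xs = solve_triangular(L, X, lower=True)
    ys = solve_triangular(L, y, lower=True)
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    r = ys - Xs @ beta
    p = X.shape[1]
    # REML: profile sigma2 on n - p dof and add the fixed-effects information
    # term, which keeps the variance components honest at small group counts.
    s2 = max(float(r @ r) / (n - p), _SIGMA2_FLOOR)
    sign, logdet_xvx = np.linalg.slogdet(Xs.T @ Xs)
    if sign <= 0:
        return np.inf
    return (n - p) * np.log(2.0 * np.pi * s2) + logdet + logdet_xvx + (n - p)


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    region_idx: np.ndarray,
    country_idx: np.ndarray,
    weights: np.ndarray,
    region_levels: list[str],
    country_levels: list[str],
) -> LMMFit:
    """Fit the two-level model by profiled REML.

    ``region_idx`` / ``country_idx`` are integer codes into the level lists;
    ``weights`` are relative precisions (an observation with weight w has
    residual variance sigma2/w).  A single region collapses the region term;
    a single country collapses the model to weighted least squares.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    w = w / w.mean()
    winv = 1.0 / w

    n_reg, n_ctry = len(region_levels), len(country_levels)
    Zc = np.zeros((n, n_ctry))
    Zc[np.arange(n), country_idx] = 1.0
    use_region = n_reg > 1
    Zr = None
    if use_region:
        Zr = np.zeros((n, n_reg))
        Zr[np.arange(n), region_idx] = 1.0

    if n_ctry <= 1:
        return _fit_wls(y, X, w, region_levels, country_levels, n)

    phi0 = np.full(2 if use_region else 1, np.log(0.1))
    res = optimize.minimize(
        _profile_neg2ll,
        phi0,
        args=(y, X, Zr, Zc, winv),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 600},
    )
    lam = np.minimum(np.exp(res.x), _LAMBDA_CAP)
    lam_r = float(lam[0]) if use_region else 0.0
    lam_c = float(lam[-1])

    # Recompute profiled quantities at the optimum.
    V0 = np.diag(winv).astype(float)
    if use_region:
        V0 += lam_r * (Zr @ Zr.T)
    V0 += lam_c * (Zc @ Zc.T)
    L = np.linalg.cholesky(V0)
    Xs = solve_triangular(L, X, lower=True)
    ys = solve_triangular(L, y, lower=True)
    beta_gls, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta_gls
    sigma2 = max(float(resid @ resid) / (n - p), _SIGMA2_FLOOR)
    tau2_r = lam_r * sigma2 if (use_region and lam_r > _LAMBDA_FLOOR) else 0.0
    tau2_c = lam_c * sigma2 if lam_c > _LAMBDA_FLOOR else 0.0

    # Henderson mixed-model equations for BLUPs and the joint covariance.
    blocks = [X]
    penalties = [np.zeros(p)]
    if tau2_r > 0.0:
        blocks.append(Zr)
        penalties.append(np.full(n_reg, sigma2 / tau2_r))
    if tau2_c > 0.0:
        blocks.append(Zc)
        penalties.append(np.full(n_ctry, sigma2 / tau2_c))
    A = np.hstack(blocks)
    pen = np.concatenate(penalties)
    Wv = w / sigma2
    M = (A * Wv[:, None]).T @ A
    M[np.arange(len(pen)), np.arange(len(pen))] += pen / sigma2
    cf = cho_factor(M)
    sol_active = cho_solve(cf, A.T @ (Wv * y))
    cov_active = cho_solve(cf, np.eye(M.shape[0]))

    # Expand to the full (p + n_reg + n_ctry) layout, zero rows for dropped terms.
    dim = p + n_reg + n_ctry
    coef = np.zeros(dim)
    cov = np.zeros((dim, dim))
    active: list[int] = list(range(p))
    if tau2_r > 0.0:
        active += list(range(p, p + n_reg))
    if tau2_c > 0.0:
        active += list(range(p + n_reg, dim))
    idx = np.asarray(active)
    coef[idx] = sol_active
    cov[np.ix_(idx, idx)] = cov_active

    beta = coef[:p]
    beta_se = np.sqrt(np.diag(cov)[:p])
    u_region = {lv: float(coef[p + i]) for i, lv in enumerate(region_levels)}
    u_country = {lv: float(coef[p + n_reg + i]) for i, lv in enumerate(country_levels)}
    return LMMFit(
        beta=beta,
        beta_se=beta_se,
        u_region=u_region,
        u_country=u_country,
        tau2_region=tau2_r,
        tau2_country=tau2_c,
        sigma2=sigma2,
        region_levels=list(region_levels),
        country_levels=list(country_levels),
        coef=coef,
        coef_cov=cov,
        n_obs=n,
        loglik=-0.5 * float(res.fun),
    )


def _fit_wls(
    y: np.ndarray,
    X: np.ndarray,
    w: np.ndarray,
    region_levels: list[str],
    country_levels: list[str],
    n: int,
) -> LMMFit:
    """Degenerate hierarchy (single country): weighted least squares."""
    p = X.shape[1]
    XtW = (X * w[:, None]).T
    cf = cho_factor(XtW @ X)
    beta = cho_solve(cf, XtW @ y)
    resid = y - X @ beta
    dof = max(n - p, 1)
    sigma2 = max(float(resid @ (w * resid)) / dof, _SIGMA2_FLOOR)
    cov_beta = cho_solve(cf, np.eye(p)) * sigma2
    dim = p + len(region_levels) + len(country_levels)
    coef = np.zeros(dim)
    coef[:p] = beta
    cov = np.zeros((dim, dim))
    cov[:p, :p] = cov_beta
    return LMMFit(
        beta=beta,
        beta_se=np.sqrt(np.diag(cov_beta)),
        u_region={lv: 0.0 for lv in region_levels},
        u_country={lv: 0.0 for lv in country_levels},
        tau2_region=0.0,
        tau2_country=0.0,
        sigma2=sigma2,
        region_levels=list(region_levels),
        country_levels=list(country_levels),
        coef=coef,
        coef_cov=cov,
        n_obs=n,
        loglik=float("nan"),
    )
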