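"""Linear mixed-effects models with continuous-AR(1) residual correlation.

The model regresses water temperature on air temperature, a catchment
factor and site-level environmental covariates, with a per-site random
intercept and air-temperature slope and, optionally, a continuous-time
AR(1) ("CAR(1)") correlation among within-site residuals:

    y_j = X_j beta + Z_j b_j + e_j,      b_j ~ N(0, D),
    e_j ~ N(0, sigma^2 R_j(phi)),        [R_j]_kl = phi ** |t_k - t_l|,

where ``Z_j = [1, Ta]`` and ``t`` is the time covariate in units of the
analysis timescale (days or months).  The CAR(1) form is valid for
non-integer gaps, so irregular series and seasonal gaps need no special
handling.

Estimation maximises the REML (default) or ML marginal likelihood over an
unconstrained parameterization: log-Cholesky factor of ``D / sigma^2``,
scaled-logit ``phi``; ``sigma^2`` and ``beta`` are profiled out in closed
form.  Computation is strictly per-site: the CAR(1) correlation is removed
by the exact gap-aware whitening recursion (O(n) per site) and the 2x2
random-effects block by the Woodbury identity, so no N x N matrix is ever
formed.

Notable numerical conventions
-----------------------------
* Catchment enters as a treatment-coded fixed factor (reference level =
  first alphabetically); a random catchment level is deliberately not used
  because four groups are too few to estimate a variance.
* Degrees of freedom for t tests follow the between-within rule:
  site-level terms are tested against ``n_sites - q_between - 1``,
  observation-level terms against ``N - n_sites - q_within``.
* Likelihood-ratio comparisons of nested fixed structures refit both
  models by ML, never REML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ConvergenceError, DataError
from .synthetic import ENV_COVARIATES

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "FittedLMM",
    "build_design",
    "car_correlation",
    "marginal_loglik",
    "fit",
    "fixed_inference",
    "lrt_compare",
]

_PHI_SCALE = 0.99999  # phi = _PHI_SCALE * expit(psi) keeps phi in [0, 1)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    ``env_covariates`` is the ordered subset of site covariates entering
    the fixed part (after air temperature and catchment).  ``correlation``
    is ``"car1"`` or ``"none"``; ``method`` is ``"REML"`` or ``"ML"``.
    """

    env_covariates: tuple[str, ...] = ENV_COVARIATES
    include_catchment: bool = True
    correlation: str = "car1"
    method: str = "REML"
    center_air: bool = False

    def __post_init__(self) -> None:
        if self.correlation not in ("car1", "none"):
            raise ValueError(f"correlation must be 'car1' or 'none', got {self.correlation!r}")
        if self.method not in ("REML", "ML"):
            raise ValueError(f"method must be 'REML' or 'ML', got {self.method!r}")
        object.__setattr__(self, "env_covariates", tuple(self.env_covariates))


@dataclass
class DesignMatrices:
    """Stacked per-site design blocks, sorted by site then time.

    ``site_starts`` indexes the first row of each site; ``between`` marks
    columns that are constant within every site (site-level terms).
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    t: np.ndarray
    site_starts: np.ndarray
    site_ids: list
    columns: list[str]
    between: np.ndarray

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_sites(self) -> int:
        return len(self.site_starts)

    def site_slices(self):
        bounds = np.append(self.site_starts, self.n_obs)
        for j in range(self.n_sites):
            yield slice(bounds[j], bounds[j + 1])


def build_design(paired: pd.DataFrame, sites: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Assemble stacked design matrices from paired observations and the
    site covariate table.

    ``paired`` needs columns ``site_id, time, ta, tw``; ``sites`` is
    indexed by site id with ``catchment`` plus covariate columns.
    Duplicate (site, time) records and sites without covariates are data
    errors; a catchment factor that is constant after subsetting is
    dropped with a warning.
    """
    required = {"site_id", "time", "ta", "tw"}
    missing = required - set(paired.columns)
    if missing:
        raise DataError(f"paired data lack columns: {sorted(missing)}")
    data = paired.sort_values(["site_id", "time"], kind="stable").reset_index(drop=True)
    if data.duplicated(["site_id", "time"]).any():
        bad = data[data.duplicated(["site_id", "time"])].iloc[0]
        raise DataError(f"duplicate period for site {bad['site_id']} at time {bad['time']}")

    unknown = set(data["site_id"].unique()) - set(sites.index)
    if unknown:
        raise DataError(f"sites without covariate records: {sorted(unknown)[:5]}")
    for cov in spec.env_covariates:
        if cov not in sites.columns:
            raise DataError(f"site table lacks covariate {cov!r}")
    site_info = sites.loc[data["site_id"]]

    cols: list[str] = ["intercept"]
    parts = [np.ones(len(data))]
    ta = data["ta"].to_numpy(dtype=float)
    if spec.center_air:
        ta = ta - ta.mean()
    parts.append(ta)
    cols.append("ta")
    if spec.include_catchment and "catchment" in sites.columns:
        levels = sorted(site_info["catchment"].unique())
        if len(levels) < 2:
            warnings.warn("catchment factor is constant after subsetting; dropped", stacklevel=2)
        else:
            for lev in levels[1:]:  # treatment coding, first level is the reference
                parts.append((site_info["catchment"] == lev).to_numpy(dtype=float))
                cols.append(f"catchment[{lev}]")
    for cov in spec.env_covariates:
        parts.append(site_info[cov].to_numpy(dtype=float))
        cols.append(cov)

    X = np.column_stack(parts)
    _check_full_rank(X, cols)

    codes, site_ids = pd.factorize(data["site_id"], sort=True)
    site_starts = np.searchsorted(codes, np.arange(len(site_ids)))
    dm = DesignMatrices(
        y=data["tw"].to_numpy(dtype=float),
        X=X,
        Z=np.column_stack([np.ones(len(data)), ta]),
        t=data["time"].to_numpy(dtype=float),
        site_starts=site_starts,
        site_ids=list(site_ids),
        columns=cols,
        between=_between_columns(X, site_starts),
    )
    return dm


def _check_full_rank(X: np.ndarray, cols: list[str]) -> None:
    s = np.linalg.svd(X / np.maximum(np.abs(X).max(axis=0), 1e-300), compute_uv=False)
    if s[-1] < 1e-10 * s[0]:
        _, _, v = np.linalg.svd(X / np.maximum(np.abs(X).max(axis=0), 1e-300))
        load = np.abs(v[-1])
        guilty = [c for c, w in zip(cols, load) if w > 0.1 * load.max()]
        raise DataError(f"design matrix is singular; collinear columns: {guilty}")


def _between_columns(X: np.ndarray, site_starts: np.ndarray) -> np.ndarray:
    """Mark columns constant within every site (site-level terms)."""
    bounds = np.append(site_starts, len(X))
    between = np.ones(X.shape[1], dtype=bool)
    for j in range(len(site_starts)):
        block = X[bounds[j] : bounds[j + 1]]
        between &= np.ptp(block, axis=0) < 1e-10
    return between


def car_correlation(phi: float, dt) -> np.ndarray | float:
    """Continuous-time AR(1) correlation ``phi ** dt`` for a gap ``dt``
    in timescale units (valid for non-integer gaps; 1 at ``dt = 0``)."""
    if not 0 <= phi < 1:
        raise ValueError(f"phi must lie in [0, 1), got {phi}")
    dt_arr = np.asarray(dt, dtype=float)
    if np.any(dt_arr < 0):
        raise ValueError("dt must be non-negative")
    out = np.where(dt_arr == 0, 1.0, phi**dt_arr)
    return float(out) if np.isscalar(dt) else out


# ---------------------------------------------------------------------------
# Likelihood internals.  All quantities live in "W units": V = sigma^2 W,
# W_j = Z_j G Z_j' + R_j(phi) with G = D / sigma^2.
# ---------------------------------------------------------------------------


def _whiten(dm: DesignMatrices, phi: float):
    """Remove the CAR(1) correlation by the exact gap recursion.

    Returns whitened copies of (y, X, Z) such that the transformed
    residual correlation is the identity, plus log|R| summed over sites.
    """
    if phi == 0:
        return dm.y, dm.X, dm.Z, 0.0
    first = np.zeros(dm.n_obs, dtype=bool)
    first[dm.site_starts] = True
    dt = np.empty(dm.n_obs)
    dt[0] = 1.0
    dt[1:] = dm.t[1:] - dm.t[:-1]
    c = np.where(first, 0.0, phi ** np.where(first, 1.0, dt))
    s2 = 1.0 - c**2
    inv_s = 1.0 / np.sqrt(s2)

    def tr(a: np.ndarray) -> np.ndarray:
        prev = np.roll(a, 1, axis=0)
        if a.ndim == 1:
            return (a - c * prev) * inv_s
        return (a - c[:, None] * prev) * inv_s[:, None]

    logdet_r = float(np.log(s2[~first]).sum())
    return tr(dm.y), tr(dm.X), tr(dm.Z), logdet_r


def _site_sums(dm, A: np.ndarray, phi: float):
    """Per-site Woodbury pieces for W = Z G Z' + R, G = A A'.

    Returns (S, logdet_w) where S = [X y]' W^{-1} [X y] summed over sites
    and logdet_w = sum_j log|W_j|.
    """
    yt, Xt, Zt, logdet_r = _whiten(dm, phi)
    M = np.column_stack([Xt, yt])
    U = Zt @ A  # (N, 2)
    MtM = M.T @ M

    UtU = np.add.reduceat(U[:, :, None] * U[:, None, :], dm.site_starts, axis=0)
    UtM = np.add.reduceat(U[:, :, None] * M[:, None, :], dm.site_starts, axis=0)
    K = UtU + np.eye(2)[None, :, :]
    L = np.linalg.cholesky(K)
    C = np.linalg.solve(L, UtM)  # (n_sites, 2, p+1), = L^{-1} U'M
    S = MtM - np.einsum("sik,sil->kl", C, C)
    logdet_w = logdet_r + 2.0 * float(np.log(np.einsum("sii->si", L)).sum())
    return S, logdet_w


def _gls_from_sums(S: np.ndarray):
    """GLS solution from the accumulated cross-products."""
    p = S.shape[0] - 1
    sxx, sxy, syy = S[:p, :p], S[:p, p], S[p, p]
    try:
        cf = np.linalg.cholesky(sxx)
    except np.linalg.LinAlgError as exc:
        raise DataError("X'V^{-1}X is singular") from exc
    beta = np.linalg.solve(cf.T, np.linalg.solve(cf, sxy))
    rss = max(float(syy - sxy @ beta), 1e-300)
    logdet_sxx = 2.0 * float(np.log(np.diag(cf)).sum())
    return beta, rss, sxx, logdet_sxx


def _theta_unpack(theta: np.ndarray, use_car: bool):
    # log scales are clipped below: past exp(-9) a variance ratio is
    # numerically zero, and flattening the objective there lets the
    # optimizer terminate instead of drifting to -inf at boundary fits
    l11, a21, l22 = np.clip(theta[0], -9.0, 8.0), theta[1], np.clip(theta[2], -9.0, 8.0)
    A = np.array([[np.exp(l11), 0.0], [a21, np.exp(l22)]])
    phi = _PHI_SCALE / (1.0 + np.exp(-np.clip(theta[3], -30.0, 30.0))) if use_car else 0.0
    return A, phi


def _profiled_neg2ll(theta: np.ndarray, dm: DesignMatrices, method: str, use_car: bool) -> float:
    if not np.all(np.isfinite(theta)):
        return 1e30
    A, phi = _theta_unpack(theta, use_car)
    try:
        S, logdet_w = _site_sums(dm, A, phi)
        beta, rss, _, logdet_sxx = _gls_from_sums(S)
    except (np.linalg.LinAlgError, DataError, FloatingPointError):
        return 1e30
    n, p = dm.n_obs, dm.X.shape[1]
    if method == "ML":
        val = n * np.log(2 * np.pi * rss / n) + n + logdet_w
    else:
        df = n - p
        val = df * np.log(2 * np.pi * rss / df) + df + logdet_w + logdet_sxx
    return float(val) if np.isfinite(val) else 1e30


def marginal_loglik(
    dm: DesignMatrices,
    D: np.ndarray,
    sigma: float,
    phi: float = 0.0,
    method: str = "REML",
) -> float:
    """Marginal Gaussian log-likelihood at given variance parameters.

    ``beta`` is profiled out by GLS.  The per-site covariance is
    ``V_j = Z_j D Z_j' + sigma^2 R_j(phi)``; computation uses per-site
    whitening and 2x2 factorizations, never a dense N x N matrix.  REML
    includes the ``-1/2 log|X' V^{-1} X|`` adjustment.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not 0 <= phi < 1:
        raise ValueError(f"phi must lie in [0, 1), got {phi}")
    D = np.asarray(D, dtype=float)
    w, q = np.linalg.eigh(D / sigma**2)
    if np.any(w < -1e-10):
        raise ValueError("D must be positive semi-definite")
    A = q @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    S, logdet_w = _site_sums(dm, A, phi)
    beta, rss, _, logdet_sxx = _gls_from_sums(S)
    n, p = dm.n_obs, dm.X.shape[1]
    s2 = sigma**2
    if method == "ML":
        n2ll = n * np.log(2 * np.pi * s2) + logdet_w + rss / s2
    elif method == "REML":
        n2ll = (
            (n - p) * np.log(2 * np.pi)
            + (n - p) * np.log(s2)
            + logdet_w
            + logdet_sxx
            + rss / s2
        )
    else:
        raise ValueError(f"method must be 'REML' or 'ML', got {method!r}")
    return -0.5 * float(n2ll)


@dataclass
class FittedLMM:
    """A converged (or diagnosed) mixed-model fit."""

    beta: pd.Series
    beta_cov: pd.DataFrame
    D: np.ndarray
    sigma: float
    phi: float | None
    loglik: float
    method: str
    converged: bool
    n_obs: int
    n_sites: int
    spec: ModelSpec
    design: DesignMatrices = field(repr=False)
    optimizer_message: str = ""

    @property
    def tau00(self) -> float:
        return float(np.sqrt(max(self.D[0, 0], 0.0)))

    @property
    def tau11(self) -> float:
        return float(np.sqrt(max(self.D[1, 1], 0.0)))

    @property
    def re_corr(self) -> float:
        denom = self.tau00 * self.tau11
        return float(self.D[0, 1] / denom) if denom > 0 else 0.0

    def fixed_prediction(self) -> np.ndarray:
        """Population-level predictions X beta (random effects zero)."""
        return self.design.X @ self.beta.to_numpy()


def _start_values(dm: DesignMatrices, use_car: bool) -> list[np.ndarray]:
    """Deterministic multi-start points from OLS-based moment heuristics."""
    beta, *_ = np.linalg.lstsq(dm.X, dm.y, rcond=None)
    resid = dm.y - dm.X @ beta
    s2 = max(float(resid @ resid) / max(dm.n_obs - dm.X.shape[1], 1), 1e-8)
    means = np.array([resid[sl].mean() for sl in dm.site_slices()])
    v0 = max(float(np.var(means)) / s2, 1e-3)
    # lag-1 autocorrelation of residuals at unit gaps, pooled over sites
    num = den = 0.0
    for sl in dm.site_slices():
        r, t = resid[sl], dm.t[sl]
        if len(r) > 2:
            adj = np.isclose(np.diff(t), 1.0)
            num += float((r[1:][adj] * r[:-1][adj]).sum())
            den += float((r**2).sum())
    rho = min(max(num / den if den > 0 else 0.3, 0.05), 0.95)
    psi = np.log(rho / (1 - rho))

    base = np.array([0.5 * np.log(v0), 0.0, 0.5 * np.log(v0) - 3.0, psi][: 3 + use_car])
    starts = [base]
    for shift in ((1.5, 0.0, 1.5, -1.0), (-1.5, 0.0, 0.5, 1.0)):
        starts.append(base + np.array(shift[: 3 + use_car]))
    return starts


def fit(
    paired: pd.DataFrame,
    sites: pd.DataFrame,
    spec: ModelSpec,
    n_starts: int = 3,
) -> FittedLMM:
    """Fit the mixed model by maximizing the REML or ML marginal likelihood.

    Uses an unconstrained parameterization (log-Cholesky for the
    random-effects covariance, scaled logit for ``phi``, with ``sigma`` and
    ``beta`` profiled out) and deterministic multi-start Nelder-Mead
    (default 3 starts) to reduce local-optimum risk.
    """
    dm = build_design(paired, sites, spec)
    return _fit_design(dm, spec, n_starts)


def _fit_design(dm: DesignMatrices, spec: ModelSpec, n_starts: int = 3) -> FittedLMM:
    if dm.n_sites < 2:
        raise DataError(f"need at least 2 sites, got {dm.n_sites}")
    if dm.n_obs < 2 * dm.X.shape[1]:
        warnings.warn(
            f"only {dm.n_obs} observations for {dm.X.shape[1]} fixed parameters",
            stacklevel=2,
        )
    if spec.correlation == "car1":
        for sl in dm.site_slices():
            d = np.diff(dm.t[sl])
            if len(d) and d.min() <= 0:
                raise DataError("duplicate time points within a site")
    use_car = spec.correlation == "car1"

    best = None
    message = ""
    for x0 in _start_values(dm, use_car)[:n_starts]:
        bounds = [(-9.5, 8.5), (-30.0, 30.0), (-9.5, 8.5)] + ([(-30.0, 30.0)] if use_car else [])
        res = optimize.minimize(
            _profiled_neg2ll,
            np.clip(x0, -9.0, 8.0),
            args=(dm, spec.method, use_car),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 300},
        )
        if best is None or res.fun < best.fun:
            best = res
            message = res.message
    # Nelder-Mead polish of the best candidate: derivative-free, immune to
    # the finite-difference noise of the quasi-Newton step near the optimum.
    polish = optimize.minimize(
        _profiled_neg2ll,
        best.x,
        args=(dm, spec.method, use_car),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000, "maxfev": 400},
    )
    ok = bool(best.success)
    if polish.fun <= best.fun:
        ok = ok or bool(polish.success)
        best = polish
    if not ok:
        # rescue pass: a full derivative-free search from the best point
        rescue = optimize.minimize(
            _profiled_neg2ll,
            best.x,
            args=(dm, spec.method, use_car),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000, "maxfev": 8000},
        )
        if rescue.fun <= best.fun:
            best = rescue
            ok = bool(rescue.success)
            message = rescue.message
    converged = ok and best.fun < 1e29

    A, phi = _theta_unpack(best.x, use_car)
    S, _ = _site_sums(dm, A, phi)
    beta, rss, sxx, _ = _gls_from_sums(S)
    n, p = dm.n_obs, dm.X.shape[1]
    s2 = rss / (n - p) if spec.method == "REML" else rss / n
    D = s2 * (A @ A.T)
    beta_cov = s2 * np.linalg.inv(sxx)

    return FittedLMM(
        beta=pd.Series(beta, index=dm.columns),
        beta_cov=pd.DataFrame(beta_cov, index=dm.columns, columns=dm.columns),
        D=D,
        sigma=float(np.sqrt(s2)),
        phi=float(phi) if use_car else None,
        loglik=-0.5 * float(best.fun),
        method=spec.method,
        converged=converged,
        n_obs=n,
        n_sites=dm.n_sites,
        spec=spec,
        design=dm,
        optimizer_message=str(message),
    )


def fixed_inference(fitted: FittedLMM) -> pd.DataFrame:
    """Coefficient table with between-within t tests.

    Site-level terms (catchment contrasts, environmental covariates) are
    tested with ``df = n_sites - q_between - 1``; observation-level terms
    (intercept, air temperature) with ``df = N - n_sites - q_within``.
    """
    if not fitted.converged:
        raise ConvergenceError(
            f"fit did not converge ({fitted.optimizer_message}); refusing inference"
        )
    dm = fitted.design
    between = dm.between.copy()
    between[dm.columns.index("intercept")] = False  # intercept is observation-level
    q_between = int(between.sum())
    q_within = int((~between).sum()) - 1  # excluding the intercept
    df_between = dm.n_sites - q_between - 1
    df_within = dm.n_obs - dm.n_sites - q_within

    se = np.sqrt(np.diag(fitted.beta_cov.to_numpy()))
    coef = fitted.beta.to_numpy()
    tval = np.divide(coef, se, out=np.zeros_like(coef), where=se > 0)
    df = np.where(between, df_between, df_within).astype(float)
    pval = 2.0 * stats.t.sf(np.abs(tval), df)
    return pd.DataFrame(
        {"coef": coef, "se": se, "t": tval, "df": df, "p": pval}, index=fitted.beta.index
    )


def lrt_compare(
    fit_reduced: FittedLMM,
    fit_full: FittedLMM,
    paired: pd.DataFrame,
    sites: pd.DataFrame,
) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fixed-effect structures.

    Both models are refit by ML when necessary (REML log-likelihoods are
    not comparable across fixed structures).  Returns ``(chi2, df, p)``.
    """
    red, full = fit_reduced.spec, fit_full.spec
    if red.correlation != full.correlation:
        raise ValueError("models must share the same correlation structure")
    red_cols = set(fit_reduced.beta.index)
    full_cols = set(fit_full.beta.index)
    if not red_cols <= full_cols:
        raise ValueError(
            f"models are not nested; reduced-only terms: {sorted(red_cols - full_cols)}"
        )
    lls = []
    for fitted in (fit_reduced, fit_full):
        if fitted.method == "ML":
            lls.append(fitted.loglik)
        else:
            refit = fit(paired, sites, replace(fitted.spec, method="ML"))
            lls.append(refit.loglik)
    chi2 = max(2.0 * (lls[1] - lls[0]), 0.0)
    df = len(full_cols) - len(red_cols)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return chi2, df, p
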