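"""Model-assessment statistics for the fitted mixed models.

Implements the variance-partitioning coefficients of determination for
mixed models with random slopes (marginal R2: fixed effects only;
conditional R2: fixed plus random), the adjusted intraclass correlation,
the population-level RMSE, and variance inflation factors with the
conventional cut-off of 10.

The residual variance entering the partition is the stationary
``sigma^2``; the CAR(1) correlation redistributes residual variance over
time but does not change its stationary magnitude, so it is ignored here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConvergenceError, UndefinedMetricError
from .lmm import DesignMatrices, FittedLMM

__all__ = [
    "MetricsReport",
    "r2_nakagawa",
    "icc_adjusted",
    "rmse_population",
    "rmse_conditional",
    "vif",
    "metrics_report",
]

logger = logging.getLogger(__name__)

VIF_CUTOFF = 10.0


@dataclass
class MetricsReport:
    r2_marginal: float
    r2_conditional: float
    icc_adjusted: float
    rmse_population: float
    vif: pd.DataFrame | None
    flagged_terms: list[str]

    def to_dict(self) -> dict:
        return {
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "icc_adjusted": self.icc_adjusted,
            "rmse_population": self.rmse_population,
            "vif": None if self.vif is None else self.vif["vif"].to_dict(),
            "flagged_terms": self.flagged_terms,
        }


def _require_converged(fitted: FittedLMM) -> None:
    if not fitted.converged:
        raise ConvergenceError("metrics require a converged fit")


def _variance_components(fitted: FittedLMM) -> tuple[float, float, float]:
    """(sigma2_fixed, sigma2_random, sigma2_residual) over all observations.

    The random-effect variance is the random-slope extension: the mean over
    observations of ``z_i' D z_i`` with ``z_i = (1, Ta_i)``.
    """
    dm = fitted.design
    fixed = dm.X @ fitted.beta.to_numpy()
    s2_f = float(np.var(fixed))
    s2_r = float(np.einsum("ij,jk,ik->i", dm.Z, fitted.D, dm.Z).mean())
    s2_e = float(fitted.sigma**2)
    return s2_f, s2_r, s2_e


def r2_nakagawa(fitted: FittedLMM) -> tuple[float, float]:
    """Marginal and conditional R2 of a random-slope mixed model.

    ``R2m = s2_f / (s2_f + s2_r + s2_e)`` and
    ``R2c = (s2_f + s2_r) / (s2_f + s2_r + s2_e)``.
    """
    _require_converged(fitted)
    s2_f, s2_r, s2_e = _variance_components(fitted)
    total = s2_f + s2_r + s2_e
    if total <= 0:
        raise UndefinedMetricError("total variance is zero; R2 undefined")
    return s2_f / total, (s2_f + s2_r) / total


def icc_adjusted(fitted: FittedLMM) -> float:
    """Adjusted ICC: share of non-fixed variance attributable to sites,
    ``s2_r / (s2_r + s2_e)`` (equivalently ``(R2c - R2m) / (1 - R2m)``)."""
    _require_converged(fitted)
    _, s2_r, s2_e = _variance_components(fitted)
    if s2_r + s2_e <= 0:
        raise UndefinedMetricError("zero random and residual variance; ICC undefined")
    return s2_r / (s2_r + s2_e)


def rmse_population(fitted: FittedLMM) -> float:
    """RMSE of population-level predictions (random effects set to zero)."""
    _require_converged(fitted)
    resid = fitted.design.y - fitted.fixed_prediction()
    if len(resid) == 0:
        raise UndefinedMetricError("no observations")
    return float(np.sqrt(np.mean(resid**2)))


def rmse_conditional(fitted: FittedLMM) -> float:
    """RMSE of site-conditional predictions using BLUPs of the random
    effects: ``b_j = D Z_j' V_j^{-1} (y_j - X_j beta)``."""
    _require_converged(fitted)
    dm = fitted.design
    phi = fitted.phi or 0.0
    resid = dm.y - fitted.fixed_prediction()
    out = np.empty_like(resid)
    for sl in dm.site_slices():
        z, t, r = dm.Z[sl], dm.t[sl], resid[sl]
        R = phi ** np.abs(t[:, None] - t[None, :]) if phi > 0 else np.eye(len(t))
        V = z @ fitted.D @ z.T + fitted.sigma**2 * R
        b = fitted.D @ z.T @ np.linalg.solve(V, r)
        out[sl] = r - z @ b
    return float(np.sqrt(np.mean(out**2)))


def _term_groups(columns: list[str]) -> dict[str, list[int]]:
    """Group design columns into terms (catchment contrasts form one term)."""
    groups: dict[str, list[int]] = {}
    for i, c in enumerate(columns):
        if c == "intercept":
            continue
        term = "catchment" if c.startswith("catchment[") else c
        groups.setdefault(term, []).append(i)
    return groups


def vif(dm: DesignMatrices) -> pd.DataFrame:
    """Variance inflation factors of the fixed design.

    Single-column terms get the classical ``1 / (1 - R2)`` VIF; the
    multi-column catchment factor gets a generalized VIF (determinant
    ratio of correlation sub-matrices).  Perfectly collinear terms are
    reported as infinite and flagged.
    """
    groups = _term_groups(dm.columns)
    if len(groups) < 2:
        raise ValueError("VIF needs at least 2 non-intercept terms")
    idx = sorted(i for g in groups.values() for i in g)
    Xc = dm.X[:, idx] - dm.X[:, idx].mean(axis=0)
    sd = Xc.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant non-intercept column in design")
    R = np.corrcoef(Xc, rowvar=False)
    pos = {col: k for k, col in enumerate(idx)}

    rows = []
    for term, cols in groups.items():
        own = [pos[c] for c in cols]
        other = [k for k in range(len(idx)) if k not in own]
        det_r = np.linalg.det(R)
        if det_r <= 1e-12:
            value = np.inf
        else:
            det_own = np.linalg.det(R[np.ix_(own, own)])
            det_other = np.linalg.det(R[np.ix_(other, other)])
            value = det_own * det_other / det_r
        rows.append(
            {
                "term": term,
                "df": len(cols),
                "vif": value,
                "flagged": bool(value > VIF_CUTOFF),
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    for term in out.index[out["flagged"]]:
        logger.warning("term %s exceeds the VIF cut-off (%.1f)", term, VIF_CUTOFF)
    return out


def metrics_report(fitted: FittedLMM) -> MetricsReport:
    """Bundle all assessment statistics for one fit."""
    r2m, r2c = r2_nakagawa(fitted)
    try:
        vif_table = vif(fitted.design)
        flagged = list(vif_table.index[vif_table["flagged"]])
    except ValueError:
        vif_table, flagged = None, []
    return MetricsReport(
        r2_marginal=r2m,
        r2_conditional=r2c,
        icc_adjusted=icc_adjusted(fitted),
        rmse_population=rmse_population(fitted),
        vif=vif_table,
        flagged_terms=flagged,
    )
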