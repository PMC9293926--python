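"""All-subsets dominance analysis of environmental predictors.

Relative importance is measured as additional marginal-R2 contributions
over a baseline model (air temperature + catchment, random structure held
fixed).  For predictors ``P`` every subset model ``baseline + S``,
``S subseteq P``, is fitted and its marginal R2 recorded; a predictor's
*additional contribution* to ``S`` is ``R2(S + {x}) - R2(S)``.

Three hierarchically related dominance levels are distinguished for each
ordered pair (x, y):

* **complete** -- x's contribution strictly exceeds y's in every subset
  model excluding both;
* **conditional** -- x's mean contribution strictly exceeds y's at every
  model size;
* **general** -- x's contribution averaged over all model sizes strictly
  exceeds y's.

Complete implies conditional implies general; exact ties yield ``none``.
The general-dominance weights are the Shapley values of the R2 game and
sum to ``R2(P) - R2(empty)``; relative importance expresses each weight as
a percentage of that increment.

The subset fit statistic comes from a pluggable engine: the mixed-model
engine refits the LMM per subset (variance components re-estimated, model
form fixed), and an OLS engine provides the fast surrogate used for exact
cross-checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .exceptions import AnalysisError
from .lmm import ModelSpec, fit

__all__ = [
    "SubsetR2Map",
    "DominanceResult",
    "enumerate_subsets",
    "additional_contribution",
    "conditional_profiles",
    "general_dominance",
    "classify_pair",
    "relative_importance",
    "dominance_analysis",
    "make_lmm_engine",
    "make_ols_engine",
]

#: Mapping from predictor subset (frozenset) to the subset model's R2.
SubsetR2Map = Mapping[frozenset, float]

LEVELS = ("complete", "conditional", "general", "none")


@dataclass
class DominanceResult:
    predictors: tuple[str, ...]
    r2: dict[frozenset, float]
    conditional_profiles: pd.DataFrame  # predictors x model sizes 0..m-1
    general: dict[str, float]
    pairwise: pd.DataFrame  # columns: source, target, level
    relative_importance: dict[str, float]  # percent of baseline-to-full increment

    @property
    def baseline_r2(self) -> float:
        return self.r2[frozenset()]

    @property
    def full_r2(self) -> float:
        return self.r2[frozenset(self.predictors)]

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "baseline_r2": self.baseline_r2,
            "full_r2": self.full_r2,
            "subset_r2": {",".join(sorted(k)): v for k, v in self.r2.items()},
            "conditional_profiles": {
                p: list(self.conditional_profiles.loc[p]) for p in self.predictors
            },
            "general_dominance": self.general,
            "relative_importance_pct": self.relative_importance,
            "pairwise_levels": self.pairwise.to_dict(orient="records"),
        }


def enumerate_subsets(r2_fn: Callable[[tuple], float], predictors: Sequence[str]) -> dict[frozenset, float]:
    """Evaluate the fit statistic for every subset of ``predictors``.

    ``r2_fn`` receives a sorted tuple of predictor names (the canonical
    cache key) and returns the subset model's R2.  Any failure aborts the
    analysis, listing the offending subsets.
    """
    predictors = list(predictors)
    if len(predictors) > 12:
        raise ValueError(f"{len(predictors)} predictors imply {2**len(predictors)} refits; cap is 12")
    out: dict[frozenset, float] = {}
    failures: list[tuple] = []
    for k in range(len(predictors) + 1):
        for combo in combinations(predictors, k):
            key = tuple(sorted(combo))
            try:
                out[frozenset(key)] = float(r2_fn(key))
            except Exception:
                failures.append(key)
    if failures:
        raise AnalysisError(f"subset models failed: {failures}")
    return out


def additional_contribution(r2_map: SubsetR2Map, x: str, subset: Sequence[str]) -> float:
    """``R2(S + {x}) - R2(S)``; may be negative when subset refits shift
    the variance components."""
    s = frozenset(subset)
    if x in s:
        raise ValueError(f"predictor {x!r} already in subset {sorted(s)}")
    return r2_map[s | {x}] - r2_map[s]


def conditional_profiles(r2_map: SubsetR2Map, predictors: Sequence[str]) -> pd.DataFrame:
    """Mean additional contribution of each predictor at each model size
    ``k = 0 .. m-1`` (size of the subset before the predictor joins)."""
    predictors = list(predictors)
    m = len(predictors)
    prof = pd.DataFrame(0.0, index=predictors, columns=range(m))
    for x in predictors:
        others = [p for p in predictors if p != x]
        for k in range(m):
            vals = [additional_contribution(r2_map, x, s) for s in combinations(others, k)]
            prof.loc[x, k] = float(np.mean(vals))
    return prof


def general_dominance(r2_map: SubsetR2Map, predictors: Sequence[str]) -> dict[str, float]:
    """Average of the conditional profile over model sizes: the Shapley
    value of the R2 game; weights sum to ``R2(full) - R2(baseline)``."""
    expected = 2 ** len(list(predictors))
    if len(r2_map) != expected:
        raise ValueError(f"incomplete subset map: {len(r2_map)} of {expected} entries")
    prof = conditional_profiles(r2_map, predictors)
    return {p: float(prof.loc[p].mean()) for p in prof.index}


def classify_pair(r2_map: SubsetR2Map, x: str, y: str, predictors: Sequence[str]) -> tuple[str, str | None]:
    """Strongest dominance level attained between ``x`` and ``y``.

    Returns ``(level, winner)`` with level in :data:`LEVELS`; ``winner`` is
    ``None`` for ``"none"`` (exact tie or no consistent direction).
    Strict inequality is required at every level.
    """
    if x == y:
        raise ValueError("cannot classify a predictor against itself")
    predictors = list(predictors)
    others = [p for p in predictors if p not in (x, y)]

    diffs = [
        additional_contribution(r2_map, x, s) - additional_contribution(r2_map, y, s)
        for k in range(len(others) + 1)
        for s in combinations(others, k)
    ]
    if all(d > 0 for d in diffs):
        return "complete", x
    if all(d < 0 for d in diffs):
        return "complete", y

    prof = conditional_profiles(r2_map, predictors)
    px, py = prof.loc[x], prof.loc[y]
    if (px > py).all():
        return "conditional", x
    if (py > px).all():
        return "conditional", y

    gx, gy = float(px.mean()), float(py.mean())
    if gx > gy:
        return "general", x
    if gy > gx:
        return "general", y
    return "none", None


def relative_importance(general: Mapping[str, float], r2_map: SubsetR2Map, predictors: Sequence[str]) -> dict[str, float]:
    """Each predictor's general-dominance weight as a percentage of the
    baseline-to-full R2 increment (sums to 100)."""
    increment = r2_map[frozenset(predictors)] - r2_map[frozenset()]
    if increment <= 0:
        raise AnalysisError(f"baseline-to-full R2 increment is {increment:.3g}; shares undefined")
    return {p: 100.0 * general[p] / increment for p in predictors}


def dominance_analysis(r2_fn: Callable[[tuple], float], predictors: Sequence[str]) -> DominanceResult:
    """Run the full analysis: enumerate subsets, build profiles and
    weights, classify every ordered pair, and verify the dominance
    hierarchy (complete implies conditional implies general)."""
    predictors = tuple(predictors)
    r2_map = enumerate_subsets(r2_fn, predictors)
    prof = conditional_profiles(r2_map, predictors)
    general = {p: float(prof.loc[p].mean()) for p in predictors}

    rows = []
    for x, y in combinations(predictors, 2):
        level, winner = classify_pair(r2_map, x, y, predictors)
        if winner is not None:
            _assert_hierarchy(prof, level, winner, y if winner == x else x)
            rows.append({"source": winner, "target": y if winner == x else x, "level": level})
        else:
            rows.append({"source": x, "target": y, "level": "none"})
    pairwise = pd.DataFrame(rows, columns=["source", "target", "level"])

    try:
        shares = relative_importance(general, r2_map, predictors)
    except AnalysisError:
        # degenerate run (non-positive baseline-to-full increment): keep
        # the weights but report no percentage shares
        warnings.warn("baseline-to-full R2 increment is not positive; no shares", stacklevel=2)
        shares = {}
    return DominanceResult(
        predictors=predictors,
        r2=r2_map,
        conditional_profiles=prof,
        general=general,
        pairwise=pairwise,
        relative_importance=shares,
    )


def _assert_hierarchy(prof: pd.DataFrame, level: str, winner: str, loser: str) -> None:
    """Complete dominance must be visible at the conditional and general
    levels too; a violation indicates a broken subset map."""
    if level != "complete":
        return
    pw, pl = prof.loc[winner], prof.loc[loser]
    if not ((pw > pl).all() and pw.mean() > pl.mean()):
        raise AnalysisError(
            f"dominance hierarchy inverted for {winner} over {loser}; subset map inconsistent"
        )


# ---------------------------------------------------------------------------
# Fit engines
# ---------------------------------------------------------------------------


def make_lmm_engine(
    paired: pd.DataFrame,
    sites: pd.DataFrame,
    base_spec: ModelSpec,
    n_starts: int = 3,
) -> Callable[[tuple], float]:
    """Marginal-R2 engine refitting the mixed model per predictor subset.

    The baseline fixed structure is air temperature (+ catchment when the
    spec includes it); the random and correlation structure of
    ``base_spec`` is held fixed across subsets while variance components
    are re-estimated.  Fits are cached by canonical subset key; a
    non-converged subset fit raises.
    """
    cache: dict[tuple, float] = {}

    def engine(subset: tuple) -> float:
        key = tuple(sorted(subset))
        if key not in cache:
            spec = replace(base_spec, env_covariates=key)
            fitted = fit(paired, sites, spec, n_starts=n_starts)
            if not fitted.converged:
                raise AnalysisError(f"subset model {key} did not converge")
            cache[key] = metrics.r2_nakagawa(fitted)[0]
        return cache[key]

    return engine


def make_ols_engine(
    X: pd.DataFrame,
    y: np.ndarray,
    baseline: Sequence[str] = (),
) -> Callable[[tuple], float]:
    """Plain-OLS R2 engine: the surrogate for exact Shapley cross-checks.

    Each subset model regresses ``y`` on an intercept, the baseline
    columns and the subset columns of ``X``.
    """
    y = np.asarray(y, dtype=float)

    def engine(subset: tuple) -> float:
        cols = [*baseline, *subset]
        design = np.column_stack([np.ones(len(y))] + [X[c].to_numpy(dtype=float) for c in cols])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        tss = float(((y - y.mean()) ** 2).sum())
        return 1.0 - float((resid**2).sum()) / tss

    return engine
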