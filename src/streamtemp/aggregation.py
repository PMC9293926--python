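"""Hourly-to-daily/monthly aggregation under a completeness threshold.

A mean daily or monthly temperature is computed from the hourly records of
that calendar unit only when at least a fraction ``threshold`` (default
0.75) of the unit's hours carry a value; otherwise the unit is a missing
observation.  Expected hours are calendar hours -- 24 per day and
24 * days-in-month per month, leap-year aware -- regardless of how much of
the unit the series happens to cover.  Monthly means are computed from the
hourly data directly, never as means of daily means.

Pairing intersects the air and water channels: a paired observation exists
only for periods where both means are present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError

__all__ = ["AggregatedSeries", "aggregate", "pair", "flag_air_exposure"]

_FREQ = {"day": "D", "month": "M"}


@dataclass
class AggregatedSeries:
    """Aggregated means for one site at one timescale.

    ``frame`` is indexed by ``pandas.Period`` and carries ``mean_air``,
    ``mean_water``, per-channel present-hour counts and the expected hour
    count of each calendar unit.
    """

    site_id: str | None
    unit: str
    frame: pd.DataFrame


def _validate_hourly(series: pd.DataFrame) -> pd.Series:
    if "timestamp" not in series.columns:
        raise DataError("hourly series must have a 'timestamp' column")
    ts = pd.to_datetime(series["timestamp"])
    if ts.duplicated().any():
        dup = ts[ts.duplicated()].iloc[0]
        raise DataError(f"duplicated hourly timestamp: {dup}")
    if not ((ts.dt.minute == 0) & (ts.dt.second == 0)).all():
        raise DataError("timestamps must fall on exact hours")
    if not ts.is_monotonic_increasing:
        raise DataError("timestamps must be sorted in increasing order")
    return ts


def aggregate(
    series: pd.DataFrame,
    unit: str,
    threshold: float = 0.75,
    site_id: str | None = None,
) -> AggregatedSeries:
    """Aggregate an hourly air/water series to daily or monthly means.

    The completeness comparison is inclusive: a unit with exactly 75% of
    its hours present (18 of 24 for a day) is kept.
    """
    if unit not in _FREQ:
        raise ValueError(f"unit must be 'day' or 'month', got {unit!r}")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    ts = _validate_hourly(series)
    periods = ts.dt.to_period(_FREQ[unit])

    rows = {}
    for channel in ("air", "water"):
        vals = pd.to_numeric(series[channel], errors="coerce") if channel in series else pd.Series(np.nan, index=series.index)
        grp = vals.groupby(periods)
        rows[f"n_{channel}"] = grp.count()
        rows[f"sum_{channel}"] = grp.sum(min_count=1)

    out = pd.DataFrame(rows)
    if unit == "day":
        expected = pd.Series(24, index=out.index)
    else:
        expected = pd.Series([p.days_in_month * 24 for p in out.index], index=out.index)
    out["n_hours_expected"] = expected
    for channel in ("air", "water"):
        ok = out[f"n_{channel}"] / out["n_hours_expected"] >= threshold
        mean = out[f"sum_{channel}"] / out[f"n_{channel}"]
        out[f"mean_{channel}"] = mean.where(ok)
        out = out.drop(columns=f"sum_{channel}")
    out.index.name = "period"
    out = out[["mean_air", "mean_water", "n_air", "n_water", "n_hours_expected"]]
    return AggregatedSeries(site_id or series.attrs.get("site_id"), unit, out)


def pair(air_agg: AggregatedSeries, water_agg: AggregatedSeries | None = None) -> pd.DataFrame:
    """Pair aggregated air and water means into model-ready observations.

    Accepts either one combined :class:`AggregatedSeries` (both channels
    aggregated together) or separate air and water aggregations of the
    same site and unit.  Returns a DataFrame with columns
    ``site_id, period, time, ta, tw`` where ``time`` is the numeric CAR
    time covariate in units of the timescale (day or month ordinals), with
    one row per period where both means are present, sorted by time.
    """
    if water_agg is None:
        water_agg = air_agg
    if air_agg.unit != water_agg.unit:
        raise ValueError(f"unit mismatch: {air_agg.unit} vs {water_agg.unit}")
    if air_agg.site_id != water_agg.site_id:
        raise ValueError(f"site mismatch: {air_agg.site_id} vs {water_agg.site_id}")
    ta = air_agg.frame["mean_air"].dropna()
    tw = water_agg.frame["mean_water"].dropna()
    common = ta.index.intersection(tw.index).sort_values()
    return pd.DataFrame(
        {
            "site_id": air_agg.site_id,
            "period": common.astype(str),
            "time": np.array([p.ordinal for p in common], dtype=float),
            "ta": ta.loc[common].to_numpy(),
            "tw": tw.loc[common].to_numpy(),
        }
    )


def pair_sites(aggs: list[AggregatedSeries]) -> pd.DataFrame:
    """Concatenate :func:`pair` output over many sites."""
    frames = [pair(a) for a in aggs]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=["site_id", "period", "time", "ta", "tw"])
    return pd.concat(frames, ignore_index=True)


def flag_air_exposure(
    series: pd.DataFrame,
    window: int = 168,
    range_ratio_threshold: float = 2.0,
    track_tolerance: float = 1.0,
) -> set:
    """Heuristic screen for periods where a water logger sat in air.

    An exposed water logger stops recording damped stream temperatures and
    starts tracking air: its diel range inflates and its level converges
    on the air channel.  The series is cut into consecutive windows of
    ``window`` hours (>= 24); a window is flagged -- and all its days
    returned as ``pandas.Period`` values -- when the water channel's mean
    diel range exceeds ``range_ratio_threshold`` times the series-median
    diel range *and* water tracks air within ``track_tolerance`` degrees C
    on average.
    """
    if window < 24:
        raise ValueError(f"window must be at least 24 hours, got {window}")
    ts = _validate_hourly(series)
    df = series.assign(_day=ts.dt.to_period("D"))
    diel = df.groupby("_day")["water"].agg(lambda v: np.nan if v.isna().all() else v.max() - v.min())
    median_range = diel.median()
    if not np.isfinite(median_range) or median_range == 0:
        median_range = np.nan  # constant or empty water channel: nothing to compare against

    flagged: set = set()
    n_windows = int(np.ceil(len(df) / window))
    for w in range(n_windows):
        block = df.iloc[w * window : (w + 1) * window]
        water, air = block["water"], block["air"]
        if water.isna().all() or air.isna().all():
            continue
        days = block["_day"].unique()
        win_range = diel.loc[days].mean()
        tracks = (water - air).abs().mean() <= track_tolerance
        if np.isfinite(median_range) and win_range > range_ratio_threshold * median_range and tracks:
            flagged.update(days)
    return flagged


def apply_flags(series: pd.DataFrame, flagged: set) -> pd.DataFrame:
    """Blank the water channel on flagged days (screening enabled path)."""
    if not flagged:
        return series.copy()
    out = series.copy()
    out.attrs = dict(series.attrs)
    days = pd.to_datetime(out["timestamp"]).dt.to_period("D")
    out.loc[days.isin(list(flagged)), "water"] = np.nan
    return out


def filter_months(paired: pd.DataFrame, months: list[int] | None) -> pd.DataFrame:
    """Optionally restrict paired observations to calendar months
    (e.g. ``[6, 7, 8, 9]`` for a June-September summer analysis)."""
    if not months:
        return paired
    period_months = pd.to_datetime(paired["period"].astype(str)).dt.month.to_numpy()
    keep = np.isin(period_months, months)
    if keep.all():
        return paired
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return paired.loc[keep].reset_index(drop=True)
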