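"""Synthetic multi-site air-water temperature data.

This module generates the two ingredients every downstream stage consumes:

* a *site table* -- one row per monitoring station with a catchment label
  and five environmental covariates (cultivated area %, Quaternary and
  pre-Quaternary volcanic geology %, reach elevation, riparian forest %);
* paired *temperature series* -- hourly logger-style records, or mean
  daily/monthly observations generated directly at the analysis timescale.

Water temperature follows the random-slope air-water mixed model: for
observation ``i`` at site ``j``

    Tw_ij = alpha + catchment_offset + (beta_air + b1_j) * Ta_ij
            + sum_x beta_x * x_j + b0_j + e_ij

with ``(b0_j, b1_j)`` a per-site bivariate normal random intercept/slope
and ``e`` a continuous-time AR(1) ("CAR(1)") residual process whose
correlation over a time gap ``dt`` is ``phi ** dt``.  Residuals are built
by the exact gap-aware recursion

    e_t = phi**dt * e_{t-dt} + sigma * sqrt(1 - phi**(2 dt)) * z,

which keeps the stationary variance at ``sigma**2`` for any gap pattern.

Default truth parameters put the generator in the regime of a 130-station,
four-catchment summer monitoring network in mid- to low-order streams
(daily residual lag-1 correlation 0.962, residual SD 1.5 C, between-site
intercept SD ~1 C).

Seeding is hierarchical: a master seed spawns one independent stream per
site, so adding sites never perturbs the series of existing ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ENV_COVARIATES",
    "CATCHMENT_NAMES",
    "TruthParams",
    "AirParams",
    "generate_sites",
    "generate_air_series",
    "generate_water_obs",
    "inject_missingness",
    "thermal_smooth",
    "simulate_paired_dataset",
    "site_rng",
]

#: The five environmental covariates, in report order.
ENV_COVARIATES = (
    "cultivated",
    "volc_quaternary",
    "volc_prequaternary",
    "elevation",
    "riparian_forest",
)

#: Default catchment labels (reference level is the first alphabetically).
CATCHMENT_NAMES = ("Hiji", "Kiso", "Sorachi", "Teshio")

HOURS_PER_DAY = 24
#: Mean Gregorian month length in days, used to express datetime gaps in
#: month units for monthly-scale CAR residuals.
DAYS_PER_MONTH = 30.4375

# Bounded covariate distributions: percentages are scaled Betas (stay in
# [0, 100] by construction), elevation a truncated log-normal in metres.
DEFAULT_COVARIATE_CONFIG: dict[str, dict] = {
    "cultivated": {"dist": "beta", "a": 1.3, "b": 5.0, "scale": 100.0},
    "volc_quaternary": {"dist": "beta", "a": 1.2, "b": 3.8, "scale": 100.0},
    "volc_prequaternary": {"dist": "beta", "a": 1.2, "b": 4.8, "scale": 100.0},
    "elevation": {"dist": "lognormal", "mu": 5.1, "sigma": 0.5, "lo": 20.0, "hi": 600.0},
    "riparian_forest": {"dist": "beta", "a": 4.5, "b": 1.8, "scale": 100.0},
}


@dataclass(frozen=True)
class TruthParams:
    """True generative parameters of the air-water mixed model.

    ``tau00``/``tau11`` are the between-site SDs of the random intercept
    and air-temperature slope, ``d_corr`` their correlation, ``sigma`` the
    residual SD (degrees C) and ``phi`` the residual correlation at a gap
    of one unit of ``timescale``.
    """

    alpha: float = 14.425
    beta_air: float = 0.315
    beta_env: Mapping[str, float] = field(
        default_factory=lambda: {
            "cultivated": 0.033,
            "volc_quaternary": -0.018,
            "volc_prequaternary": -0.002,
            "elevation": -0.044,
            "riparian_forest": -0.013,
        }
    )
    catchment_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"Kiso": -0.327, "Sorachi": -3.922, "Teshio": -3.626}
    )
    tau00: float = 1.081
    tau11: float = 0.09
    d_corr: float = 0.0
    sigma: float = 1.518
    phi: float = 0.962
    timescale: str = "day"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.tau00 < 0 or self.tau11 < 0:
            raise ValueError("tau00 and tau11 must be >= 0")
        if not -1 < self.d_corr < 1:
            raise ValueError(f"d_corr must lie in (-1, 1), got {self.d_corr}")
        if not 0 <= self.phi < 1:
            raise ValueError(f"phi must lie in [0, 1), got {self.phi}")
        if self.timescale not in ("day", "month"):
            raise ValueError(f"timescale must be 'day' or 'month', got {self.timescale!r}")

    @classmethod
    def daily(cls, **overrides) -> "TruthParams":
        """Daily-scale defaults (the class defaults)."""
        return cls(**{"timescale": "day", **overrides})

    @classmethod
    def monthly(cls, **overrides) -> "TruthParams":
        """Monthly-scale defaults: steeper air slope, smaller residual SD,
        no residual autocorrelation."""
        base = dict(
            alpha=6.647,
            beta_air=0.622,
            beta_env={
                "cultivated": 0.043,
                "volc_quaternary": -0.019,
                "volc_prequaternary": -0.008,
                "elevation": -0.022,
                "riparian_forest": -0.006,
            },
            catchment_offsets={"Kiso": -0.702, "Sorachi": -1.987, "Teshio": -1.544},
            tau00=1.323,
            tau11=0.135,
            d_corr=0.0,
            sigma=0.826,
            phi=0.0,
            timescale="month",
        )
        base.update(overrides)
        return cls(**base)

    def replace(self, **overrides) -> "TruthParams":
        return dataclasses.replace(self, **overrides)

    def random_effects_cov(self) -> np.ndarray:
        """2x2 covariance of the per-site (intercept, slope) deviations."""
        off = self.d_corr * self.tau00 * self.tau11
        return np.array([[self.tau00**2, off], [off, self.tau11**2]])


@dataclass(frozen=True)
class AirParams:
    """Air-temperature generator: site mean (with a weak elevational lapse)
    plus annual and diel sinusoids and stationary AR(1) hourly noise."""

    mean_level: float = 20.0  # C at sea level
    lapse_rate: float = 0.004  # C lost per metre of reach elevation
    annual_amplitude: float = 10.0  # C, peak-to-mean of the annual cycle
    diel_amplitude: float = 3.0  # C, half the mean diel range
    annual_peak_doy: float = 215.0  # day of year of the warmest day
    diel_peak_hour: float = 14.0  # local hour of the warmest hour
    ar_coef: float = 0.7  # hourly lag-1 autocorrelation of the noise
    noise_sd: float = 1.5  # stationary SD of the AR(1) noise, C

    def __post_init__(self) -> None:
        if not -1 < self.ar_coef < 1:
            raise ValueError(f"ar_coef must lie in (-1, 1), got {self.ar_coef}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def site_rng(master_seed: int, site_index: int) -> np.random.Generator:
    """Independent per-site random stream derived from a master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(site_index)]))


def _draw_covariate(rng: np.random.Generator, n: int, cfg: Mapping) -> np.ndarray:
    dist = cfg["dist"]
    if dist == "beta":
        return cfg.get("scale", 1.0) * rng.beta(cfg["a"], cfg["b"], size=n)
    if dist == "lognormal":
        x = rng.lognormal(cfg["mu"], cfg["sigma"], size=n)
        return np.clip(x, cfg.get("lo", 0.0), cfg.get("hi", np.inf))
    if dist == "uniform":
        return rng.uniform(cfg["lo"], cfg["hi"], size=n)
    if dist == "normal":
        return cfg.get("mean", 0.0) + cfg.get("sd", 1.0) * rng.standard_normal(n)
    raise ValueError(f"unknown covariate distribution {dist!r}")


def generate_sites(
    n_sites: int,
    n_catchments: int = 4,
    covariate_config: Mapping[str, Mapping] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the site covariate table.

    Parameters
    ----------
    n_sites, n_catchments
        Numbers of monitoring stations and catchments.  Catchment labels
        are assigned cyclically then shuffled, so every catchment is
        non-empty whenever ``n_sites >= n_catchments``.
    covariate_config
        Mapping covariate name -> distribution settings; defaults to
        :data:`DEFAULT_COVARIATE_CONFIG`.  Extra names are allowed and
        become extra site columns.
    seed
        Master seed; the table is bit-reproducible under a fixed seed.

    Returns
    -------
    DataFrame indexed by ``site_id`` with a ``catchment`` column plus one
    column per configured covariate.
    """
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    if n_catchments < 1:
        raise ValueError(f"n_catchments must be >= 1, got {n_catchments}")
    cfg = dict(covariate_config) if covariate_config is not None else dict(DEFAULT_COVARIATE_CONFIG)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))

    labels = list(CATCHMENT_NAMES[:n_catchments])
    labels += [f"C{i}" for i in range(len(labels) + 1, n_catchments + 1)]
    catchment = np.array(labels)[np.arange(n_sites) % n_catchments]
    catchment = rng.permutation(catchment)

    width = max(3, len(str(n_sites)))
    table = pd.DataFrame(
        {"catchment": catchment},
        index=pd.Index([f"S{i:0{width}d}" for i in range(1, n_sites + 1)], name="site_id"),
    )
    for name, c in cfg.items():
        table[name] = _draw_covariate(rng, n_sites, c)
    return table


def generate_air_series(
    site: Mapping,
    start,
    end,
    params: AirParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate an hourly air-temperature series for one site.

    ``start``/``end`` delimit a half-open interval of hourly instants.
    Returns a DataFrame with ``timestamp``, ``air`` and an empty ``water``
    column (filled later by :func:`generate_water_obs`), with the site id
    in ``DataFrame.attrs['site_id']``.
    """
    params = params or AirParams()
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if not start < end:
        raise ValueError(f"start must precede end, got {start} >= {end}")
    ts = pd.date_range(start, end, freq="h", inclusive="left")
    rng = np.random.default_rng(seed)

    doy = ts.dayofyear.to_numpy() + ts.hour.to_numpy() / 24.0
    hour = ts.hour.to_numpy().astype(float)
    mean = params.mean_level - params.lapse_rate * float(site.get("elevation", 0.0))
    air = (
        mean
        + params.annual_amplitude * np.cos(2 * np.pi * (doy - params.annual_peak_doy) / 365.25)
        + params.diel_amplitude * np.cos(2 * np.pi * (hour - params.diel_peak_hour) / 24.0)
    )
    if params.noise_sd > 0:
        z = rng.standard_normal(len(ts))
        inn = params.noise_sd * np.sqrt(1.0 - params.ar_coef**2) * z
        inn[0] = params.noise_sd * z[0]  # stationary start
        air = air + signal.lfilter([1.0], [1.0, -params.ar_coef], inn)

    out = pd.DataFrame({"timestamp": ts, "air": air, "water": np.nan})
    out.attrs["site_id"] = site.get("site_id", getattr(site, "name", None))
    return out


def _times_to_units(times, timescale: str) -> np.ndarray:
    """Coerce a time axis to float units of the CAR timescale."""
    arr = np.asarray(times)
    if np.issubdtype(arr.dtype, np.datetime64):
        days = (arr - arr[0]) / np.timedelta64(1, "s") / 86400.0
        return days if timescale == "day" else days / DAYS_PER_MONTH
    return arr.astype(float)


def _car1_residuals(t: np.ndarray, sigma: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Exact stationary CAR(1) residuals on an arbitrary (sorted) time grid."""
    n = len(t)
    z = rng.standard_normal(n)
    if sigma == 0 or n == 0:
        return np.zeros(n)
    if phi == 0:
        return sigma * z
    dt = np.diff(t)
    c = phi**dt
    s = sigma * np.sqrt(1.0 - c**2)
    e = np.empty(n)
    e[0] = sigma * z[0]
    if np.ptp(dt) < 1e-12:  # uniform spacing: one AR(1) filter pass
        inn = np.empty(n)
        inn[0] = e[0]
        inn[1:] = s * z[1:]
        return signal.lfilter([1.0], [1.0, -c[0]], inn)
    for k in range(1, n):
        e[k] = c[k - 1] * e[k - 1] + s[k - 1] * z[k]
    return e


def generate_water_obs(
    site: Mapping,
    times,
    ta,
    truth: TruthParams,
    seed: int = 0,
) -> np.ndarray:
    """Generate water temperatures from air temperatures at one site.

    ``times`` may be numeric (already in units of ``truth.timescale``) or
    datetime-like (converted to elapsed days, or mean-length months for the
    monthly scale); they must be strictly increasing.  The per-site random
    intercept/slope pair and the CAR(1) residual stream are drawn from
    ``seed``, so re-simulating a site with its own seed reproduces both.
    """
    t = _times_to_units(times, truth.timescale)
    ta = np.asarray(ta, dtype=float)
    if t.shape != ta.shape:
        raise ValueError("times and ta must have the same length")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")

    rng = np.random.default_rng(seed)
    cov = truth.random_effects_cov()
    w, q = np.linalg.eigh(cov)
    b0, b1 = q @ (np.sqrt(np.clip(w, 0.0, None)) * rng.standard_normal(2))
    e = _car1_residuals(t, truth.sigma, truth.phi, rng)

    try:
        env = sum(coef * float(site[name]) for name, coef in truth.beta_env.items())
    except KeyError as exc:
        raise ValueError(f"site record lacks covariate {exc} named in beta_env") from None
    offset = truth.catchment_offsets.get(site["catchment"], 0.0) if "catchment" in site else 0.0
    return truth.alpha + offset + env + b0 + (truth.beta_air + b1) * ta + e


def inject_missingness(
    series: pd.DataFrame,
    rate: float,
    mean_burst_hours: float = 12.0,
    seed: int = 0,
    columns: Sequence[str] = ("air", "water"),
) -> pd.DataFrame:
    """Blank out values in bursts, emulating logger failure episodes.

    Bursts have geometric lengths with the given mean; gaps between bursts
    are sized so the expected missing fraction equals ``rate``.  Channels
    fail independently.  Timestamps are never touched.
    """
    if not 0 <= rate <= 1:
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    out = series.copy()
    out.attrs = dict(series.attrs)
    if rate == 0:
        return out
    n = len(out)
    rng = np.random.default_rng(seed)
    for col in columns:
        if col not in out.columns:
            continue
        if rate == 1:
            out[col] = np.nan
            continue
        mask = np.zeros(n, dtype=bool)
        # Alternating renewal process: burst lengths 1+Geom (mean mb >= 1),
        # intact runs 0+Geom (mean mb*(1-rate)/rate, may be < 1).
        mb = max(mean_burst_hours, 1.0)
        p_burst = 1.0 / mb
        p_ok = 1.0 / (mb * (1.0 - rate) / rate + 1.0)
        pos = 0
        missing_first = rng.random() < rate
        if not missing_first:
            pos += rng.geometric(p_ok) - 1
        while pos < n:
            burst = rng.geometric(p_burst)
            mask[pos : pos + burst] = True
            pos += burst + rng.geometric(p_ok) - 1
        out.loc[mask, col] = np.nan
    return out


def thermal_smooth(values: np.ndarray, times_hours: np.ndarray, time_constant_hours: float) -> np.ndarray:
    """Gap-aware exponential moving average of an hourly driver series.

    Emulates the thermal inertia of a stream: water responds to a low-pass
    filtered version of air temperature with the given time constant.  A
    zero time constant returns the input unchanged.
    """
    if time_constant_hours <= 0:
        return np.asarray(values, dtype=float).copy()
    v = np.asarray(values, dtype=float)
    t = np.asarray(times_hours, dtype=float)
    out = np.empty_like(v)
    out[0] = v[0]
    w = np.exp(-np.diff(t) / time_constant_hours)
    for k in range(1, len(v)):
        out[k] = w[k - 1] * out[k - 1] + (1.0 - w[k - 1]) * v[k]
    return out


def simulate_paired_dataset(
    n_sites: int,
    n_periods: int,
    truth: TruthParams,
    seed: int = 0,
    n_catchments: int = 4,
    covariate_config: Mapping[str, Mapping] | None = None,
    air_amplitude: float = 6.0,
    air_ar: float = 0.5,
    air_sd: float = 2.0,
    air_site_sd: float = 1.0,
    extra_site_effects: Mapping[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a paired-observation dataset directly at the analysis scale.

    The workhorse for parameter-recovery studies: air temperature is drawn
    per site as a site mean plus a seasonal sinusoid plus AR(1) noise at
    the target timescale, and water follows ``truth``.  Returns
    ``(sites, paired)`` where ``paired`` has columns
    ``site_id, time, ta, tw`` sorted by site then time.

    ``extra_site_effects`` maps covariate names to per-observation weight
    arrays (length ``n_periods``, shared across sites) or to callables
    ``f(rng, n) -> array`` drawn independently per site; the covariate's
    value is multiplied by that weight at each time step, allowing effects
    that live only in the high-frequency part of the signal.
    """
    sites = generate_sites(n_sites, n_catchments, covariate_config, seed=seed)
    period = 365.25 if truth.timescale == "day" else 12.0
    t = np.arange(n_periods, dtype=float)
    season = air_amplitude * np.sin(2 * np.pi * t / period)

    frames = []
    for i, (site_id, site) in enumerate(sites.iterrows()):
        rng = site_rng(seed, i + 1)
        mean = 18.0 + air_site_sd * rng.standard_normal()
        ta = mean + season + _car1_residuals(t, air_sd, air_ar, rng)
        tw = generate_water_obs(
            {**site.to_dict(), "catchment": site["catchment"]},
            t,
            ta,
            truth,
            seed=np.random.SeedSequence([int(seed), i + 1, 7]),
        )
        if extra_site_effects:
            for name, weights in extra_site_effects.items():
                w = weights(rng, n_periods) if callable(weights) else np.asarray(weights, dtype=float)
                tw = tw + float(site[name]) * w
        frames.append(pd.DataFrame({"site_id": site_id, "time": t, "ta": ta, "tw": tw}))
    paired = pd.concat(frames, ignore_index=True)
    return sites, paired
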