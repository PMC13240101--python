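"""Seeded synthetic reservoir inputs for the squeeze pipeline.

The generator emulates a warm-monomictic, bowl-shaped reservoir: a smooth
basin from a deep centre to a flood-pool rim, water levels with a seasonal
sinusoid plus AR(1) persistence, vertical temperature/DO profiles that are
fully mixed in winter and stratify in summer (logistic thermocline and
oxycline with hypolimnetic oxygen depletion), and annual winter gillnet
survey metrics with a configurable — by default zero — linear dependence on
the previous summer's habitat indicators.

Defaults are tuned to a large south-central US reservoir: rim at the
195 m AMSL flood pool, mean level near 189 m, summer surface water around
30 degC, and a
thermocline centred just below the profiled 0-10 m window so the strictest
(25 degC) squeeze range closes almost completely in late summer while the
most permissive (30 degC) range retains most of the layer volume.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawn keys, so each generator draws an
independent, reproducible stream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, MissingInputError
from .hypsometry import BathymetryGrid

#: Survey descriptors: winter gillnet catch-per-net-night for the total
#: catch and three length classes, and relative weight for two classes.
DESCRIPTORS = ("cf_total", "cf_lt12", "cf_12_20", "cf_gt20", "wr_lt12", "wr_gt20")

_STREAM_BATHY, _STREAM_LEVELS, _STREAM_PROFILES = 0, 1, 2


@dataclass(frozen=True)
class LakeSimConfig:
    """Parameters of the synthetic lake.

    Geometry is a smooth elliptic bowl from ``basin_min_elev`` at the centre
    to ``basin_rim_elev`` at the edges, on a square-cell grid.  Water level
    follows ``mean_level + level_seasonal_amp * sin(2*pi*doy/365.25)`` plus
    an AR(1) residual.  Surface temperature is a seasonal sinusoid peaking
    in late July; between ``strat_onset_doy`` and ``strat_end_doy`` a
    stratification index s(t) in [0, 1] ramps up and back down, deepening a
    logistic thermocline (total top-to-bottom contrast ``strat_deltat_max``
    at peak) and depleting hypolimnetic oxygen towards
    ``hypolimnion_do_floor``.
    """

    grid_rows: int = 40
    grid_cols: int = 40
    cell_size: float = 486.06
    basin_min_elev: float = 178.0
    basin_rim_elev: float = 195.0
    bathy_noise_sd: float = 0.0

    mean_level: float = 189.0
    level_seasonal_amp: float = 2.0
    level_ar1_phi: float = 0.97
    level_noise_sd: float = 0.15

    surf_temp_mean: float = 18.0
    surf_temp_amp: float = 11.0
    surf_temp_peak_doy: int = 202
    strat_deltat_max: float = 12.0
    strat_depth_mid: float = 11.0
    strat_width: float = 2.0
    hypolimnion_do_floor: float = 1.0
    epilimnion_do: float = 8.0
    strat_onset_doy: int = 150
    strat_end_doy: int = 290
    temp_anom_phi: float = 0.98
    temp_anom_sd: float = 0.15
    profile_noise_sd: float = 0.1

    years: Sequence[int] = tuple(range(1995, 2021))
    gap_dates: Sequence[tuple[str, str]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 3 or self.grid_cols < 3:
            raise InvalidConfigError("grid must be at least 3x3")
        if self.cell_size <= 0:
            raise InvalidConfigError("cell_size must be positive")
        if not self.basin_min_elev < self.basin_rim_elev:
            raise InvalidConfigError("basin_min_elev must be below basin_rim_elev")
        if not 0 <= self.level_ar1_phi < 1:
            raise InvalidConfigError("level_ar1_phi must lie in [0, 1)")
        if not 0 <= self.temp_anom_phi < 1:
            raise InvalidConfigError("temp_anom_phi must lie in [0, 1)")
        if self.hypolimnion_do_floor < 0:
            raise InvalidConfigError("hypolimnion_do_floor must be non-negative")
        if self.epilimnion_do < self.hypolimnion_do_floor:
            raise InvalidConfigError("epilimnion_do must be >= hypolimnion_do_floor")
        if not 0 < self.strat_onset_doy < self.strat_end_doy <= 366:
            raise InvalidConfigError("need 0 < strat_onset_doy < strat_end_doy <= 366")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream,))
        )


@dataclass(frozen=True)
class SurveyEffectSpec:
    """Generative law for one survey descriptor.

    value(year) = baseline + slope_per_m3 * indicator(year - 1) + N(0, noise_sd),
    where the indicator is drawn from the annual-indicator table by squeeze
    range and column name.
    """

    descriptor: str
    baseline: float
    slope_per_m3: float = 0.0
    indicator_range: str = "preference_25"
    indicator_col: str = "min_daily_m3"
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.descriptor not in DESCRIPTORS:
            raise InvalidConfigError(
                f"unknown descriptor {self.descriptor!r}; expected one of {DESCRIPTORS}"
            )
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")


def default_effect_specs(
    slope_per_m3: float = 0.0,
    indicator_range: str = "preference_25",
    indicator_col: str = "min_daily_m3",
) -> list[SurveyEffectSpec]:
    """Null survey model: realistic baselines/noise, configurable slope."""
    baselines = {
        "cf_total": 10.0,
        "cf_lt12": 4.5,
        "cf_12_20": 3.5,
        "cf_gt20": 2.0,
        "wr_lt12": 85.0,
        "wr_gt20": 92.0,
    }
    noise = {
        "cf_total": 2.0,
        "cf_lt12": 1.2,
        "cf_12_20": 1.0,
        "cf_gt20": 0.6,
        "wr_lt12": 4.0,
        "wr_gt20": 5.0,
    }
    return [
        SurveyEffectSpec(
            d,
            baselines[d],
            slope_per_m3=slope_per_m3,
            indicator_range=indicator_range,
            indicator_col=indicator_col,
            noise_sd=noise[d],
        )
        for d in DESCRIPTORS
    ]


def simulation_dates(config: LakeSimConfig) -> pd.DatetimeIndex:
    """All calendar days of the configured years, minus gap windows."""
    if len(config.years) == 0:
        raise InvalidConfigError("years must be non-empty")
    parts = [
        pd.date_range(f"{y}-01-01", f"{y}-12-31", freq="D") for y in sorted(config.years)
    ]
    dates = parts[0].append(parts[1:]) if len(parts) > 1 else parts[0]
    keep = np.ones(len(dates), dtype=bool)
    for start, end in config.gap_dates:
        keep &= ~((dates >= pd.Timestamp(start)) & (dates <= pd.Timestamp(end)))
    return dates[keep]


def generate_bathymetry(config: LakeSimConfig) -> BathymetryGrid:
    """Smooth elliptic-paraboloid bowl, optionally with seeded roughness.

    The normalised squared radius is rescaled so the raster minimum equals
    ``basin_min_elev`` and the maximum equals ``basin_rim_elev`` exactly
    (noise, when enabled, is clipped back into that band).  Elevation is
    monotone non-decreasing along rays from the centre.
    """
    rows, cols = config.grid_rows, config.grid_cols
    i = np.arange(rows)[:, None]
    j = np.arange(cols)[None, :]
    u = (i - (rows - 1) / 2) / ((rows - 1) / 2)
    v = (j - (cols - 1) / 2) / ((cols - 1) / 2)
    r2 = u * u + v * v
    r2 = (r2 - r2.min()) / (r2.max() - r2.min())
    elev = config.basin_min_elev + (config.basin_rim_elev - config.basin_min_elev) * r2
    if config.bathy_noise_sd > 0:
        noise = config.rng(_STREAM_BATHY).normal(0.0, config.bathy_noise_sd, elev.shape)
        elev = np.clip(elev + noise, config.basin_min_elev, config.basin_rim_elev)
    return BathymetryGrid(elevations=elev, cell_size=config.cell_size)


def _day_fraction(dates: pd.DatetimeIndex) -> np.ndarray:
    return dates.dayofyear.to_numpy(dtype=float)


def generate_water_levels(config: LakeSimConfig) -> pd.DataFrame:
    """Daily water-surface elevations (m AMSL) with seasonality and AR(1).

    The AR(1) residual is simulated over the continuous day count (so its
    persistence is unbroken across gap windows) and gap dates are dropped
    from the output afterwards — gaps are absent rows, not sentinels.
    """
    if len(config.years) == 0:
        raise InvalidConfigError("years must be non-empty")
    years = sorted(config.years)
    all_days = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    all_days = all_days[np.isin(all_days.year, years)]

    phi, sd = config.level_ar1_phi, config.level_noise_sd
    rng = config.rng(_STREAM_LEVELS)
    resid = np.zeros(len(all_days))
    if sd > 0:
        innov = rng.normal(0.0, sd, len(all_days))
        resid[0] = innov[0] / np.sqrt(1.0 - phi * phi)  # stationary start
        for t in range(1, len(all_days)):
            resid[t] = phi * resid[t - 1] + innov[t]
    seasonal = config.level_seasonal_amp * np.sin(
        2.0 * np.pi * _day_fraction(all_days) / 365.25
    )
    level = config.mean_level + seasonal + resid
    out = pd.DataFrame({"date": all_days, "level_m": level})
    keep_dates = simulation_dates(config)
    return out[out["date"].isin(keep_dates)].reset_index(drop=True)


def stratification_index(doy: np.ndarray, config: LakeSimConfig) -> np.ndarray:
    """Seasonal stratification strength s(t) in [0, 1].

    Zero outside [strat_onset_doy, strat_end_doy]; inside, a smooth
    sin^2 ramp peaking mid-interval (full stratification)."""
    doy = np.asarray(doy, dtype=float)
    span = config.strat_end_doy - config.strat_onset_doy
    s = np.sin(np.pi * (doy - config.strat_onset_doy) / span) ** 2
    inside = (doy >= config.strat_onset_doy) & (doy <= config.strat_end_doy)
    return np.where(inside, s, 0.0)


def surface_temperature(doy: np.ndarray, config: LakeSimConfig) -> np.ndarray:
    """Seasonal surface-water temperature sinusoid (degC)."""
    doy = np.asarray(doy, dtype=float)
    return config.surf_temp_mean + config.surf_temp_amp * np.cos(
        2.0 * np.pi * (doy - config.surf_temp_peak_doy) / 365.25
    )


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_profiles(
    dates: pd.DatetimeIndex | Sequence,
    levels: pd.DataFrame,
    config: LakeSimConfig,
) -> pd.DataFrame:
    """Daily temperature/DO profiles at integer depths 0-10 m.

    temp(d, t) = surf(t) + anom(t) - strat_deltat_max * s(t) * logistic((d - mid)/width)
    do(d, t)   = epi_do - (epi_do - floor) * s(t) * logistic((d - mid)/width)

    ``anom(t)`` is a persistent AR(1) water-temperature anomaly (coefficient
    ``temp_anom_phi``, innovation sd ``temp_anom_sd``) shifting the whole
    column, so summers differ from year to year in how hard the thermal
    limits bind.  Both profiles are non-increasing in depth and collapse to
    mixed (depth-constant) columns when s(t) = 0.  Optional iid Gaussian
    noise (``profile_noise_sd``) is added to both variables; DO is clipped
    at zero.  Anomaly and noise draw from the same seeded stream, so the
    series is reproducible for a fixed config.
    """
    dates = pd.DatetimeIndex(dates)
    have = set(pd.DatetimeIndex(levels["date"]))
    missing = [d for d in dates if d not in have]
    if missing:
        raise MissingInputError(
            f"no water level for {len(missing)} requested dates, e.g. {missing[0].date()}"
        )
    rng = config.rng(_STREAM_PROFILES)
    doy = _day_fraction(dates)
    s = stratification_index(doy, config)
    surf = surface_temperature(doy, config)
    if config.temp_anom_sd > 0:
        # simulate over the continuous span so gaps do not reset the anomaly
        span = pd.date_range(dates.min(), dates.max(), freq="D")
        phi, sd = config.temp_anom_phi, config.temp_anom_sd
        innov = rng.normal(0.0, sd, len(span))
        anom = np.zeros(len(span))
        anom[0] = innov[0] / np.sqrt(1.0 - phi * phi)
        for t in range(1, len(span)):
            anom[t] = phi * anom[t - 1] + innov[t]
        surf = surf + pd.Series(anom, index=span).loc[dates].to_numpy()
    depths = np.arange(11)
    grad = _logistic((depths - config.strat_depth_mid) / config.strat_width)

    temp = surf[:, None] - config.strat_deltat_max * s[:, None] * grad[None, :]
    do = config.epilimnion_do - (
        config.epilimnion_do - config.hypolimnion_do_floor
    ) * s[:, None] * grad[None, :]
    if config.profile_noise_sd > 0:
        temp = temp + rng.normal(0.0, config.profile_noise_sd, temp.shape)
        do = np.clip(do + rng.normal(0.0, config.profile_noise_sd, do.shape), 0.0, None)

    return pd.DataFrame(
        {
            "date": np.repeat(np.asarray(dates), len(depths)),
            "depth_m": np.tile(depths, len(dates)),
            "temp_c": temp.ravel(),
            "do_mgl": do.ravel(),
        }
    )


def generate_survey(
    years: Sequence[int],
    indicators: pd.DataFrame,
    specs: Sequence[SurveyEffectSpec],
    seed: int,
) -> pd.DataFrame:
    """Annual survey metrics, optionally driven by lagged habitat indicators.

    ``indicators`` is the annual-indicator table (columns ``year``,
    ``range_name`` and indicator columns); a survey value for year Y uses
    the indicator of year Y-1.  Years whose lagged indicator is missing
    still emit baseline + noise (the effect term is skipped).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    rows = []
    for spec in specs:
        ind = indicators[indicators["range_name"] == spec.indicator_range]
        lookup = ind.set_index("year")[spec.indicator_col]
        for y in sorted(years):
            value = spec.baseline + rng.normal(0.0, spec.noise_sd)
            prev = lookup.get(y - 1)
            if spec.slope_per_m3 != 0.0 and prev is not None and np.isfinite(prev):
                value += spec.slope_per_m3 * float(prev)
            rows.append({"year": y, "descriptor": spec.descriptor, "value": value})
    return pd.DataFrame(rows)


def with_seed(config: LakeSimConfig, seed: int) -> LakeSimConfig:
    """Copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
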