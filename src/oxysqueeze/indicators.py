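"""Seasonal climatology and annual disturbance indicators.

The daily habitat-volume series is reduced in two ways:

* a day-of-year climatology (mean and SD across years) describing the
  seasonal squeeze cycle, and
* three annual indicators per squeeze range — the yearly minimum daily
  volume (a "pulse" disturbance: the single worst day) and the minimum
  14-day and 30-day forward rolling-window averages (press disturbances:
  the worst sustained fortnight/month).

Day-of-year uses a leap-calendar index so the same calendar date always
maps to the same day number (Feb 29 = 60, Mar 1 = 61 in every year).
Rolling windows start on each day of the calendar year, stay wholly within
it, and are only used when every day in the window is observed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .habitat import Scenario

logger = logging.getLogger(__name__)

#: Leap-calendar day numbers spanning the squeeze season (June 1 - Oct 31);
#: years observing fewer than half of these days are flagged invalid.
SEASON_DOY = (153, 305)
MIN_SEASON_COVERAGE = 0.5


def day_of_year(dates) -> np.ndarray:
    """Leap-calendar day-of-year: Feb 29 is day 60, Mar 1 is 61 always."""
    dates = pd.DatetimeIndex(dates)
    doy = dates.dayofyear.to_numpy()
    shift = (~dates.is_leap_year) & (dates.month >= 3)
    return doy + shift.astype(int)


def _select(volumes: pd.DataFrame, range_name: str | None, scenario) -> pd.DataFrame:
    out = volumes
    if range_name is not None:
        out = out[out["range_name"] == range_name]
    if scenario is not None:
        out = out[out["scenario"] == Scenario(scenario).value]
    return out


def seasonal_climatology(volumes: pd.DataFrame) -> pd.DataFrame:
    """Across-year mean/SD of daily volume per (day-of-year, range, scenario).

    SD is the sample standard deviation, reported as 0 when only one year
    contributes.  An empty input yields an empty output (logged).
    """
    if len(volumes) == 0:
        logger.warning("seasonal_climatology: empty volume table")
        return pd.DataFrame(
            columns=["doy", "range_name", "scenario", "mean_m3", "sd_m3", "n"]
        )
    df = volumes.copy()
    df["doy"] = day_of_year(df["date"])
    g = df.groupby(["doy", "range_name", "scenario"])["volume_m3"]
    out = g.agg(mean_m3="mean", sd_m3=lambda v: v.std(ddof=1), n="count").reset_index()
    out.loc[out["n"] == 1, "sd_m3"] = 0.0
    return out


def annual_min(
    volumes: pd.DataFrame,
    year: int,
    range_name: str,
    scenario: Scenario | str = Scenario.BOTH,
) -> float:
    """Yearly minimum daily volume (pulse indicator); NaN if unobserved."""
    df = _select(volumes, range_name, scenario)
    vals = df.loc[pd.DatetimeIndex(df["date"]).year == year, "volume_m3"]
    if len(vals) == 0:
        return float("nan")
    return float(vals.min())


def rolling_min_average(
    volumes: pd.DataFrame,
    year: int,
    range_name: str,
    window: int,
    scenario: Scenario | str = Scenario.BOTH,
) -> float:
    """Minimum forward ``window``-day average volume within a calendar year.

    Windows start on every day of the year, must lie wholly within the
    year, and are skipped when any member day is unobserved; NaN when no
    complete window exists (press indicator).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    df = _select(volumes, range_name, scenario)
    df = df[pd.DatetimeIndex(df["date"]).year == year]
    cal = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    series = df.set_index("date")["volume_m3"].reindex(cal)
    # trailing mean at window end == forward mean labelled at window start
    means = series.rolling(window, min_periods=window).mean().shift(-(window - 1))
    if means.notna().sum() == 0:
        return float("nan")
    return float(means.min())


def annual_indicators(
    volumes: pd.DataFrame,
    windows: tuple[int, int] = (14, 30),
    scenario: Scenario | str = Scenario.BOTH,
) -> pd.DataFrame:
    """Annual pulse/press indicator table per (year, squeeze range).

    Columns: ``year, range_name, min_daily_m3, min_avg_{w}d_m3`` for each
    window, plus ``coverage`` (fraction of calendar days observed),
    ``season_coverage`` (fraction of June-October days observed) and
    ``valid`` (season coverage at least 50%, and all indicators defined).
    Indicators are computed under the combined-stressor scenario by
    default, the squeeze the press/pulse framing refers to.
    """
    df = _select(volumes, None, scenario)
    rows = []
    years = sorted(pd.DatetimeIndex(df["date"]).year.unique())
    doys = day_of_year(df["date"])
    df = df.assign(_year=pd.DatetimeIndex(df["date"]).year, _doy=doys)
    season_lo, season_hi = SEASON_DOY
    for rng_name in sorted(df["range_name"].unique()):
        sub_r = df[df["range_name"] == rng_name]
        for year in years:
            sub = sub_r[sub_r["_year"] == year]
            n_days = 366 if pd.Timestamp(f"{year}-12-31").is_leap_year else 365
            coverage = len(sub) / n_days
            season_days = sub["_doy"].between(season_lo, season_hi).sum()
            season_total = season_hi - season_lo + 1
            season_cov = season_days / season_total
            rec = {
                "year": year,
                "range_name": rng_name,
                "min_daily_m3": annual_min(volumes, year, rng_name, scenario),
                "coverage": coverage,
                "season_coverage": season_cov,
            }
            for w in windows:
                rec[f"min_avg_{w}d_m3"] = rolling_min_average(
                    volumes, year, rng_name, w, scenario
                )
            rec["valid"] = bool(
                season_cov >= MIN_SEASON_COVERAGE
                and np.isfinite(list(rec[f"min_avg_{w}d_m3"] for w in windows)).all()
                and np.isfinite(rec["min_daily_m3"])
            )
            rows.append(rec)
    return pd.DataFrame(rows)


def lag1_autocorrelation(
    volumes: pd.DataFrame,
    range_name: str,
    scenario: Scenario | str = Scenario.BOTH,
) -> float:
    """Lag-1 Pearson autocorrelation over consecutive-day pairs.

    Only pairs of dates exactly one day apart enter, so data gaps cannot
    create spurious lags.  Returns NaN for a zero-variance series.
    """
    df = _select(volumes, range_name, scenario).sort_values("date")
    dates = pd.DatetimeIndex(df["date"])
    vals = df["volume_m3"].to_numpy(dtype=float)
    consec = np.diff(dates.values).astype("timedelta64[D]") == np.timedelta64(1, "D")
    x, y = vals[:-1][consec], vals[1:][consec]
    if len(x) < 3:
        raise InsufficientDataError(
            f"need >= 3 consecutive-day pairs, found {len(x)}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:  # exact zero-variance check
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
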