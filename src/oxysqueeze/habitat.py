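"""Daily suitable-habitat volume under an oxythermal squeeze.

A squeeze range pairs an upper thermal limit with a dissolved-oxygen floor.
For each date, each one-metre depth plane in the top of the water column is
either fully suitable (the plane's temperature and DO pass the thresholds)
or contributes nothing; a suitable plane contributes its full plan area
times 1 m of thickness.  Summing planes gives the daily habitat volume.

Four stressor scenarios decompose the drivers: ``both`` applies both
thresholds, ``temp_only`` and ``do_only`` apply one each, and ``none`` is
the control (total water volume of the profiled layer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import IncompleteProfileError, NoOverlapError
from .hypsometry import HypsometricCurve, area_at_elevation

logger = logging.getLogger(__name__)

#: Number of one-metre depth planes profiled by default: depths 0..10 m
#: inclusive (a literal reading of "repeated at 1 m intervals" over the
#: 0-10 m profile grid yields 11 planes; set 10 to drop the deepest one).
DEFAULT_DEPTH_PLANES = 11


class Scenario(str, Enum):
    """Which stressors constrain suitability."""

    NONE = "none"
    DO_ONLY = "do_only"
    TEMP_ONLY = "temp_only"
    BOTH = "both"


@dataclass(frozen=True)
class SqueezeRange:
    """Trait thresholds defining one squeeze range.

    ``t_max`` is the upper thermal limit in degC and ``do_min`` the
    dissolved-oxygen floor in mg/L; both comparisons are inclusive.
    """

    name: str
    t_max: float
    do_min: float

    def __post_init__(self) -> None:
        if self.do_min < 0:
            raise ValueError("do_min must be non-negative")


#: The three striped-bass squeeze ranges: upper thermal preference,
#: upper thermal tolerance, and acute upper thermal tolerance, all with a
#: 3 mg/L dissolved-oxygen floor.
PRESET_RANGES: tuple[SqueezeRange, ...] = (
    SqueezeRange("preference_25", 25.0, 3.0),
    SqueezeRange("tolerance_28", 28.0, 3.0),
    SqueezeRange("acute_30", 30.0, 3.0),
)

ALL_SCENARIOS: tuple[Scenario, ...] = (
    Scenario.NONE,
    Scenario.DO_ONLY,
    Scenario.TEMP_ONLY,
    Scenario.BOTH,
)


def is_suitable(temp, do, range_: SqueezeRange, scenario: Scenario | str):
    """Element-wise suitability of (temp degC, DO mg/L) pairs.

    NaN temperature or DO makes a plane unsuitable under any scenario that
    consults the missing variable; the control scenario ``none`` is always
    suitable.  Vectorised; returns a bool (array).
    """
    scenario = Scenario(scenario)
    temp = np.asarray(temp, dtype=float)
    do = np.asarray(do, dtype=float)
    with np.errstate(invalid="ignore"):
        temp_ok = temp <= range_.t_max  # NaN compares False
        do_ok = do >= range_.do_min
    if scenario is Scenario.NONE:
        out = np.ones(np.broadcast(temp, do).shape, dtype=bool)
    elif scenario is Scenario.TEMP_ONLY:
        out = temp_ok
    elif scenario is Scenario.DO_ONLY:
        out = do_ok
    else:
        out = temp_ok & do_ok
    if out.ndim == 0:
        return bool(out)
    return out


def _profile_arrays(profile: pd.DataFrame, n_planes: int) -> tuple[np.ndarray, np.ndarray]:
    """Extract (temp, do) arrays indexed by integer depth 0..n_planes-1."""
    prof = profile.set_index("depth_m")
    depths = np.arange(n_planes)
    missing = [d for d in depths if d not in prof.index]
    if missing:
        raise IncompleteProfileError(f"profile missing depth rows {missing}")
    temp = prof.loc[depths, "temp_c"].to_numpy(dtype=float)
    do = prof.loc[depths, "do_mgl"].to_numpy(dtype=float)
    return temp, do


def daily_volume(
    curve: HypsometricCurve,
    level: float,
    profile: pd.DataFrame,
    range_: SqueezeRange,
    scenario: Scenario | str = Scenario.BOTH,
    n_planes: int = DEFAULT_DEPTH_PLANES,
) -> float:
    """Suitable habitat volume (m^3) for a single date.

    ``profile`` is a single-date frame with columns depth_m, temp_c, do_mgl
    covering integer depths ``0..n_planes-1``.  Each suitable plane at depth
    d contributes ``area(level - d) * 1 m``; planes below the basin floor
    have zero area and contribute nothing.
    """
    temp, do = _profile_arrays(profile, n_planes)
    depths = np.arange(n_planes)
    areas = area_at_elevation(curve, level - depths)
    suit = is_suitable(temp, do, range_, scenario)
    return float(np.sum(areas * suit))


def volume_series(
    curve: HypsometricCurve,
    levels: pd.DataFrame,
    profiles: pd.DataFrame,
    ranges: Sequence[SqueezeRange] = PRESET_RANGES,
    scenarios: Iterable[Scenario | str] = ALL_SCENARIOS,
    n_planes: int = DEFAULT_DEPTH_PLANES,
    diagnostics: bool = False,
) -> pd.DataFrame:
    """Daily suitable-habitat volume for every (date, range, scenario).

    Parameters
    ----------
    levels
        Frame with columns ``date`` and ``level_m`` (m AMSL), unique dates.
    profiles
        Long frame with columns ``date``, ``depth_m``, ``temp_c``,
        ``do_mgl``; every present date must cover integer depths
        ``0..n_planes-1``.
    diagnostics
        When True, also return the per-depth plane table (date, depth,
        plane elevation, area, temp, DO and per-range suitability flags).

    Returns
    -------
    DataFrame with columns ``date, range_name, scenario, volume_m3`` (and,
    if requested, a second diagnostics frame).  Dates present in only one
    input are skipped and logged, as are NaN profile planes.
    """
    scenarios = [Scenario(s) for s in scenarios]
    lev = levels.drop_duplicates("date").set_index("date")["level_m"]
    prof_dates = pd.Index(profiles["date"].unique())
    dates = prof_dates.intersection(lev.index).sort_values()
    if len(dates) == 0:
        raise NoOverlapError("water levels and profiles share no dates")
    skipped = len(prof_dates.symmetric_difference(lev.index))
    if skipped:
        logger.info("volume_series: %d dates present in only one input, skipped", skipped)

    wide_t = profiles.pivot_table(index="date", columns="depth_m", values="temp_c")
    wide_o = profiles.pivot_table(index="date", columns="depth_m", values="do_mgl")
    depths = np.arange(n_planes)
    missing_cols = [d for d in depths if d not in wide_t.columns]
    if missing_cols:
        raise IncompleteProfileError(f"profiles missing depth columns {missing_cols}")
    temp = wide_t.loc[dates, depths].to_numpy(dtype=float)  # (n_dates, n_planes)
    do = wide_o.loc[dates, depths].to_numpy(dtype=float)
    n_nan = int(np.isnan(temp).sum() + np.isnan(do).sum())
    if n_nan:
        logger.info("volume_series: %d NaN profile planes treated as unsuitable", n_nan)

    level_arr = lev.loc[dates].to_numpy(dtype=float)
    plane_elev = level_arr[:, None] - depths[None, :]
    areas = np.asarray(
        area_at_elevation(curve, plane_elev.ravel())
    ).reshape(plane_elev.shape)

    records = []
    for rng in ranges:
        for scen in scenarios:
            suit = is_suitable(temp, do, rng, scen)
            vol = (areas * suit).sum(axis=1)
            records.append(
                pd.DataFrame(
                    {
                        "date": dates,
                        "range_name": rng.name,
                        "scenario": scen.value,
                        "volume_m3": vol,
                    }
                )
            )
    out = pd.concat(records, ignore_index=True)

    if diagnostics:
        diag = pd.DataFrame(
            {
                "date": np.repeat(np.asarray(dates), n_planes),
                "depth_m": np.tile(depths, len(dates)),
                "plane_elev_m": plane_elev.ravel(),
                "area_m2": areas.ravel(),
                "temp_c": temp.ravel(),
                "do_mgl": do.ravel(),
            }
        )
        for rng in ranges:
            diag[f"suitable_{rng.name}"] = is_suitable(
                temp, do, rng, Scenario.BOTH
            ).ravel()
        return out, diag
    return out
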