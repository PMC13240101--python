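"""End-to-end run orchestration: simulate -> hypsometry -> volumes ->
indicators -> GAM -> regression screen, with every stage product written to
CSV and a machine-readable manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gam, indicators as ind_mod, screen as screen_mod, synthetic
from .errors import InvalidConfigError
from .habitat import ALL_SCENARIOS, DEFAULT_DEPTH_PLANES, PRESET_RANGES, SqueezeRange, volume_series
from .hypsometry import (
    build_hypsometric_curve,
    export_curve_csv,
    read_elevation_raster,
    write_elevation_raster,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    In simulation mode (default) all inputs come from the synthetic lake;
    otherwise ``raster_path``, ``levels_path``, ``profiles_path`` and
    ``survey_path`` name pre-existing files in the formats this package
    writes (GeoTIFF and CSV).
    """

    simulate: bool = True
    sim: synthetic.LakeSimConfig = field(default_factory=synthetic.LakeSimConfig)
    survey_specs: list[synthetic.SurveyEffectSpec] = field(
        default_factory=synthetic.default_effect_specs
    )
    raster_path: str | None = None
    levels_path: str | None = None
    profiles_path: str | None = None
    survey_path: str | None = None

    ranges: tuple[SqueezeRange, ...] = PRESET_RANGES
    scenarios: tuple = ALL_SCENARIOS
    windows: tuple[int, int] = (14, 30)
    n_planes: int = DEFAULT_DEPTH_PLANES
    k_lag: int = 10
    k_doy: int = 20
    k_date: int = 10
    k_level: int = 10
    alpha: float = 0.05
    survey_lag_years: int = 1
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        if len(self.ranges) == 0:
            raise InvalidConfigError("at least one squeeze range is required")
        if not self.simulate:
            for name in ("raster_path", "levels_path", "profiles_path", "survey_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise InvalidConfigError(f"{name} must exist in non-simulation mode")

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (tuple, set)):
                return list(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_survey(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full analysis; returns the run manifest (also written
    to ``outdir/manifest.json``).  Deterministic for a fixed config+seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        grid = synthetic.generate_bathymetry(sim)
        write_elevation_raster(grid, outdir / "bathymetry.tif")
        grid = read_elevation_raster(outdir / "bathymetry.tif")
        levels = synthetic.generate_water_levels(sim)
        profiles = synthetic.generate_profiles(
            pd.DatetimeIndex(levels["date"]), levels, sim
        )
        levels.assign(date=levels["date"].dt.date).to_csv(
            outdir / "water_levels.csv", index=False
        )
        profiles.assign(date=pd.DatetimeIndex(profiles["date"]).date).to_csv(
            outdir / "profiles.csv", index=False
        )
    else:
        grid = read_elevation_raster(config.raster_path)
        levels = pd.read_csv(config.levels_path, parse_dates=["date"])
        profiles = pd.read_csv(config.profiles_path, parse_dates=["date"])
    manifest["stages"]["inputs"] = {
        "n_levels": int(len(levels)),
        "n_profile_rows": int(len(profiles)),
        "grid_shape": list(grid.elevations.shape),
        "valid_cells": grid.n_valid,
    }

    # --- hypsometry -------------------------------------------------------
    curve = build_hypsometric_curve(grid)
    export_curve_csv(curve, outdir / "hypsometric_curve.csv")
    manifest["stages"]["hypsometry"] = {"n_steps": int(len(curve.elevations))}

    # --- daily habitat volumes -------------------------------------------
    volumes = volume_series(
        curve,
        levels,
        profiles,
        ranges=config.ranges,
        scenarios=config.scenarios,
        n_planes=config.n_planes,
    )
    vol_out = volumes.assign(date=pd.DatetimeIndex(volumes["date"]).date)
    vol_out.to_csv(outdir / "daily_volumes.csv", index=False)
    manifest["stages"]["volumes"] = {
        "n_rows": int(len(volumes)),
        "n_tables": len(config.ranges) * len(config.scenarios),
    }

    # --- climatology + indicators ----------------------------------------
    clim = ind_mod.seasonal_climatology(volumes)
    clim.to_csv(outdir / "climatology.csv", index=False)
    indicators = ind_mod.annual_indicators(volumes, windows=config.windows)
    indicators.to_csv(outdir / "annual_indicators.csv", index=False)
    rho1 = {
        r.name: ind_mod.lag1_autocorrelation(volumes, r.name) for r in config.ranges
    }
    manifest["stages"]["indicators"] = {
        "n_years": int(indicators["year"].nunique()),
        "n_valid": int(indicators["valid"].sum()),
        "lag1_autocorrelation": rho1,
    }

    # --- GAM per range ----------------------------------------------------
    gam_fits = {}
    gam_summaries = []
    partials = []
    for r in config.ranges:
        table = gam.prepare_gam_table(volumes, levels, r.name)
        fit = gam.fit_squeeze_gam(
            table,
            k_lag=config.k_lag,
            k_doy=config.k_doy,
            k_date=config.k_date,
            k_level=config.k_level,
        )
        gam_fits[r.name] = fit
        sf = fit.summary_frame().assign(range_name=r.name, r2_adj=fit.r_squared_adj)
        gam_summaries.append(sf)
        partials.append(fit.partial_effects.assign(range_name=r.name))
        trend = gam.long_term_trend_test(fit)
        manifest["stages"].setdefault("gam", {})[r.name] = {
            "n": fit.n,
            "r2": fit.r_squared,
            "r2_adj": fit.r_squared_adj,
            "trend": {k: (v if not isinstance(v, float) else float(v)) for k, v in trend.items()},
        }
    pd.concat(gam_summaries, ignore_index=True).to_csv(
        outdir / "gam_summary.csv", index=False
    )
    pd.concat(partials, ignore_index=True).to_csv(
        outdir / "gam_partial_effects.csv", index=False
    )

    # --- survey + regression screen --------------------------------------
    if config.simulate:
        years = sorted(set(pd.DatetimeIndex(levels["date"]).year))
        survey_years = [y + config.survey_lag_years for y in years]
        survey = synthetic.generate_survey(
            survey_years, indicators, config.survey_specs, seed=config.seed
        )
        survey.to_csv(outdir / "survey.csv", index=False)
    else:
        survey = _load_survey(config.survey_path)
    paired = screen_mod.align_survey_to_indicators(
        survey, indicators, lag_years=config.survey_lag_years
    )
    results = screen_mod.run_screen(
        paired,
        ranges=[r.name for r in config.ranges],
        alpha=config.alpha,
    )
    results.to_csv(outdir / "screen_results.csv", index=False)
    (outdir / "screen_report.txt").write_text(screen_mod.screen_report(results))
    manifest["stages"]["screen"] = screen_mod.screen_summary(results)

    if config.make_plots:
        _make_plots(outdir, clim, config, partials, paired, results)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=float))
    return manifest


def _make_plots(outdir, clim, config, partials, paired, results) -> None:
    """Figures mirroring the seasonal-climatology, stressor-decomposition,
    GAM partial-effect and screen-scatter panels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    range_names = [r.name for r in config.ranges]

    fig, axes = plt.subplots(1, len(range_names), figsize=(4 * len(range_names), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, rn in zip(axes, range_names):
        sub = clim[(clim["range_name"] == rn) & (clim["scenario"] == "both")]
        ax.plot(sub["doy"], sub["mean_m3"], color="k", lw=1)
        ax.fill_between(
            sub["doy"],
            sub["mean_m3"] - sub["sd_m3"],
            sub["mean_m3"] + sub["sd_m3"],
            alpha=0.3,
            color="grey",
        )
        ax.set_title(rn)
        ax.set_xlabel("day of year")
    axes[0].set_ylabel("suitable volume (m$^3$)")
    fig.tight_layout()
    fig.savefig(outdir / "fig_climatology.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, len(range_names), figsize=(4 * len(range_names), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, rn in zip(axes, range_names):
        for scen, color in [("none", "g"), ("do_only", "orange"), ("temp_only", "b"), ("both", "purple")]:
            sub = clim[(clim["range_name"] == rn) & (clim["scenario"] == scen)]
            if len(sub):
                ax.plot(sub["doy"], sub["mean_m3"], label=scen, color=color, lw=1)
        ax.set_title(rn)
        ax.set_xlabel("day of year")
    axes[0].set_ylabel("mean volume (m$^3$)")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "fig_stressor_scenarios.png", dpi=120)
    plt.close(fig)

    pe = pd.concat(partials, ignore_index=True)
    terms = pe["term"].unique()
    fig, axes = plt.subplots(
        len(terms), len(range_names), figsize=(4 * len(range_names), 2.4 * len(terms)), squeeze=False
    )
    for i, term in enumerate(terms):
        for j, rn in enumerate(range_names):
            sub = pe[(pe["term"] == term) & (pe["range_name"] == rn)]
            ax = axes[i][j]
            ax.plot(sub["grid_value"], sub["effect"], "k", lw=1)
            ax.fill_between(
                sub["grid_value"],
                sub["effect"] - 1.96 * sub["se"],
                sub["effect"] + 1.96 * sub["se"],
                color="grey",
                alpha=0.4,
            )
            if i == 0:
                ax.set_title(rn, fontsize=8)
            if j == 0:
                ax.set_ylabel(term, fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "fig_gam_partials.png", dpi=120)
    plt.close(fig)

    ex = results.nsmallest(3, "p") if len(results) else results
    fig, axes = plt.subplots(1, max(len(ex), 1), figsize=(4 * max(len(ex), 1), 3.2))
    axes = np.atleast_1d(axes)
    for ax, (_, row) in zip(axes, ex.iterrows()):
        sub = paired[
            (paired["range_name"] == row["range_name"])
            & (paired["descriptor"] == row["descriptor"])
        ]
        ax.scatter(sub[row["indicator"]], sub["value"], s=12)
        xg = np.linspace(sub[row["indicator"]].min(), sub[row["indicator"]].max(), 10)
        ax.plot(xg, row["intercept"] + row["slope"] * xg, "k--", lw=1)
        ax.set_xlabel(f"{row['range_name']} {row['indicator']}", fontsize=7)
        ax.set_ylabel(row["descriptor"], fontsize=7)
        ax.set_title(f"p={row['p']:.3f}", fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "fig_screen_examples.png", dpi=120)
    plt.close(fig)
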