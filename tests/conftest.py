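import numpy as np
import pandas as pd
import pytest

import oxysqueeze as oz


@pytest.fixture(scope="session")
def tiny_grid():
    """3x3 hand-checkable grid: elevations 1..5, cell size 2 m."""
    elev = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [3.0, 4.0, 5.0]])
    return oz.BathymetryGrid(elevations=elev, cell_size=2.0)


@pytest.fixture(scope="session")
def tiny_curve(tiny_grid):
    return oz.build_hypsometric_curve(tiny_grid)


@pytest.fixture(scope="session")
def short_sim():
    """Four simulated years of a small lake, shared across tests."""
    cfg = oz.LakeSimConfig(grid_rows=20, grid_cols=20, years=range(2001, 2005), seed=11)
    grid = oz.generate_bathymetry(cfg)
    curve = oz.build_hypsometric_curve(grid)
    levels = oz.generate_water_levels(cfg)
    profiles = oz.generate_profiles(pd.DatetimeIndex(levels["date"]), levels, cfg)
    volumes = oz.volume_series(curve, levels, profiles)
    return {
        "config": cfg,
        "grid": grid,
        "curve": curve,
        "levels": levels,
        "profiles": profiles,
        "volumes": volumes,
    }


def random_grid(rng, rows=None, cols=None):
    """Small random elevation grid with occasional nodata cells."""
    rows = rows or rng.integers(3, 7)
    cols = cols or rng.integers(3, 7)
    elev = rng.uniform(0.0, 12.0, (rows, cols))
    if rng.random() < 0.5:
        mask = rng.random((rows, cols)) < 0.2
        if mask.all():
            mask[0, 0] = False
        elev = np.where(mask, np.nan, elev)
    return oz.BathymetryGrid(elevations=elev, cell_size=float(rng.uniform(0.5, 3.0)))


def brute_force_area(grid, z):
    """Reference area: explicit per-cell count, inclusive comparison."""
    vals = grid.elevations[np.isfinite(grid.elevations)]
    return sum(1 for v in vals if v <= z) * grid.cell_area


def brute_force_volume(grid, level, temp, do, range_, scenario, n_planes=11):
    """Reference volume: explicit per-cell, per-slab counting.

    Counts are integers, so multiplying each plane count by the cell area
    and summing with ``np.sum`` reproduces the implementation's arithmetic
    exactly; the independence of the oracle lies in how the counts are
    obtained (a literal per-cell scan instead of the step-function lookup).
    """
    vals = grid.elevations[np.isfinite(grid.elevations)]
    plane_vols = []
    for d in range(n_planes):
        plane = level - d
        if not oz.is_suitable(temp[d], do[d], range_, scenario):
            plane_vols.append(0.0)
            continue
        count = sum(1 for v in vals if v <= plane)
        plane_vols.append(count * grid.cell_area)
    return float(np.sum(plane_vols))
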