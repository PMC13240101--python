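"""Reservoir hypsometry from an elevation raster.

The basin geometry enters the habitat model only through its hypsometric
curve: the cumulative count of raster cells at or below a given elevation,
scaled by the (square) cell area.  The curve is an exact right-continuous
step function — no sub-cell interpolation — so every area it returns is an
integer multiple of ``cell_area`` and agrees with a per-cell count to the
last bit.

Rasters are single-band float GeoTIFFs.  Georeferencing uses the standard
GeoTIFF ModelPixelScale/ModelTiepoint tags; nodata cells are stored as NaN
and additionally advertised through the GDAL nodata tag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import AlignmentError, EmptyRasterError, UnsupportedRasterError

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class BathymetryGrid:
    """Elevation raster with square-cell geometry.

    Parameters
    ----------
    elevations
        2-D float array of elevations in m AMSL; NaN marks nodata cells
        (outside the basin).
    cell_size
        Edge length of a (square) cell in metres.
    origin
        ``(x, y)`` map coordinate of the upper-left corner of the upper-left
        cell.  Carried as metadata; the hypsometry itself only needs
        ``cell_size``.
    """

    elevations: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        elev = np.asarray(self.elevations, dtype=float)
        if elev.ndim != 2:
            raise UnsupportedRasterError("elevation raster must be 2-D")
        if not self.cell_size > 0:
            raise UnsupportedRasterError("cell_size must be positive")
        if not np.isfinite(elev).any():
            raise EmptyRasterError("raster has no valid cells")
        object.__setattr__(self, "elevations", elev)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.elevations)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def cell_area(self) -> float:
        return self.cell_size * self.cell_size

    def aligned_with(self, other: "BathymetryGrid") -> bool:
        return (
            self.elevations.shape == other.elevations.shape
            and np.isclose(self.cell_size, other.cell_size, rtol=1e-9)
            and np.allclose(self.origin, other.origin)
        )


@dataclass(frozen=True)
class HypsometricCurve:
    """Area-at-elevation step function for a basin.

    ``elevations`` holds the sorted unique valid cell elevations and
    ``cum_counts`` the number of cells at or below each; ``area(z)`` is the
    count of cells with elevation <= z times ``cell_area`` (cells exactly at
    the water plane count as submerged).
    """

    elevations: np.ndarray
    cum_counts: np.ndarray
    cell_area: float

    def area_at(self, z) -> np.ndarray | float:
        return area_at_elevation(self, z)

    @property
    def total_cells(self) -> int:
        return int(self.cum_counts[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "elevation_m": self.elevations,
                "cumulative_area_m2": self.cum_counts * self.cell_area,
            }
        )


def write_elevation_raster(grid: BathymetryGrid, path: str | Path) -> None:
    """Write a grid as a single-band float64 GeoTIFF (NaN nodata)."""
    x0, y0 = grid.origin
    tifffile.imwrite(
        str(path),
        grid.elevations.astype(np.float64),
        extratags=[
            (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
            (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
            (_TAG_GDAL_NODATA, "s", 4, "nan"),
        ],
    )


def read_elevation_raster(path: str | Path) -> BathymetryGrid:
    """Read a single-band elevation GeoTIFF into a :class:`BathymetryGrid`.

    Cells equal to the declared nodata value (or NaN) are masked.  The pixel
    scale must be square to within a 1e-6 relative tolerance because the
    hypsometry multiplies counts by a single scalar cell area.
    """
    with tifffile.TiffFile(str(path)) as tf:
        if len(tf.pages) != 1:
            raise UnsupportedRasterError("expected a single-band raster")
        page = tf.pages[0]
        arr = np.asarray(page.asarray(), dtype=float)
        if arr.ndim != 2:
            raise UnsupportedRasterError("expected a single-band 2-D raster")
        tags = {t.code: t.value for t in page.tags.values()}

    sx, sy = 1.0, 1.0
    if _TAG_MODEL_PIXEL_SCALE in tags:
        sx, sy = float(tags[_TAG_MODEL_PIXEL_SCALE][0]), float(tags[_TAG_MODEL_PIXEL_SCALE][1])
        if abs(sx - sy) > 1e-6 * max(abs(sx), abs(sy)):
            raise UnsupportedRasterError(
                f"non-square cells ({sx} x {sy} m) are not supported"
            )
    origin = (0.0, 0.0)
    if _TAG_MODEL_TIEPOINT in tags:
        tp = tags[_TAG_MODEL_TIEPOINT]
        origin = (float(tp[3]), float(tp[4]))
    if _TAG_GDAL_NODATA in tags:
        try:
            nodata = float(str(tags[_TAG_GDAL_NODATA]).strip("\x00 "))
        except ValueError:
            nodata = np.nan
        if np.isfinite(nodata):
            arr = np.where(arr == nodata, np.nan, arr)

    if not np.isfinite(arr).any():
        raise EmptyRasterError(f"{path}: raster has no valid cells")
    return BathymetryGrid(elevations=arr, cell_size=sx, origin=origin)


def combine_bathymetry_dem(bathy: BathymetryGrid, dem: BathymetryGrid) -> BathymetryGrid:
    """Compose sonar bathymetry with a land DEM into one elevation surface.

    Surveyed bathymetry typically stops at the conservation-pool elevation;
    the surrounding DEM supplies the flood-pool shoreline above it.  The
    output takes the bathymetric elevation wherever it is valid and the DEM
    elevation elsewhere, so the merged raster covers every attainable water
    level.  Grids must share shape, cell size and origin.
    """
    if not bathy.aligned_with(dem):
        raise AlignmentError("bathymetry and DEM grids are not aligned")
    merged = np.where(np.isfinite(bathy.elevations), bathy.elevations, dem.elevations)
    return BathymetryGrid(elevations=merged, cell_size=bathy.cell_size, origin=bathy.origin)


def build_hypsometric_curve(grid: BathymetryGrid) -> HypsometricCurve:
    """Compress a grid into its exact area-at-elevation step function."""
    vals = grid.elevations[grid.valid_mask]
    elevs, counts = np.unique(vals, return_counts=True)
    return HypsometricCurve(
        elevations=elevs,
        cum_counts=np.cumsum(counts),
        cell_area=grid.cell_area,
    )


def area_at_elevation(curve: HypsometricCurve, z) -> np.ndarray | float:
    """Submerged plan area (m^2) at water-plane elevation ``z`` (m AMSL).

    Vectorised over ``z``; exact step-function evaluation with an inclusive
    comparison (cells whose elevation equals ``z`` count as submerged).
    """
    z_arr = np.asarray(z, dtype=float)
    if np.isnan(z_arr).any():
        raise ValueError("elevation query must be finite, got NaN")
    idx = np.searchsorted(curve.elevations, z_arr, side="right")
    counts = np.concatenate(([0], curve.cum_counts))
    area = counts[idx] * curve.cell_area
    if np.isscalar(z) or z_arr.ndim == 0:
        return float(area)
    return area


def export_curve_csv(curve: HypsometricCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False)
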