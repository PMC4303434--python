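"""Gaussian areas of influence rasterized into per-category kernel surfaces.

Each species contributes a radially symmetric influence field centred on its
range centroid: value 1 at the centroid, decaying as a Gaussian with
sigma = radius / 3 so the field is ~0 (3 sigma) at the edge of the circular
area of influence, and exactly 0 beyond it. A category's kernel index k at a
raster cell is the plain sum of the influences of the category's species at
the cell centre — an indicator of distributional overlap, not a normalized
density (the per-category min-max standardization applied before the
consensus absorbs any global scale factor).

The raster is a plain geographic lon/lat lattice (default cell 0.1 degrees);
cell-to-centroid distances use the same haversine metric as the range
summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .occurrences import OccurrenceTable
from .ranges import (
    KM_PER_DEG,
    CategoryScheme,
    great_circle_km,
    planar_degrees_km,
)

logger = logging.getLogger(__name__)

#: Gaussian sigma as a fraction of the influence radius (3-sigma truncation)
DEFAULT_SIGMA_RATIO = 1.0 / 3.0
DEFAULT_CELL_DEG = 0.1


@dataclass(frozen=True)
class RasterGrid:
    """A lon/lat raster: ``values[0, 0]`` is the north-west cell.

    Rows run north to south, columns west to east; cell centres are offset
    half a cell from the edges.
    """

    lon_min: float
    lat_min: float
    cell_size_deg: float
    values: np.ndarray  # (ny, nx) float

    def __post_init__(self):
        if self.cell_size_deg <= 0:
            raise ValueError("cell size must be positive")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("values must be a non-empty 2-D array")
        object.__setattr__(self, "values", v)

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.shape[1] * self.cell_size_deg

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.shape[0] * self.cell_size_deg

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.shape[1]) + 0.5) * self.cell_size_deg

    @property
    def lat_centers(self) -> np.ndarray:
        """Descending: row 0 is the northernmost."""
        return self.lat_max - (np.arange(self.shape[0]) + 0.5) * self.cell_size_deg

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.lon_min, other.lon_min)
            and np.isclose(self.lat_min, other.lat_min)
            and np.isclose(self.cell_size_deg, other.cell_size_deg)
        )

    def blank(self) -> "RasterGrid":
        return replace(self, values=np.zeros(self.shape))

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise ValueError("replacement values must keep the grid shape")
        return replace(self, values=values)

    def cell_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(row, col, inside) for points; half-open cells [west, east) x [south, north)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.cell_size_deg).astype(int)
        row_from_south = np.floor((lat - self.lat_min) / self.cell_size_deg).astype(int)
        row = self.shape[0] - 1 - row_from_south
        inside = (
            (col >= 0) & (col < self.shape[1]) & (row >= 0) & (row < self.shape[0])
        )
        return row, col, inside

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return float(self.lon_centers[col]), float(self.lat_centers[row])

    # -- text I/O ----------------------------------------------------------
    def write_ascii(self, path: str | Path, *, nodata: float = -9999.0) -> None:
        """Write as an ESRI ASCII grid (plain text, readable by any GIS)."""
        ny, nx = self.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {nx}\n")
            fh.write(f"nrows {ny}\n")
            fh.write(f"xllcorner {self.lon_min}\n")
            fh.write(f"yllcorner {self.lat_min}\n")
            fh.write(f"cellsize {self.cell_size_deg}\n")
            fh.write(f"NODATA_value {nodata}\n")
            np.savetxt(fh, self.values, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterGrid":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        return cls(
            lon_min=header["xllcorner"],
            lat_min=header["yllcorner"],
            cell_size_deg=header["cellsize"],
            values=values,
        )


def make_grid(
    lon_min: float,
    lon_max: float,
    lat_min: float,
    lat_max: float,
    cell_size_deg: float = DEFAULT_CELL_DEG,
) -> RasterGrid:
    """Empty grid covering at least the requested extent."""
    if lon_max <= lon_min or lat_max <= lat_min:
        raise ValueError("empty extent")
    nx = int(np.ceil((lon_max - lon_min) / cell_size_deg))
    ny = int(np.ceil((lat_max - lat_min) / cell_size_deg))
    return RasterGrid(lon_min, lat_min, cell_size_deg, np.zeros((ny, nx)))


def grid_for_ranges(
    ranges: pd.DataFrame, cell_size_deg: float = DEFAULT_CELL_DEG, *, pad_km: float | None = None
) -> RasterGrid:
    """Auto extent: all centroids padded by the largest influence radius.

    The km pad is converted to degrees at the grid's mid-latitude (longitude)
    and at the equatorial scale (latitude), then rounded up to whole cells.
    """
    if ranges.empty:
        raise ValueError("no species ranges")
    pad = float(pad_km if pad_km is not None else ranges["influence_radius_km"].max())
    lon = ranges["centroid_lon"].to_numpy()
    lat = ranges["centroid_lat"].to_numpy()
    mid_lat = 0.5 * (lat.min() + lat.max())
    pad_lat = pad / KM_PER_DEG
    pad_lon = pad / (KM_PER_DEG * max(np.cos(np.radians(mid_lat)), 0.1))
    return make_grid(
        lon.min() - pad_lon,
        lon.max() + pad_lon,
        lat.min() - pad_lat,
        lat.max() + pad_lat,
        cell_size_deg,
    )


def influence_value(
    dist_km, radius_km: float, *, sigma_ratio: float = DEFAULT_SIGMA_RATIO
):
    """Unitless influence in [0, 1] at distance ``dist_km`` from a centroid.

    exp(-d^2 / (2 sigma^2)) with sigma = sigma_ratio * radius, truncated to
    exactly 0 beyond the influence radius.
    """
    if radius_km <= 0:
        raise ValueError("influence radius must be positive")
    d = np.asarray(dist_km, dtype=float)
    sigma = sigma_ratio * radius_km
    v = np.exp(-(d**2) / (2.0 * sigma**2))
    v = np.where(d > radius_km, 0.0, v)
    return v if v.ndim else float(v)


@dataclass(frozen=True)
class CategorySurface:
    """Kernel-index raster for one range-size category."""

    category: int
    grid: RasterGrid
    n_species: int
    radius_km: float


def _metric(name: str):
    return great_circle_km if name == "haversine" else planar_degrees_km


def rasterize_category(
    ranges: pd.DataFrame,
    grid: RasterGrid,
    *,
    sigma_ratio: float = DEFAULT_SIGMA_RATIO,
    metric: str = "haversine",
    windowed: bool = True,
) -> CategorySurface:
    """Sum the influence fields of one category's species onto a grid.

    ``ranges`` must all share one category (hence one radius). With
    ``windowed`` (default) each species is evaluated only on the sub-grid
    its truncated kernel can reach — a pure optimization, identical to the
    full double loop because the kernel is exactly zero outside the radius.
    """
    cats = ranges["category"].unique()
    if len(cats) > 1:
        raise ValueError(f"ranges mix categories {sorted(cats)}")
    radii = ranges["influence_radius_km"].unique()
    radius = float(radii[0]) if len(radii) else 0.0

    values = np.zeros(grid.shape)
    dist = _metric(metric)
    lon_c = grid.lon_centers
    lat_c = grid.lat_centers
    for _, sp in ranges.iterrows():
        cx, cy = float(sp["centroid_lon"]), float(sp["centroid_lat"])
        if windowed:
            # reach of the truncated kernel plus one cell diagonal of slack
            reach_lat = radius / KM_PER_DEG + 2 * grid.cell_size_deg
            cos_lat = max(np.cos(np.radians(cy)), 0.05)
            reach_lon = radius / (KM_PER_DEG * cos_lat) + 2 * grid.cell_size_deg
            cols = np.nonzero(np.abs(lon_c - cx) <= reach_lon)[0]
            rows = np.nonzero(np.abs(lat_c - cy) <= reach_lat)[0]
            if cols.size == 0 or rows.size == 0:
                continue
            glon, glat = np.meshgrid(lon_c[cols], lat_c[rows])
            d = dist(cx, cy, glon, glat)
            values[np.ix_(rows, cols)] += influence_value(
                d, radius, sigma_ratio=sigma_ratio
            )
        else:
            glon, glat = np.meshgrid(lon_c, lat_c)
            d = dist(cx, cy, glon, glat)
            values += influence_value(d, radius, sigma_ratio=sigma_ratio)

    cat = int(cats[0]) if len(cats) else -1
    return CategorySurface(cat, grid.with_values(values), len(ranges), radius)


def build_all_surfaces(
    ranges: pd.DataFrame,
    scheme: CategoryScheme | str,
    grid: RasterGrid | None = None,
    *,
    cell_size_deg: float = DEFAULT_CELL_DEG,
    sigma_ratio: float = DEFAULT_SIGMA_RATIO,
    metric: str = "haversine",
) -> dict[int, CategorySurface]:
    """One kernel surface per populated category, all on one shared grid.

    Categories with no species are omitted with a log note (their surface
    would be identically zero).
    """
    from .ranges import get_scheme

    scheme = get_scheme(scheme)
    if grid is None:
        grid = grid_for_ranges(ranges, cell_size_deg)
    surfaces: dict[int, CategorySurface] = {}
    for cat in range(scheme.n_classes):
        sub = ranges[ranges["category"] == cat]
        if sub.empty:
            logger.info("category %d (%s): no species, surface omitted", cat, scheme.class_label(cat))
            continue
        surfaces[cat] = rasterize_category(
            sub, grid, sigma_ratio=sigma_ratio, metric=metric
        )
    return surfaces


def brute_force_surface(
    ranges: pd.DataFrame,
    grid: RasterGrid,
    *,
    sigma_ratio: float = DEFAULT_SIGMA_RATIO,
    metric: str = "haversine",
) -> np.ndarray:
    """Reference double loop over (cells x species); for verification only.

    Evaluates every species at every cell centre with no windowing and no
    vectorization over cells.
    """
    dist = _metric(metric)
    ny, nx = grid.shape
    lon_c, lat_c = grid.lon_centers, grid.lat_centers
    out = np.zeros((ny, nx))
    for i in range(ny):
        for j in range(nx):
            total = 0.0
            for _, sp in ranges.iterrows():
                d = dist(sp["centroid_lon"], sp["centroid_lat"], lon_c[j], lat_c[i])
                r = float(sp["influence_radius_km"])
                if d <= r:
                    sigma = sigma_ratio * r
                    total += float(np.exp(-(d**2) / (2.0 * sigma**2)))
            out[i, j] = total
    return out
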