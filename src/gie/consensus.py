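"""Consensus kernel map, isolines and delimitation of areas of endemism.

Each category surface is min-max standardized to [0, 1] so that categories
with many species do not dominate, then the standardized surfaces are summed
(optionally with per-category weights) into the consensus map. Areas of
endemism are the connected regions of the consensus at or above a threshold
level; nested thresholds express the hierarchy of areas at multiple spatial
scales. An area's support is its count of synendemic species — species whose
records all fall inside it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box, mapping
from shapely.ops import unary_union
from skimage import measure

from .kernel import CategorySurface, RasterGrid
from .occurrences import OccurrenceTable

#: default delimitation level as a fraction of the consensus maximum —
#: the outer fuzzy boundary of the areas
DEFAULT_LEVEL_FRACTION = 0.05

#: 8-connectivity for connected raster components
_STRUCTURE = np.ones((3, 3), dtype=int)


def standardize(surface: CategorySurface) -> CategorySurface:
    """Min-max rescale a surface to [0, 1] cell-wise.

    A constant surface carries no spatial signal and maps to all zeros.
    """
    v = surface.grid.values
    if not np.all(np.isfinite(v)):
        raise ValueError("surface contains non-finite values")
    lo, hi = float(v.min()), float(v.max())
    scaled = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    return CategorySurface(
        surface.category, surface.grid.with_values(scaled), surface.n_species, surface.radius_km
    )


@dataclass(frozen=True)
class ConsensusSurface:
    """Weighted sum of standardized category surfaces on a shared grid."""

    grid: RasterGrid
    category_indices: tuple[int, ...]
    weights: tuple[float, ...]

    @property
    def max_value(self) -> float:
        return float(self.grid.values.max())


def build_consensus(
    surfaces: Mapping[int, CategorySurface],
    weights: Mapping[int, float] | None = None,
) -> ConsensusSurface:
    """Standardize each category surface and sum them, optionally weighted.

    ``weights`` maps category index -> non-negative multiplier (default 1
    for every category); weighting a scale emphasizes it in the consensus
    without changing the isoline geometry of the others.
    """
    if not surfaces:
        raise ValueError("no surfaces to combine")
    cats = sorted(surfaces)
    ref = surfaces[cats[0]].grid
    total = np.zeros(ref.shape)
    used_w = []
    for cat in cats:
        s = surfaces[cat]
        if not s.grid.same_geometry(ref):
            raise ValueError("surfaces must share one grid geometry")
        w = 1.0 if weights is None else float(weights.get(cat, 1.0))
        if w < 0:
            raise ValueError("weights must be >= 0")
        used_w.append(w)
        total += w * standardize(s).grid.values
    return ConsensusSurface(ref.with_values(total), tuple(cats), tuple(used_w))


def extract_isolines(
    consensus: ConsensusSurface, levels: Sequence[float]
) -> dict[float, list[np.ndarray]]:
    """Level curves of the consensus raster (marching squares).

    Returns, per level, a list of (n, 2) lon/lat vertex arrays. Contours are
    computed on cell centres with bilinear sub-cell interpolation; a level
    above the raster maximum yields no curves.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("no isoline levels given")
    g = consensus.grid
    out: dict[float, list[np.ndarray]] = {}
    for level in levels:
        rings = []
        for contour in measure.find_contours(g.values, level):
            lon = g.lon_min + (contour[:, 1] + 0.5) * g.cell_size_deg
            lat = g.lat_max - (contour[:, 0] + 0.5) * g.cell_size_deg
            rings.append(np.column_stack([lon, lat]))
        out[float(level)] = rings
    return out


@dataclass(frozen=True)
class EndemismArea:
    """One delimited area of endemism at a stated consensus level."""

    area_id: int
    level: float
    polygon: object  # shapely (Multi)Polygon: union of the component's cells
    endemic_species: tuple[str, ...]
    peak_k: float
    n_cells: int
    touches_border: bool
    cell_mask: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def n_synendemics(self) -> int:
        return len(self.endemic_species)


def _component_polygon(grid: RasterGrid, mask: np.ndarray):
    """Union of the cell rectangles of a raster component."""
    rows, cols = np.nonzero(mask)
    cells = [
        box(
            grid.lon_min + c * grid.cell_size_deg,
            grid.lat_max - (r + 1) * grid.cell_size_deg,
            grid.lon_min + (c + 1) * grid.cell_size_deg,
            grid.lat_max - r * grid.cell_size_deg,
        )
        for r, c in zip(rows, cols)
    ]
    return unary_union(cells)


def delimit_areas(
    consensus: ConsensusSurface,
    table: OccurrenceTable,
    *,
    level: float | None = None,
    level_fraction: float = DEFAULT_LEVEL_FRACTION,
    min_synendemics: int = 1,
    endemic_fraction: float = 1.0,
) -> list[EndemismArea]:
    """Delimit areas of endemism at one consensus threshold.

    The threshold is ``level`` if given, else ``level_fraction`` times the
    consensus maximum. Cells with consensus >= threshold (ties inside) form
    8-connected components; a species supports a component when at least
    ``endemic_fraction`` of its records fall in it (default 1.0: every
    record, the strict synendemic reading — a record outside the grid never
    counts as inside). Components with fewer than ``min_synendemics``
    endemic species are discarded. Areas are ordered west to east and
    numbered from 0; components touching the grid border are kept but
    flagged as possibly truncated by the extent.
    """
    g = consensus.grid
    if level is None:
        level = level_fraction * consensus.max_value
    if level <= 0:
        raise ValueError("delimitation level must be positive")
    mask = g.values >= level
    labels, n_comp = ndimage.label(mask, structure=_STRUCTURE)

    # map every record to its component (0 = background / off grid)
    rows, cols, inside = g.cell_of(table.df["lon"].to_numpy(), table.df["lat"].to_numpy())
    rec_comp = np.zeros(len(table.df), dtype=int)
    rec_comp[inside] = labels[rows[inside], cols[inside]]
    species = table.df["species"].to_numpy()

    areas = []
    for comp in range(1, n_comp + 1):
        comp_mask = labels == comp
        members = []
        for sp in np.unique(species):
            sel = species == sp
            frac = np.mean(rec_comp[sel] == comp)
            if frac >= endemic_fraction and frac > 0:
                members.append(sp)
        if len(members) < min_synendemics:
            continue
        rr, cc = np.nonzero(comp_mask)
        touches = bool(
            rr.min() == 0 or cc.min() == 0
            or rr.max() == g.shape[0] - 1 or cc.max() == g.shape[1] - 1
        )
        areas.append(
            dict(
                polygon=_component_polygon(g, comp_mask),
                endemic_species=tuple(sorted(members)),
                peak_k=float(g.values[comp_mask].max()),
                n_cells=int(comp_mask.sum()),
                touches_border=touches,
                cell_mask=comp_mask,
                west=g.lon_centers[cc.min()],
            )
        )

    areas.sort(key=lambda a: (a["west"], -a["n_cells"]))
    return [
        EndemismArea(
            area_id=i,
            level=float(level),
            polygon=a["polygon"],
            endemic_species=a["endemic_species"],
            peak_k=a["peak_k"],
            n_cells=a["n_cells"],
            touches_border=a["touches_border"],
            cell_mask=a["cell_mask"],
        )
        for i, a in enumerate(areas)
    ]


def delimit_nested(
    consensus: ConsensusSurface,
    table: OccurrenceTable,
    levels: Sequence[float],
    **kwargs,
) -> dict[float, list[EndemismArea]]:
    """Areas at each level of an ascending isoline ladder (nested hierarchy)."""
    levels = sorted(float(v) for v in levels)
    return {lv: delimit_areas(consensus, table, level=lv, **kwargs) for lv in levels}


def area_report(areas: Sequence[EndemismArea]) -> pd.DataFrame:
    """Tabular summary, one row per area, deterministic ordering."""
    rows = [
        {
            "area_id": a.area_id,
            "level": a.level,
            "peak_k": a.peak_k,
            "n_cells": a.n_cells,
            "n_synendemics": a.n_synendemics,
            "touches_border": a.touches_border,
            "species": ";".join(a.endemic_species),
        }
        for a in sorted(areas, key=lambda a: (a.level, a.area_id))
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "area_id", "level", "peak_k", "n_cells",
            "n_synendemics", "touches_border", "species",
        ],
    )


def areas_to_geojson(areas: Sequence[EndemismArea], path: str | Path | None = None) -> dict:
    """GeoJSON FeatureCollection of area polygons with their support stats."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(a.polygon),
            "properties": {
                "area_id": a.area_id,
                "level": a.level,
                "peak_k": a.peak_k,
                "n_synendemics": a.n_synendemics,
                "touches_border": a.touches_border,
                "endemic_species": list(a.endemic_species),
            },
        }
        for a in areas
    ]
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(collection))
    return collection


def isolines_to_geojson(
    isolines: Mapping[float, list[np.ndarray]], path: str | Path | None = None
) -> dict:
    """GeoJSON FeatureCollection of isoline curves tagged with their level."""
    features = []
    for level, rings in isolines.items():
        for ring in rings:
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [[float(x), float(y)] for x, y in ring],
                    },
                    "properties": {"level": level},
                }
            )
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(collection))
    return collection
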