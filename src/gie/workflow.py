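"""End-to-end convenience wrapper: occurrences in, areas of endemism out."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .consensus import (
    ConsensusSurface,
    DEFAULT_LEVEL_FRACTION,
    EndemismArea,
    area_report,
    areas_to_geojson,
    build_consensus,
    delimit_areas,
    delimit_nested,
    extract_isolines,
    isolines_to_geojson,
)
from .kernel import (
    DEFAULT_CELL_DEG,
    CategorySurface,
    RasterGrid,
    build_all_surfaces,
    grid_for_ranges,
)
from .occurrences import OccurrenceTable
from .ranges import CategoryScheme, DEFAULT_SCHEME, build_ranges, get_scheme


@dataclass(frozen=True)
class GIEResult:
    """Everything one analysis produces, from ranges to delimited areas."""

    ranges: pd.DataFrame
    surfaces: dict[int, CategorySurface]
    consensus: ConsensusSurface
    areas: list[EndemismArea]
    nested: dict[float, list[EndemismArea]]
    level: float

    @property
    def report(self) -> pd.DataFrame:
        return area_report(self.areas)


def run_gie(
    table: OccurrenceTable,
    scheme: CategoryScheme | str = DEFAULT_SCHEME,
    *,
    cell_size_deg: float = DEFAULT_CELL_DEG,
    grid: RasterGrid | None = None,
    weights: Mapping[int, float] | None = None,
    level_fraction: float = DEFAULT_LEVEL_FRACTION,
    levels: Sequence[float] | None = None,
    min_synendemics: int = 1,
    endemic_fraction: float = 1.0,
) -> GIEResult:
    """Run the full analysis on one occurrence table.

    ``levels`` are additional absolute isoline thresholds for the nested
    hierarchy; the primary delimitation always uses ``level_fraction`` of
    the consensus maximum.
    """
    scheme = get_scheme(scheme)
    ranges = build_ranges(table, scheme)
    if grid is None:
        grid = grid_for_ranges(ranges, cell_size_deg)
    surfaces = build_all_surfaces(ranges, scheme, grid)
    consensus = build_consensus(surfaces, weights)
    level = level_fraction * consensus.max_value
    areas = delimit_areas(
        consensus,
        table,
        level=level,
        min_synendemics=min_synendemics,
        endemic_fraction=endemic_fraction,
    )
    nested = (
        delimit_nested(
            consensus, table, levels,
            min_synendemics=min_synendemics, endemic_fraction=endemic_fraction,
        )
        if levels
        else {}
    )
    return GIEResult(ranges, surfaces, consensus, areas, nested, level)


def write_results(result: GIEResult, out_dir: str | Path) -> None:
    """Write the standard output set: rasters, areas, isolines, report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.ranges.to_csv(out / "ranges.csv", index=False)
    for cat, surf in result.surfaces.items():
        surf.grid.write_ascii(out / f"category_{cat}.asc")
    result.consensus.grid.write_ascii(out / "consensus.asc")
    result.report.to_csv(out / "areas.csv", index=False)
    areas_to_geojson(result.areas, out / "areas.geojson")
    if result.nested:
        iso = extract_isolines(result.consensus, sorted(result.nested))
        isolines_to_geojson(iso, out / "isolines.geojson")
        frames = [area_report(a) for a in result.nested.values() if a]
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                out / "areas_nested.csv", index=False
            )
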