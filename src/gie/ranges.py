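"""Per-species range summaries: centroid, farthest-point distance, category.

Each species' distribution is summarized by the arithmetic-mean centroid of
its record coordinates and by the great-circle distance from that centroid
to its farthest record. The farthest-point distance sorts species into
range-size categories; every species in a category shares one influence
radius, the category's upper distance bound, used downstream as the kernel
bandwidth scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .occurrences import OccurrenceTable

logger = logging.getLogger(__name__)

#: mean Earth radius, km (IUGG); 1 degree of arc = 111.195 km
EARTH_RADIUS_KM = 6371.0088
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Haversine great-circle distance in km on a sphere of radius 6371.0088 km.

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


def planar_degrees_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Planar Euclidean distance in degree-equivalent km (unit-test aid only).

    Treats lon/lat as plane coordinates and scales degrees by 111.195 km.
    Not meaningful away from the equator; exists so hand calculations on
    small planar configurations can be checked exactly.
    """
    d = np.hypot(np.asarray(lon2, float) - lon1, np.asarray(lat2, float) - lat1) * KM_PER_DEG
    return d if np.ndim(d) else float(d)


def compute_centroid(coords: np.ndarray) -> tuple[float, float]:
    """Arithmetic-mean centroid (lon, lat) of an (n, 2) lon/lat array.

    The mean is taken coordinate-wise in degrees — deliberately not a
    geodesic mean, because the range summary is defined that way. A warning
    is emitted for species spanning more than 180 degrees of longitude,
    where a plain mean is not meaningful (antimeridian wrap).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise ValueError("cannot compute the centroid of an empty record set")
    if np.ptp(coords[:, 0]) > 180.0:
        logger.warning("species spans >180 degrees of longitude; centroid may wrap")
    lon, lat = coords.mean(axis=0)
    return float(lon), float(lat)


def max_range_distance(
    coords: np.ndarray, centroid: tuple[float, float], *, metric: str = "haversine"
) -> float:
    """Distance from the centroid to the farthest record, km (0 for singletons)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    dist = great_circle_km if metric == "haversine" else planar_degrees_km
    return float(np.max(dist(centroid[0], centroid[1], coords[:, 0], coords[:, 1])))


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered range-size classes defined by increasing km breakpoints.

    Class 0 covers [0, breakpoints[0]]; class i > 0 covers
    (breakpoints[i-1], breakpoints[i]]. The right-closed convention keeps a
    species sitting exactly on a bound in the smaller class, whose radius is
    the less generous generalization of its range.
    """

    breakpoints_km: tuple[float, ...]
    labels: tuple[str, ...] | None = None
    name: str = "custom"

    def __post_init__(self):
        b = np.asarray(self.breakpoints_km, dtype=float)
        if b.size == 0 or np.any(b <= 0) or np.any(np.diff(b) <= 0):
            raise ValueError("breakpoints must be strictly increasing positive km")
        if self.labels is not None and len(self.labels) != b.size:
            raise ValueError("one label per class required")

    @property
    def n_classes(self) -> int:
        return len(self.breakpoints_km)

    @property
    def max_distance_km(self) -> float:
        return self.breakpoints_km[-1]

    def class_label(self, index: int) -> str:
        if self.labels is not None:
            return self.labels[index]
        lo = 0.0 if index == 0 else self.breakpoints_km[index - 1]
        return f"up to {self.breakpoints_km[0]:g} km" if index == 0 else (
            f"{lo:g}-{self.breakpoints_km[index]:g} km"
        )

    def assign(self, max_dist_km: float) -> int:
        """Category index for a farthest-point distance."""
        if max_dist_km < 0:
            raise ValueError("distance must be >= 0")
        if max_dist_km > self.max_distance_km:
            raise ValueError(
                f"range distance {max_dist_km:.1f} km exceeds the scheme's largest "
                f"bound ({self.max_distance_km:g} km); extend the scheme"
            )
        return int(np.searchsorted(self.breakpoints_km, max_dist_km, side="left"))

    def radius_of(self, index: int) -> float:
        """Influence radius for a class: its upper distance bound, km."""
        return float(self.breakpoints_km[index])


#: preset categorization schemes (continental-scale defaults; the 9-class
#: scheme is the package default, with a coarser 5-class and finer 18-class
#: alternative for sensitivity checks)
PRESET_SCHEMES: dict[str, CategoryScheme] = {
    "classes9": CategoryScheme(
        (50, 200, 400, 600, 800, 1000, 1500, 2000, 3299), name="classes9"
    ),
    "classes5": CategoryScheme((50, 400, 600, 800, 3299), name="classes5"),
    "classes18": CategoryScheme(
        (25, 50, 100, 200, 300, 400, 500, 600, 700, 800, 900, 1000,
         1300, 1600, 1750, 2000, 2500, 3299),
        name="classes18",
    ),
}
DEFAULT_SCHEME = PRESET_SCHEMES["classes9"]


def get_scheme(spec: str | Sequence[float] | CategoryScheme) -> CategoryScheme:
    """Resolve a scheme from a preset name, a breakpoint list, or pass through."""
    if isinstance(spec, CategoryScheme):
        return spec
    if isinstance(spec, str):
        try:
            return PRESET_SCHEMES[spec]
        except KeyError:
            raise KeyError(
                f"unknown scheme {spec!r}; presets: {sorted(PRESET_SCHEMES)}"
            ) from None
    return CategoryScheme(tuple(float(b) for b in spec))


#: columns of the range-summary table
RANGE_COLUMNS = (
    "species", "n_records", "centroid_lon", "centroid_lat",
    "max_dist_km", "category", "influence_radius_km",
)


def build_ranges(
    table: OccurrenceTable,
    scheme: CategoryScheme | str = DEFAULT_SCHEME,
    *,
    metric: str = "haversine",
) -> pd.DataFrame:
    """One range summary row per species (columns: ``RANGE_COLUMNS``).

    ``influence_radius_km`` is the upper bound of the species' category, so
    all species in a class share one radius.
    """
    scheme = get_scheme(scheme)
    rows = []
    for sp, sub in table.df.groupby("species", sort=True):
        coords = sub[["lon", "lat"]].to_numpy()
        centroid = compute_centroid(coords)
        d = max_range_distance(coords, centroid, metric=metric)
        cat = scheme.assign(d)
        rows.append((sp, len(sub), centroid[0], centroid[1], d, cat, scheme.radius_of(cat)))
    return pd.DataFrame(rows, columns=list(RANGE_COLUMNS))


def write_ranges_csv(ranges: pd.DataFrame, path: str | Path) -> None:
    ranges.to_csv(path, index=False)
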