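"""Synthetic occurrence datasets with planted endemism structure.

The generator emulates the profile of a large, museum-style continental
occurrence database: a long-tailed record-count distribution in which about
40% of species are known from a single record, 45% from 2-15 records, 10%
from 16-60, 3% from 61-100 and 2% from more than 100; clusters of
co-occurring restricted-range species planted around well-separated
endemic centers; plus widespread species whose records span the whole
extent and should support no area. The planted membership (species ->
center) is returned as ground truth, which is what makes end-to-end
recovery experiments possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .occurrences import OccurrenceTable
from .ranges import KM_PER_DEG, great_circle_km

#: record-count bins and default species fractions (singletons first)
DEFAULT_COUNT_BINS = ((1, 1), (2, 15), (16, 60), (61, 100), (101, 200))
DEFAULT_BIN_PROBS = (0.40, 0.45, 0.10, 0.03, 0.02)

WIDESPREAD = "widespread"


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of a planted endemism landscape.

    The defaults describe a continental-scale extent with five endemic
    centers of 30 restricted species each. Scatter of a species' records
    about its center is an isotropic Gaussian with sigma =
    ``within_center_radius_km / 2`` hard-truncated at the radius, so no
    planted record lies farther than the radius from its center and
    category assignment stays predictable. Auto-placed centers keep a
    minimum pairwise separation of ``min_separation_km`` (default 800 km =
    4x the 200-km range-size class that multi-record planted species with
    50-km scatter typically occupy, so neighbouring clusters stay
    resolvable).
    """

    extent: tuple[float, float, float, float] = (-70.0, -35.0, -30.0, 5.0)
    n_centers: int = 5
    center_positions: tuple[tuple[float, float], ...] | None = None
    species_per_center: int = 30
    within_center_radius_km: float = 50.0
    min_separation_km: float = 800.0
    n_widespread: int = 10
    widespread_records: tuple[int, int] = (5, 30)
    singleton_fraction: float = 0.40
    count_bins: tuple[tuple[int, int], ...] = DEFAULT_COUNT_BINS
    bin_probs: tuple[float, ...] = DEFAULT_BIN_PROBS
    seed: int = 0

    def __post_init__(self):
        lon0, lon1, lat0, lat1 = self.extent
        if lon1 <= lon0 or lat1 <= lat0:
            raise ValueError("empty extent")
        if not 0.0 <= self.singleton_fraction <= 1.0:
            raise ValueError("singleton_fraction must lie in [0, 1]")
        if self.within_center_radius_km <= 0:
            raise ValueError("within_center_radius_km must be positive")
        if len(self.bin_probs) != len(self.count_bins):
            raise ValueError("one probability per count bin")


@dataclass(frozen=True)
class GroundTruth:
    """Planted membership: species id -> center index, or 'widespread'."""

    membership: dict[str, int | str]
    center_positions: tuple[tuple[float, float], ...]

    def species_of_center(self, center: int) -> list[str]:
        return sorted(sp for sp, c in self.membership.items() if c == center)

    @property
    def endemic_species(self) -> list[str]:
        return sorted(sp for sp, c in self.membership.items() if c != WIDESPREAD)


def _draw_record_counts(
    rng: np.random.Generator, n: int, spec: LandscapeSpec
) -> np.ndarray:
    """Long-tailed record counts honouring the singleton fraction."""
    probs = np.asarray(spec.bin_probs, dtype=float)
    probs = probs / probs.sum()
    if spec.singleton_fraction != probs[0]:
        rest = probs[1:] / probs[1:].sum() * (1.0 - spec.singleton_fraction)
        probs = np.concatenate([[spec.singleton_fraction], rest])
    bins = rng.choice(len(spec.count_bins), size=n, p=probs)
    counts = np.empty(n, dtype=int)
    for i, b in enumerate(bins):
        lo, hi = spec.count_bins[b]
        if lo == hi:
            counts[i] = lo
        elif (lo, hi) == (2, 15):
            # geometric-like tail over 2..15
            k = lo + rng.geometric(0.3) - 1
            counts[i] = min(int(k), hi)
        else:
            counts[i] = rng.integers(lo, hi + 1)
    return counts


def _place_centers(rng: np.random.Generator, spec: LandscapeSpec) -> np.ndarray:
    if spec.center_positions is not None:
        if len(spec.center_positions) != spec.n_centers:
            raise ValueError("need one position per center")
        return np.asarray(spec.center_positions, dtype=float)
    lon0, lon1, lat0, lat1 = spec.extent
    centers: list[tuple[float, float]] = []
    for _ in range(10000):
        if len(centers) == spec.n_centers:
            break
        lon = rng.uniform(lon0, lon1)
        lat = rng.uniform(lat0, lat1)
        if all(
            great_circle_km(lon, lat, c[0], c[1]) >= spec.min_separation_km
            for c in centers
        ):
            centers.append((lon, lat))
    else:
        raise RuntimeError(
            "could not place centers with the requested separation; "
            "enlarge the extent or reduce min_separation_km"
        )
    return np.asarray(centers, dtype=float)


def _scatter_about(
    rng: np.random.Generator, lon: float, lat: float, radius_km: float, n: int
) -> np.ndarray:
    """Isotropic Gaussian km offsets (sigma = radius/2) truncated at radius."""
    sigma = radius_km / 2.0
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        need = n - filled
        dx = rng.normal(0.0, sigma, size=2 * need + 4)
        dy = rng.normal(0.0, sigma, size=2 * need + 4)
        ok = np.hypot(dx, dy) <= radius_km
        take = min(int(ok.sum()), need)
        out[filled : filled + take, 0] = dx[ok][:take]
        out[filled : filled + take, 1] = dy[ok][:take]
        filled += take
    lon_off = out[:, 0] / (KM_PER_DEG * np.cos(np.radians(lat)))
    lat_off = out[:, 1] / KM_PER_DEG
    return np.column_stack([lon + lon_off, lat + lat_off])


def generate_dataset(spec: LandscapeSpec) -> tuple[OccurrenceTable, GroundTruth]:
    """Generate a planted landscape; bit-reproducible from ``spec.seed``.

    Endemic species scatter around their center within
    ``within_center_radius_km``; widespread species are uniform over the
    extent. Species ids encode nothing about membership beyond a stable
    naming convention (``c<center>_s<i>`` / ``wide_s<i>``) used by the
    ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(rng, spec)

    rows = []
    membership: dict[str, int | str] = {}
    n_endemic = spec.n_centers * spec.species_per_center
    counts = _draw_record_counts(rng, n_endemic, spec)
    i_sp = 0
    for c, (clon, clat) in enumerate(centers):
        for _ in range(spec.species_per_center):
            sp = f"c{c}_s{i_sp:04d}"
            n_rec = counts[i_sp]
            coords = _scatter_about(rng, clon, clat, spec.within_center_radius_km, n_rec)
            for lon, lat in coords:
                rows.append((sp, lon, lat))
            membership[sp] = c
            i_sp += 1

    lon0, lon1, lat0, lat1 = spec.extent
    for w in range(spec.n_widespread):
        sp = f"wide_s{w:04d}"
        n_rec = int(rng.integers(spec.widespread_records[0], spec.widespread_records[1] + 1))
        lon = rng.uniform(lon0, lon1, n_rec)
        lat = rng.uniform(lat0, lat1, n_rec)
        for x, y in zip(lon, lat):
            rows.append((sp, x, y))
        membership[sp] = WIDESPREAD

    df = pd.DataFrame(rows, columns=["species", "lon", "lat"])
    table, _ = OccurrenceTable.from_dataframe(df)
    truth = GroundTruth(membership, tuple((float(a), float(b)) for a, b in centers))
    return table, truth


def perturb_dataset(
    table: OccurrenceTable,
    jitter_km: float = 0.0,
    drop_fraction: float = 0.0,
    seed: int = 0,
) -> OccurrenceTable:
    """Jitter coordinates isotropically and/or drop records at random.

    ``jitter_km`` is the per-axis Gaussian sigma of the km displacement;
    ``drop_fraction`` removes round(fraction * n) records uniformly.
    Reproducible from ``seed``; with both parameters zero the table is
    returned unchanged.
    """
    if jitter_km < 0 or not 0.0 <= drop_fraction < 1.0:
        raise ValueError("jitter_km >= 0 and 0 <= drop_fraction < 1 required")
    if jitter_km == 0.0 and drop_fraction == 0.0:
        return table
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    if drop_fraction > 0:
        n_drop = int(round(drop_fraction * len(df)))
        if n_drop:
            drop_idx = rng.choice(len(df), size=n_drop, replace=False)
            df = df.drop(df.index[drop_idx])
    if jitter_km > 0:
        dx = rng.normal(0.0, jitter_km, len(df))
        dy = rng.normal(0.0, jitter_km, len(df))
        df["lon"] = df["lon"] + dx / (KM_PER_DEG * np.cos(np.radians(df["lat"])))
        df["lat"] = df["lat"] + dy / KM_PER_DEG
    table2, _ = OccurrenceTable.from_dataframe(df)
    return table2
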