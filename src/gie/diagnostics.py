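"""Robustness and screening diagnostics for centroid-based endemism analysis.

Covers: rarefaction of occurrence records to gauge centroid stability under
sampling deficiency; screening for elongated or disjoint species
distributions, which a circular area of influence generalizes poorly;
correlation between kernel maps (cell-wise or by sampling random points per
coarse grid cell); sensitivity of the consensus to the range-size
categorization scheme; and export of the presence/absence species-by-cell
matrix used by grid-based methods for external comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .consensus import ConsensusSurface, build_consensus
from .kernel import CategorySurface, RasterGrid, build_all_surfaces, grid_for_ranges
from .occurrences import OccurrenceTable
from .ranges import (
    KM_PER_DEG,
    CategoryScheme,
    build_ranges,
    compute_centroid,
    get_scheme,
    great_circle_km,
)

DEFAULT_REMOVAL_FRACTIONS = (0.1, 0.2, 0.3)
DEFAULT_N_REPLICATES = 100

#: sentinel elongation for degenerate (collinear / 2-point) distributions
ELONGATION_CAP = 1e3


# ---------------------------------------------------------------------------
# rarefaction of occurrence points
# ---------------------------------------------------------------------------

def rarefy_centroids(
    table: OccurrenceTable,
    fractions: Sequence[float] = DEFAULT_REMOVAL_FRACTIONS,
    n_reps: int = DEFAULT_N_REPLICATES,
    seed: int | None = 0,
    *,
    per_species: bool = True,
) -> pd.DataFrame:
    """Centroid displacement under random removal of occurrence records.

    For each species and removal fraction, records are removed at random
    (count = round(fraction * n), at least 1) in ``n_reps`` replicates and
    the great-circle displacement between the original and rarefied centroid
    is recorded. Species with a single record are skipped — removing their
    only record leaves nothing to summarize. Fully reproducible from
    ``seed``.

    With ``per_species=False`` the removal is global: each replicate drops
    the fraction from the pooled record set, and species losing all their
    records in a replicate contribute no displacement value to it.

    Returns a DataFrame with columns species, fraction, n_records,
    mean_displacement_km, var_displacement_km2, n_replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    fractions = [float(f) for f in fractions]
    if any(f < 0 or f >= 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    groups = {
        sp: sub[["lon", "lat"]].to_numpy()
        for sp, sub in table.df.groupby("species", sort=True)
    }
    eligible = {sp: xy for sp, xy in groups.items() if len(xy) >= 2}
    centroids = {sp: compute_centroid(xy) for sp, xy in eligible.items()}

    rows = []
    if per_species:
        for sp, xy in eligible.items():
            n = len(xy)
            c0 = centroids[sp]
            for frac in fractions:
                n_remove = int(round(frac * n))
                if frac > 0:
                    n_remove = max(n_remove, 1)
                n_remove = min(n_remove, n - 1)
                disp = np.empty(n_reps)
                for rep in range(n_reps):
                    if n_remove == 0:
                        disp[rep] = 0.0
                        continue
                    keep = np.ones(n, dtype=bool)
                    keep[rng.choice(n, size=n_remove, replace=False)] = False
                    c1 = compute_centroid(xy[keep])
                    disp[rep] = great_circle_km(c0[0], c0[1], c1[0], c1[1])
                rows.append(
                    (sp, frac, n, float(disp.mean()), float(disp.var(ddof=0)), n_reps)
                )
    else:
        df = table.df
        n_total = len(df)
        species_arr = df["species"].to_numpy()
        xy_all = df[["lon", "lat"]].to_numpy()
        for frac in fractions:
            n_remove = max(int(round(frac * n_total)), 1) if frac > 0 else 0
            disp_acc: dict[str, list[float]] = {sp: [] for sp in eligible}
            for rep in range(n_reps):
                keep = np.ones(n_total, dtype=bool)
                if n_remove:
                    keep[rng.choice(n_total, size=n_remove, replace=False)] = False
                for sp in eligible:
                    sel = keep & (species_arr == sp)
                    if not sel.any():
                        continue
                    c0 = centroids[sp]
                    c1 = compute_centroid(xy_all[sel])
                    disp_acc[sp].append(
                        float(great_circle_km(c0[0], c0[1], c1[0], c1[1]))
                    )
            for sp, vals in disp_acc.items():
                v = np.asarray(vals)
                rows.append(
                    (sp, frac, len(eligible[sp]), float(v.mean()),
                     float(v.var(ddof=0)), len(v))
                )

    return pd.DataFrame(
        rows,
        columns=[
            "species", "fraction", "n_records",
            "mean_displacement_km", "var_displacement_km2", "n_replicates",
        ],
    )


def displacement_histogram(
    results: pd.DataFrame, bin_km: float = 50.0
) -> pd.DataFrame:
    """Species counts per displacement class, per removal fraction.

    Bins are half-open on the left, (i*bin, (i+1)*bin], with zero
    displacements counted in the first bin; the same binning is applied to
    the replicate variance (in km^2, bin width ``bin_km``^2). Counts per
    fraction sum to the number of species analyzed.
    """
    if results.empty:
        raise ValueError("no rarefaction results to bin")

    def bin_index(v: np.ndarray, width: float) -> np.ndarray:
        idx = np.ceil(np.asarray(v) / width).astype(int) - 1
        return np.maximum(idx, 0)

    rows = []
    for frac, sub in results.groupby("fraction"):
        mean_bins = bin_index(sub["mean_displacement_km"].to_numpy(), bin_km)
        var_bins = bin_index(sub["var_displacement_km2"].to_numpy(), bin_km**2)
        n_bins = int(max(mean_bins.max(), var_bins.max())) + 1
        for b in range(n_bins):
            rows.append(
                {
                    "fraction": frac,
                    "bin_low_km": b * bin_km,
                    "bin_high_km": (b + 1) * bin_km,
                    "n_species_mean": int((mean_bins == b).sum()),
                    "n_species_var": int((var_bins == b).sum()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# shape screening: elongation and disjunction
# ---------------------------------------------------------------------------

def _local_km(coords: np.ndarray) -> np.ndarray:
    """Project lon/lat to km east/north offsets about the centroid.

    Equirectangular about the centroid latitude — adequate at range scale.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    lon0, lat0 = coords.mean(axis=0)
    x = (coords[:, 0] - lon0) * KM_PER_DEG * np.cos(np.radians(lat0))
    y = (coords[:, 1] - lat0) * KM_PER_DEG
    return np.column_stack([x, y])


def elongation_index(
    coords: np.ndarray, *, threshold: float = 3.0, cap: float = ELONGATION_CAP
) -> tuple[float, bool]:
    """Anisotropy of a species' records: sqrt of the covariance eigenvalue ratio.

    1.0 for an isotropic cloud, larger the more elongated. Collinear or
    two-point distributions have a degenerate minor axis and are capped at
    ``cap`` and flagged. Returns ``(index, flagged)`` with ``flagged`` true
    when the index is at or above ``threshold``.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if len(coords) < 2:
        raise ValueError("elongation needs at least 2 records")
    xy = _local_km(coords)
    cov = np.cov(xy, rowvar=False)
    evals = np.sort(np.linalg.eigvalsh(cov))
    if evals[0] <= 1e-12 * max(evals[1], 1.0):
        return float(cap), True
    ratio = float(np.sqrt(evals[1] / evals[0]))
    ratio = min(ratio, cap)
    return ratio, ratio >= threshold


def screen_elongation(
    table: OccurrenceTable, *, threshold: float = 3.0
) -> pd.DataFrame:
    """Elongation index and flag for every species with >= 2 records."""
    rows = []
    for sp, sub in table.df.groupby("species", sort=True):
        if len(sub) < 2:
            continue
        idx, flagged = elongation_index(sub[["lon", "lat"]].to_numpy(), threshold=threshold)
        rows.append((sp, len(sub), idx, flagged))
    return pd.DataFrame(rows, columns=["species", "n_records", "elongation", "flagged"])


def detect_disjoint(coords: np.ndarray, gap_km: float) -> np.ndarray:
    """Single-linkage clusters of one species' records at a km gap threshold.

    Two records share a cluster when a chain of records links them with no
    step longer than ``gap_km``. Returns integer labels (0..k-1) per record,
    numbered by order of first appearance.
    """
    if gap_km <= 0:
        raise ValueError("gap_km must be positive")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    if n == 1:
        return np.zeros(1, dtype=int)
    lon, lat = coords[:, 0], coords[:, 1]
    dmat = great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    z = linkage(squareform(dmat, checks=False), method="single")
    raw = fcluster(z, t=gap_km, criterion="distance")
    # renumber by first appearance for determinism
    order: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        labels[i] = order.setdefault(r, len(order))
    return labels


def split_disjoint_species(
    table: OccurrenceTable, gap_km: float, *, min_cluster_size: int = 1
) -> OccurrenceTable:
    """Relabel disjoint species so each record cluster is its own pseudo-species.

    A species split into k > 1 clusters appears as ``<id>@0`` .. ``<id>@k-1``,
    each with its own centroid and range downstream, so one species can
    support several areas of endemism. Clusters below ``min_cluster_size``
    keep the split label but can be filtered by the caller.
    """
    frames = []
    for sp, sub in table.df.groupby("species", sort=True):
        labels = detect_disjoint(sub[["lon", "lat"]].to_numpy(), gap_km)
        out = sub.copy()
        if labels.max() > 0:
            out["species"] = [f"{sp}@{k}" for k in labels]
        frames.append(out)
    df = pd.concat(frames, ignore_index=True)
    table2, _ = OccurrenceTable.from_dataframe(df)
    return table2


# ---------------------------------------------------------------------------
# map congruence
# ---------------------------------------------------------------------------

def _as_grid(surface) -> RasterGrid:
    if isinstance(surface, RasterGrid):
        return surface
    if isinstance(surface, (CategorySurface, ConsensusSurface)):
        return surface.grid
    raise TypeError(f"cannot interpret {type(surface).__name__} as a raster")


def map_correlation(
    surface_a,
    surface_b,
    *,
    mode: str = "cellwise",
    grid_cell_deg: float = 2.0,
    n_points_per_cell: int = 10,
    seed: int | None = 0,
) -> float:
    """Pearson correlation between two kernel maps on one grid geometry.

    ``cellwise`` pairs every raster cell (deterministic). ``sampled``
    reproduces the coarse-grid congruence protocol: overlay a coarse grid of
    ``grid_cell_deg`` cells, estimate each coarse cell's value on each map
    as the mean over ``n_points_per_cell`` uniform random points (the point
    takes the value of the fine cell containing it), then correlate the
    per-cell means.
    """
    ga, gb = _as_grid(surface_a), _as_grid(surface_b)
    if not ga.same_geometry(gb):
        raise ValueError("maps must share one grid geometry")

    if mode == "cellwise":
        a, b = ga.values.ravel(), gb.values.ravel()
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        a_means, b_means = [], []
        lon_edges = np.arange(ga.lon_min, ga.lon_max, grid_cell_deg)
        lat_edges = np.arange(ga.lat_min, ga.lat_max, grid_cell_deg)
        for lon0 in lon_edges:
            for lat0 in lat_edges:
                lon = rng.uniform(lon0, min(lon0 + grid_cell_deg, ga.lon_max), n_points_per_cell)
                lat = rng.uniform(lat0, min(lat0 + grid_cell_deg, ga.lat_max), n_points_per_cell)
                rows, cols, inside = ga.cell_of(lon, lat)
                if not inside.any():
                    continue
                a_means.append(ga.values[rows[inside], cols[inside]].mean())
                b_means.append(gb.values[rows[inside], cols[inside]].mean())
        a, b = np.asarray(a_means), np.asarray(b_means)
    else:
        raise ValueError("mode must be 'cellwise' or 'sampled'")

    if a.size < 3:
        raise ValueError("fewer than 3 pairs for correlation")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0  # two constant maps are identical up to offset
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("one map is constant; correlation undefined")
    if np.array_equal(a, b):
        return 1.0
    return float(pearsonr(a, b)[0])


def compare_schemes(
    table: OccurrenceTable,
    schemes: Sequence[CategoryScheme | str],
    *,
    cell_size_deg: float = 0.1,
    grid: RasterGrid | None = None,
    mode: str = "cellwise",
    seed: int | None = 0,
) -> pd.DataFrame:
    """Pairwise Pearson r between consensus maps built under each scheme.

    All schemes are run on one shared grid (auto-sized to cover every
    centroid padded by the largest influence radius over all schemes), so
    the correlations compare the consensus values cell for cell.
    """
    schemes = [get_scheme(s) for s in schemes]
    if len(schemes) < 2:
        raise ValueError("need at least two schemes to compare")
    names = []
    for i, s in enumerate(schemes):
        names.append(s.name if s.name != "custom" else f"scheme{i}")

    range_sets = [build_ranges(table, s) for s in schemes]
    if grid is None:
        pad = max(r["influence_radius_km"].max() for r in range_sets)
        grid = grid_for_ranges(range_sets[0], cell_size_deg, pad_km=pad)

    consensi = []
    for s, ranges in zip(schemes, range_sets):
        surfaces = build_all_surfaces(ranges, s, grid)
        consensi.append(build_consensus(surfaces))

    n = len(schemes)
    r = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r[i, j] = r[j, i] = map_correlation(
                consensi[i], consensi[j], mode=mode, seed=seed
            )
    return pd.DataFrame(r, index=names, columns=names)


# ---------------------------------------------------------------------------
# presence/absence grid matrix (for external grid-based methods)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridMatrix:
    """Binary species-by-cell incidence over a rectangular lon/lat grid.

    ``incidence`` is a DataFrame: rows = cell ids (``r<row>c<col>``),
    columns = species, values 0/1. Cells are half-open,
    [west, east) x [south, north), so a record on a shared edge belongs to
    exactly one cell.
    """

    cell_deg: float
    lon_min: float
    lat_min: float
    n_rows: int
    n_cols: int
    incidence: pd.DataFrame

    def cell_bounds(self, cell_id: str) -> tuple[float, float, float, float]:
        r, c = cell_id[1:].split("c")
        r, c = int(r), int(c)
        w = self.lon_min + c * self.cell_deg
        s = self.lat_min + r * self.cell_deg
        return (w, s, w + self.cell_deg, s + self.cell_deg)

    def write_csv(self, path: str | Path) -> None:
        self.incidence.to_csv(path, index_label="cell")

    def write_nexus(self, path: str | Path, *, add_root: bool = True) -> None:
        """NEXUS data block (cells as taxa, species as binary characters).

        With ``add_root`` an all-absent hypothetical cell is appended for
        rooting a parsimony analysis.
        """
        inc = self.incidence
        taxa = list(inc.index)
        rows = {t: "".join(str(int(v)) for v in inc.loc[t]) for t in taxa}
        if add_root:
            taxa = ["root_all_absent"] + taxa
            rows["root_all_absent"] = "0" * inc.shape[1]
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(taxa)} NCHAR={inc.shape[1]};\n")
            fh.write('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
            fh.write("  MATRIX\n")
            width = max(len(t) for t in taxa) + 2
            for t in taxa:
                fh.write(f"    {t:<{width}}{rows[t]}\n")
            fh.write("  ;\nEND;\n")


def build_grid_matrix(
    table: OccurrenceTable,
    cell_deg: float = 2.0,
    extent: tuple[float, float, float, float] | None = None,
) -> GridMatrix:
    """Presence/absence matrix of species over a grid of ``cell_deg`` cells.

    ``extent`` is (lon_min, lon_max, lat_min, lat_max); by default the grid
    snaps to cell multiples covering every record. A species is present in a
    cell iff at least one of its records falls in the half-open cell.
    """
    if cell_deg <= 0:
        raise ValueError("cell_deg must be positive")
    df = table.df
    if extent is None:
        lon_min = np.floor(df["lon"].min() / cell_deg) * cell_deg
        lat_min = np.floor(df["lat"].min() / cell_deg) * cell_deg
        lon_max = df["lon"].max()
        lat_max = df["lat"].max()
    else:
        lon_min, lon_max, lat_min, lat_max = extent
    n_cols = max(int(np.floor((lon_max - lon_min) / cell_deg)) + 1, 1)
    n_rows = max(int(np.floor((lat_max - lat_min) / cell_deg)) + 1, 1)

    col = np.floor((df["lon"].to_numpy() - lon_min) / cell_deg).astype(int)
    row = np.floor((df["lat"].to_numpy() - lat_min) / cell_deg).astype(int)
    inside = (col >= 0) & (col < n_cols) & (row >= 0) & (row < n_rows)

    species = sorted(df["species"].unique())
    cell_ids = [f"r{r}c{c}" for r in range(n_rows) for c in range(n_cols)]
    inc = pd.DataFrame(0, index=cell_ids, columns=species, dtype=int)
    sp_arr = df["species"].to_numpy()
    for i in np.nonzero(inside)[0]:
        inc.loc[f"r{row[i]}c{col[i]}", sp_arr[i]] = 1
    return GridMatrix(cell_deg, float(lon_min), float(lat_min), n_rows, n_cols, inc)
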