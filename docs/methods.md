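# Methods

## The problem

An *area of endemism* — the basic unit of historical biogeography — is a
region delimited by the overlapping ranges of two or more species restricted
to it. Because real species never share exactly the same range limits, areas
of endemism have fuzzy edges, which grid-based delimitation methods (cell
clustering, parsimony analysis of endemism, NDM-style optimality searches)
represent poorly: a record on a cell edge claims the whole cell, and the
cell size imposes a hard lower bound on detectable spatial scale.

This package implements a grid-free alternative: kernel interpolation of
species-range centroids. The degree of distributional overlap among species
is estimated as a continuous surface, and areas of endemism are read off the
surface as nested isoline-bounded regions.

## The procedure

For each species *s* with occurrence records
(x₁,y₁) … (x_n,y_n) in decimal degrees:

1. **Centroid** — the coordinate-wise arithmetic mean of the record
   longitudes and latitudes. Deliberately not a geodesic mean; the
   definition is the plain average, and at the regional scales intended
   (well away from the antimeridian) the difference is negligible. A
   warning is emitted for species spanning > 180° of longitude.
2. **Range distance** — d_s = max_i haversine(centroid, record_i) on a
   sphere of radius R = 6371.0088 km (so one degree of arc = 111.195 km).
   Zero for single-record species.
3. **Category** — d_s sorts the species into one of an ordered set of
   range-size classes given by km breakpoints b₁ < … < b_K. Class 0 covers
   [0, b₁]; class j covers (b_j, b_{j+1}]. Right-closed intervals keep a
   species sitting exactly on a bound in the *smaller* class: assigning it
   the larger class's radius would overestimate the range of the more
   restricted species. A distance beyond b_K is an error instructing the
   user to extend the scheme.
4. **Influence field** — every species in class j radiates influence
   v(d) = exp(−d² / 2σ²) with σ = r_j / 3 and r_j = b_{j+1} the class's
   upper bound, truncated to exactly 0 for d > r_j. The σ = r/3 choice
   makes the field ≈ 0 (three sigma) at the boundary of the circular area
   of influence, so "circular area" and "Gaussian decay" are honoured
   simultaneously; the ratio is configurable (`sigma_ratio`).
5. **Kernel index** — per category, k(cell) = Σ_s v(haversine(cell centre,
   centroid_s)). This is a raw sum of influences, not a density normalized
   by bandwidth area: k is an indicator of overlap, and the standardization
   below absorbs any global per-category scale factor (an invariance the
   tests assert directly).
6. **Consensus** — each category raster is min–max standardized to [0, 1]
   (a constant raster maps to zeros), then the standardized rasters are
   summed, optionally with non-negative per-category weights to emphasize a
   scale. Standardization prevents species-rich categories from dominating.
7. **Areas of endemism** — cells with consensus ≥ a threshold level form
   8-connected components. The default level is 0.05 × the consensus
   maximum (the outer fuzzy boundary); a user-supplied ladder of levels
   yields the nested hierarchy of areas at finer scales. Isolines for
   display are extracted by marching squares with bilinear sub-cell
   interpolation.
8. **Synendemic support** — a species supports an area when **all** of its
   records fall inside (records off the grid never count as inside). This
   totality rule is the strictest reading of "endemic to"; a relaxed
   threshold (`endemic_fraction` < 1) admits species with a stated fraction
   of records inside. Areas with fewer than `min_synendemics` (default 1)
   supporting species are discarded.

Area polygons are exported as the union of the component's cell rectangles,
so point-in-polygon membership and raster-mask membership coincide by
construction.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| scheme | `classes9` (50, 200, 400, 600, 800, 1000, 1500, 2000, 3299 km) | range-size classes; `classes5` and `classes18` presets for sensitivity checks |
| cell size | 0.1° | raster resolution; the grid auto-extends to all centroids padded by the largest influence radius |
| sigma_ratio | 1/3 | Gaussian σ as a fraction of the influence radius |
| level_fraction | 0.05 | delimitation threshold relative to the consensus maximum |
| endemic_fraction | 1.0 | fraction of a species' records required inside an area |

The preset breakpoints are continental-scale defaults; users should explore
alternative schemes (`compare_schemes` quantifies the effect as pairwise
Pearson correlations between consensus maps computed on one shared grid).

## Diagnostics

- **Rarefaction** (`rarefy_centroids`): per species, remove
  round(f·n) ≥ 1 records at random (f ∈ {0.1, 0.2, 0.3} by default, 100
  replicates) and record the mean and variance of the centroid
  displacement. Species with one record are skipped — removing their only
  record is undefined. Per-species removal is the primary mode; a global
  mode (drop a fraction of the pooled records) is available behind
  `per_species=False`. Same seed ⇒ bit-identical results.
- **Elongation** (`elongation_index`): √(λ₁/λ₂) of the covariance of the
  records projected to km east/north offsets about the centroid
  (equirectangular: Δlon·cos φ·111.195, Δlat·111.195 — adequate at range
  scale). 1 for isotropic clouds, ≈ a/b for a uniform a:b ellipse;
  collinear or two-point species have a degenerate minor axis and are
  capped at 10³ and flagged. Species flagged above the threshold (default
  3) are poorly generalized by a circular area of influence.
- **Disjunction** (`detect_disjoint`): single-linkage clustering of a
  species' records with a km gap threshold; `split_disjoint_species`
  relabels each cluster as a pseudo-species (`id@k`) so one species can
  support several areas, each cluster with its own centroid.
- **Map congruence** (`map_correlation`): Pearson r between two rasters of
  one geometry, either cell-wise (deterministic; the test default) or by
  the sampled protocol used for comparisons against coarse-grid methods:
  mean of 10 uniform random points per 2° cell (each point takes its fine
  cell's value), then correlate the per-cell means.
- **Grid matrix** (`build_grid_matrix`): binary species × cell incidence
  over half-open cells [west, east) × [south, north); exported as CSV and
  as a NEXUS block with an optional all-absent hypothetical root row for
  external parsimony software.

## The synthetic-data generator

`generate_dataset(LandscapeSpec(...))` plants K endemic centers (default 5,
auto-placed with ≥ 800 km pairwise separation in a 35° × 35° extent) with
`species_per_center` restricted species each, plus widespread species
uniform over the extent. Record counts per species follow the long-tailed
museum-database profile: 40% singletons, 45% with 2–15 records
(truncated-geometric), 10% with 16–60, 3% with 61–100, 2% with more than
100. Records scatter around their center as an isotropic Gaussian with
σ = radius/2 hard-truncated at `within_center_radius_km` (default 50 km),
so no planted record exceeds the radius and category assignment stays
predictable. The 800 km default separation is 4 × the 200-km class radius
that multi-record planted species typically occupy, which keeps neighbouring
clusters resolvable at the default level.

What the generator does **not** emulate: spatial sampling bias (real
databases oversample roads and research stations), georeferencing error,
taxonomic inconsistency, environmental structure in ranges, and
non-circular (elongated, river- or mountain-bound) true ranges. Passing
recovery tests therefore shows the machinery is correct under the model's
own assumptions, not that real areas of endemism are equally recoverable.

## Numerical choices and degenerate inputs

- Distances are haversine on a sphere; an optional planar-degrees metric
  exists solely for unit tests against hand calculations.
- Windowed rasterization skips species farther from a cell than the
  truncation radius plus slack — exact, because the kernel is identically
  zero there (asserted against a naive double loop at 1e−9 relative).
- A constant category surface standardizes to zeros; a level above the
  consensus maximum yields no areas; ties at exactly the level count as
  inside; areas touching the grid border are flagged as possibly truncated.
- `map_correlation` returns exactly 1.0 for bit-identical inputs and for
  two constant maps, and raises when only one map is constant or fewer
  than 3 pairs are available.

## Known limitations

- Species whose farthest-point distance sits near a class breakpoint can
  flip class under small coordinate perturbations; when a class holds few
  species, its standardized surface — and hence the consensus — can change
  noticeably. Well-populated classes are insensitive to single flips. This
  is inherent to hard categorization; explore alternative schemes.
- Elongated but congruent species ranges are delimited correctly in
  location but rendered as circular overlap, inflating the area's spatial
  footprint; screen with `elongation_index` first.
- The arithmetic-mean centroid is not meaningful across the antimeridian.
- The consensus maximum depends on how many categories are populated, so
  the default level (a fraction of the maximum) is landscape-relative;
  absolute thresholds are available wherever a level is accepted.

## Problem sizes used in the test suite

Recovery experiments use 5 centers × 30 species (~1,100–1,600 records) on a
~0.1° grid over 20 fixed seeds; scheme comparisons use one 160-species
landscape; rarefaction uses 40 species × 50 records × 100 replicates;
kernel-oracle checks use ≤ 5 species on ≤ 50 × 50 grids over 100 random
configurations. These sizes make the full suite run in well under a minute
while leaving every statistical check comfortably powered.
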