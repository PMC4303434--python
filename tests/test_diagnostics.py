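"""Rarefaction, shape screening, map congruence and the grid matrix."""

import numpy as np
import pandas as pd
import pytest

from gie import (
    build_grid_matrix,
    compare_schemes,
    detect_disjoint,
    displacement_histogram,
    elongation_index,
    great_circle_km,
    make_grid,
    map_correlation,
    rarefy_centroids,
    screen_elongation,
    split_disjoint_species,
)

from conftest import make_table


class TestRarefyCentroids:
    def test_coincident_records_never_move_the_centroid(self):
        table = make_table([(f"a", 10.0 + 1e-9 * i, 5.0) for i in range(6)])
        res = rarefy_centroids(table, (0.1, 0.3), n_reps=20, seed=0)
        assert (res["mean_displacement_km"] < 1e-3).all()

    def test_singleton_species_excluded(self):
        table = make_table([("solo", 0, 0), ("duo", 1, 1), ("duo", 1.2, 1)])
        res = rarefy_centroids(table, (0.1,), n_reps=5, seed=0)
        assert set(res["species"]) == {"duo"}

    def test_zero_removal_count_gives_zero_displacement(self):
        table = make_table([("a", 0, 0), ("a", 1, 0), ("a", 2, 0)])
        res = rarefy_centroids(table, (0.0,), n_reps=5, seed=0)
        assert (res["mean_displacement_km"] == 0).all()

    def test_same_seed_bit_reproducible(self, isotropic_table):
        a = rarefy_centroids(isotropic_table, (0.1, 0.2), n_reps=20, seed=9)
        b = rarefy_centroids(isotropic_table, (0.1, 0.2), n_reps=20, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_disjoint_seeds_agree_within_monte_carlo_error(self, isotropic_table):
        a = rarefy_centroids(isotropic_table, (0.2,), n_reps=100, seed=1)
        b = rarefy_centroids(isotropic_table, (0.2,), n_reps=100, seed=2)
        se = np.sqrt(
            a["var_displacement_km2"] / a["n_replicates"]
            + b["var_displacement_km2"] / b["n_replicates"]
        )
        diff = (a["mean_displacement_km"] - b["mean_displacement_km"]).abs()
        assert (diff <= 3 * se + 1e-9).all()

    def test_displacement_nondecreasing_in_fraction(self, isotropic_table):
        res = rarefy_centroids(isotropic_table, (0.1, 0.2, 0.3), n_reps=100, seed=7)
        piv = res.pivot(index="species", columns="fraction", values="mean_displacement_km")
        violations = ((piv[0.2] < piv[0.1]) | (piv[0.3] < piv[0.2])).mean()
        assert violations <= 0.05

    def test_ring_species_small_monotone_displacement(self):
        # 100 records on a 1-degree ring: removing 10% moves the centroid
        # far less than the ring radius
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        table = make_table(
            [("ring", float(np.cos(t)), float(np.sin(t))) for t in theta]
        )
        res = rarefy_centroids(table, (0.1, 0.2, 0.3), n_reps=100, seed=3)
        ring_radius_km = 111.195
        assert (res["mean_displacement_km"] < 0.2 * ring_radius_km).all()
        m = res.set_index("fraction")["mean_displacement_km"]
        assert m[0.1] <= m[0.2] + 1.0 and m[0.2] <= m[0.3] + 1.0

    def test_global_mode_runs_and_reports_all_eligible(self, isotropic_table):
        res = rarefy_centroids(
            isotropic_table, (0.2,), n_reps=10, seed=0, per_species=False
        )
        assert res["species"].nunique() == 40


class TestDisplacementHistogram:
    def test_all_zero_displacements_in_first_bin(self):
        res = pd.DataFrame(
            {
                "species": ["a", "b"],
                "fraction": [0.1, 0.1],
                "n_records": [5, 5],
                "mean_displacement_km": [0.0, 0.0],
                "var_displacement_km2": [0.0, 0.0],
                "n_replicates": [10, 10],
            }
        )
        h = displacement_histogram(res, bin_km=50)
        assert h.loc[0, "n_species_mean"] == 2

    def test_two_species_in_adjacent_bins(self):
        res = pd.DataFrame(
            {
                "species": ["a", "b"],
                "fraction": [0.1, 0.1],
                "n_records": [5, 5],
                "mean_displacement_km": [10.0, 70.0],
                "var_displacement_km2": [0.0, 0.0],
                "n_replicates": [10, 10],
            }
        )
        h = displacement_histogram(res, bin_km=50).set_index("bin_low_km")
        assert h.loc[0, "n_species_mean"] == 1
        assert h.loc[50, "n_species_mean"] == 1

    def test_counts_match_brute_force_tally(self, isotropic_table):
        res = rarefy_centroids(isotropic_table, (0.1, 0.3), n_reps=20, seed=5)
        h = displacement_histogram(res, bin_km=5.0)
        for frac, sub in res.groupby("fraction"):
            hh = h[h["fraction"] == frac]
            assert hh["n_species_mean"].sum() == len(sub)
            # oracle: sort + count per half-open bin
            for _, row in hh.iterrows():
                lo, hi = row["bin_low_km"], row["bin_high_km"]
                vals = sub["mean_displacement_km"]
                expected = (
                    ((vals > lo) & (vals <= hi)).sum()
                    if lo > 0
                    else (vals <= hi).sum()
                )
                assert row["n_species_mean"] == expected


class TestElongation:
    def test_square_is_isotropic(self):
        # symmetric about the equator so the local km projection is exact
        idx, flagged = elongation_index(
            [(0, -0.05), (0, 0.05), (0.1, -0.05), (0.1, 0.05)]
        )
        assert idx == pytest.approx(1.0, abs=1e-9)
        assert not flagged

    def test_collinear_capped_and_flagged(self):
        idx, flagged = elongation_index([(0, 0), (0.5, 0), (1.0, 0)])
        assert idx == 1e3 and flagged

    def test_two_points_degenerate(self):
        idx, flagged = elongation_index([(0, 0), (1, 1)])
        assert flagged

    def test_uniform_three_to_one_ellipse(self):
        rng = np.random.default_rng(20)
        pts = []
        while len(pts) < 200:
            x, y = rng.uniform(-3, 3), rng.uniform(-1, 1)
            if (x / 3) ** 2 + y**2 <= 1:
                pts.append((x * 0.1, y * 0.1))
        idx, flagged = elongation_index(pts)
        assert idx == pytest.approx(3.0, rel=0.1)
        assert flagged

    def test_screen_skips_singletons(self):
        table = make_table([("solo", 0, 0), ("duo", 0, 0), ("duo", 1, 0)])
        out = screen_elongation(table)
        assert set(out["species"]) == {"duo"}


class TestDetectDisjoint:
    def test_two_far_clusters_split(self):
        coords = [(0, 0), (0.1, 0), (9, 0), (9.1, 0)]  # ~1000 km apart
        labels = detect_disjoint(np.array(coords), gap_km=200)
        assert labels.tolist() == [0, 0, 1, 1]

    def test_large_gap_merges_everything(self):
        coords = [(0, 0), (0.1, 0), (9, 0), (9.1, 0)]
        labels = detect_disjoint(np.array(coords), gap_km=2000)
        assert len(set(labels)) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-5, 5, (20, 2))
        gap = 150.0
        labels = detect_disjoint(coords, gap)

        # independent union-find over the thresholded distance graph
        parent = list(range(20))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(20):
            for j in range(i + 1, 20):
                d = great_circle_km(coords[i, 0], coords[i, 1], coords[j, 0], coords[j, 1])
                if d <= gap:
                    parent[find(i)] = find(j)
        roots = [find(i) for i in range(20)]
        # same partition: label equality pattern must match
        for i in range(20):
            for j in range(20):
                assert (labels[i] == labels[j]) == (roots[i] == roots[j])

    def test_split_creates_pseudo_species(self):
        table = make_table(
            [("sp", 0, 0), ("sp", 0.1, 0), ("sp", 9, 0), ("sp", 9.1, 0), ("one", 3, 3)]
        )
        t2 = split_disjoint_species(table, gap_km=200)
        assert set(t2.df["species"]) == {"sp@0", "sp@1", "one"}


class TestMapCorrelation:
    def make(self, values):
        return make_grid(0, values.shape[1], 0, values.shape[0], 1.0).with_values(values)

    def test_identity_is_exactly_one(self):
        rng = np.random.default_rng(0)
        g = self.make(rng.uniform(0, 1, (10, 10)))
        assert map_correlation(g, g) == 1.0

    def test_reflection_is_minus_one(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, (10, 10))
        r = map_correlation(self.make(v), self.make(v.max() - v))
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(10):
            a = self.make(rng.uniform(0, 1, (25, 40)))  # 1000 cells
            b = self.make(rng.uniform(0, 1, (25, 40)))
            if abs(map_correlation(a, b)) < 0.1:
                hits += 1
        assert hits >= 9

    def test_bounds_always_hold(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = self.make(rng.uniform(0, 5, (6, 6)))
            b = self.make(rng.uniform(0, 5, (6, 6)))
            assert -1.0 <= map_correlation(a, b) <= 1.0

    def test_sampled_mode_reproducible_and_close_to_cellwise(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(0, 1, (40, 40))
        a = self.make(base)
        b = self.make(base + rng.normal(0, 0.1, (40, 40)))
        r1 = map_correlation(a, b, mode="sampled", grid_cell_deg=4.0, seed=5)
        r2 = map_correlation(a, b, mode="sampled", grid_cell_deg=4.0, seed=5)
        assert r1 == r2
        assert -1.0 <= r1 <= 1.0

    def test_too_few_pairs_rejected(self):
        g = self.make(np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError):
            map_correlation(g, g)


class TestCompareSchemes:
    def test_identical_schemes_correlate_perfectly(self, planted):
        _, table, _ = planted
        r = compare_schemes(table, ["classes9", "classes9"], cell_size_deg=0.2)
        assert r.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matrix_symmetric_unit_diagonal(self, planted):
        _, table, _ = planted
        r = compare_schemes(table, ["classes5", "classes9"], cell_size_deg=0.2)
        assert np.allclose(r.values, r.values.T)
        assert np.allclose(np.diag(r.values), 1.0)

    def test_single_scheme_rejected(self, planted):
        _, table, _ = planted
        with pytest.raises(ValueError):
            compare_schemes(table, ["classes9"])


class TestGridMatrix:
    def test_single_record_single_incidence(self):
        table = make_table([("a", 0.5, 0.5)])
        gm = build_grid_matrix(table, cell_deg=2.0)
        assert gm.incidence.values.sum() == 1

    def test_shared_edge_assigned_to_one_cell_only(self):
        # record exactly on the lon=2 edge of a 2-degree grid
        table = make_table([("a", 2.0, 0.5), ("pad", 0.1, 0.1), ("pad2", 3.9, 1.9)])
        gm = build_grid_matrix(table, cell_deg=2.0, extent=(0, 4, 0, 2))
        col_a = gm.incidence["a"]
        assert col_a.sum() == 1
        assert col_a["r0c1"] == 1  # east-exclusive: belongs to the eastern cell

    def test_three_species_hand_enumerated(self):
        table = make_table(
            [
                ("a", 0.5, 0.5),          # cell r0c0
                ("b", 2.5, 0.5),          # cell r0c1
                ("b", 0.5, 2.5),          # cell r1c0
                ("c", 2.5, 2.5),          # cell r1c1
                ("c", 2.6, 2.7),          # same cell
            ]
        )
        gm = build_grid_matrix(table, cell_deg=2.0, extent=(0, 4, 0, 4))
        expected = {
            ("r0c0", "a"): 1, ("r0c1", "b"): 1, ("r1c0", "b"): 1, ("r1c1", "c"): 1,
        }
        for (cell, sp), v in expected.items():
            assert gm.incidence.loc[cell, sp] == v
        assert gm.incidence.values.sum() == 4

    def test_row_col_sums_match_direct_tally(self, planted):
        _, table, _ = planted
        gm = build_grid_matrix(table, cell_deg=2.0)
        df = table.df
        for sp in list(gm.incidence.columns)[:10]:
            sub = df[df["species"] == sp]
            cells = set(
                (
                    int(np.floor((y - gm.lat_min) / gm.cell_deg)),
                    int(np.floor((x - gm.lon_min) / gm.cell_deg)),
                )
                for x, y in sub[["lon", "lat"]].to_numpy()
            )
            assert gm.incidence[sp].sum() == len(cells)

    def test_writers_produce_nexus_with_root(self, tmp_path):
        table = make_table([("a", 0.5, 0.5), ("b", 2.5, 0.5)])
        gm = build_grid_matrix(table, cell_deg=2.0)
        gm.write_csv(tmp_path / "m.csv")
        gm.write_nexus(tmp_path / "m.nex", add_root=True)
        text = (tmp_path / "m.nex").read_text()
        assert "#NEXUS" in text and "root_all_absent" in text
        assert "0" * 2 in text
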