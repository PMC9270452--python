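"""Great-circle math, equal-area grid, cluster hulls, dispersion, decay, space-for-time."""

import math

import numpy as np
import pytest

from paleobeta.geography import (
    EARTH_RADIUS_KM,
    GridSpec,
    assign_to_cells,
    behrmann_project,
    behrmann_unproject,
    cluster_hull_range,
    distance_decay,
    great_circle_km,
    mean_range_size,
    multivariate_dispersion,
    occupancy,
    space_for_time_map,
)
from .conftest import make_site


class TestGreatCircle:
    def test_identical_points(self):
        assert great_circle_km(-100.0, 40.0, -100.0, 40.0) == 0.0

    def test_antipodal(self):
        assert great_circle_km(0.0, 0.0, 180.0, 0.0) == pytest.approx(math.pi * EARTH_RADIUS_KM, abs=0.01)

    def test_one_equatorial_degree(self):
        assert great_circle_km(0.0, 0.0, 1.0, 0.0) == pytest.approx(EARTH_RADIUS_KM * math.pi / 180, abs=1e-6)

    def test_symmetry_and_triangle_inequality(self, rng):
        pts = np.column_stack([rng.uniform(-180, 180, 30), rng.uniform(-80, 80, 30)])
        for (x1, y1), (x2, y2), (x3, y3) in zip(pts[:10], pts[10:20], pts[20:]):
            d12 = great_circle_km(x1, y1, x2, y2)
            assert d12 == pytest.approx(great_circle_km(x2, y2, x1, y1), abs=1e-9)
            assert d12 <= great_circle_km(x1, y1, x3, y3) + great_circle_km(x3, y3, x2, y2) + 1e-6


class TestBehrmann:
    def test_origin(self):
        x, y = behrmann_project(0.0, 0.0)
        assert (x, y) == (0.0, 0.0)

    def test_one_degree_lon(self):
        x, y = behrmann_project(1.0, 0.0)
        assert x == pytest.approx(111.195 * math.cos(math.radians(30)), abs=0.01)
        assert y == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("lat", [0.0, 30.0, 60.0, 70.0])
    def test_equal_area_vs_spherical_patch(self, lat):
        # spherical area of a 1x1 degree cell: R^2 * dlam * (sin(lat2) - sin(lat1))
        x1, y1 = behrmann_project(10.0, lat)
        x2, y2 = behrmann_project(11.0, lat + 1.0)
        projected = abs((x2 - x1) * (y2 - y1))
        spherical = EARTH_RADIUS_KM**2 * math.radians(1.0) * (
            math.sin(math.radians(lat + 1.0)) - math.sin(math.radians(lat))
        )
        assert projected == pytest.approx(spherical, rel=1e-3)

    def test_unproject_roundtrip(self, rng):
        lon = rng.uniform(-170, 170, 20)
        lat = rng.uniform(-80, 80, 20)
        lon2, lat2 = behrmann_unproject(*behrmann_project(lon, lat))
        assert np.allclose(lon, lon2) and np.allclose(lat, lat2)


class TestGrid:
    def test_nearby_sites_share_cell(self):
        grid = GridSpec.north_america()
        sites = [make_site("a", {"sp"}, lon=-100.0, lat=40.0), make_site("b", {"sp"}, lon=-100.05, lat=40.05)]
        cells = assign_to_cells(sites, grid)
        assert len(cells["sp"]) == 1

    def test_occupancy_fraction(self):
        grid = GridSpec(x0=0.0, y0=0.0, ncols=121, nrows=76)  # 9196 cells
        assert grid.n_cells == 9196
        assert occupancy({1, 2, 3, 4, 5}, grid) == pytest.approx(5 / 9196)

    def test_boundary_tie_goes_to_lower_cell(self):
        grid = GridSpec(x0=0.0, y0=0.0, ncols=4, nrows=4, cell_km=100.0)
        # x=100 is equidistant between the centers of columns 0 and 1
        assert grid.assign_xy(100.0, 50.0)[0] == 0
        assert grid.assign_xy(150.0, 50.0)[0] == 1

    def test_outside_extent_names_site(self):
        grid = GridSpec(x0=0.0, y0=0.0, ncols=2, nrows=2)
        with pytest.raises(ValueError, match="lost"):
            grid.assign_xy(999.0, 50.0, names=["lost"])

    def test_merging_cells_never_exceeds_unit_occupancy(self, small_binned):
        grid = GridSpec.north_america()
        for _, members in small_binned.bins:
            for cells in assign_to_cells(members, grid).values():
                assert 0 < occupancy(cells, grid) <= 1


class TestClusterHull:
    def test_coincident_points(self):
        pts = np.zeros((5, 2))
        assert cluster_hull_range(pts) == 0.0

    def test_right_triangle_with_interior_points(self):
        # hull is the 100-km right triangle; interior points do not change it
        pts = np.array([[0, 0], [100, 0], [0, 100], [20, 20], [30, 10]], dtype=float)
        assert cluster_hull_range(pts) == pytest.approx(5000.0, abs=1e-6)

    def test_two_far_clusters_sum_small_hulls(self, rng):
        c1 = rng.normal(0, 30, size=(10, 2))
        c2 = rng.normal(0, 30, size=(10, 2)) + [2000.0, 0.0]
        area = cluster_hull_range(np.vstack([c1, c2]), level=0.95)
        # one giant hull would span ~2000 km x cluster width (>> 2 x small hulls)
        from shapely.geometry import MultiPoint

        giant = MultiPoint([tuple(p) for p in np.vstack([c1, c2])]).convex_hull.area
        small = (MultiPoint([tuple(p) for p in c1]).convex_hull.area
                 + MultiPoint([tuple(p) for p in c2]).convex_hull.area)
        # clusters never span the 2000-km gap: the estimate is bounded by the
        # sum of the per-cloud hulls (sub-clustering can only shrink it) and is
        # far below the single spanning hull
        assert 0 < area <= small + 1e-9
        assert area < giant / 5

    def test_point_order_invariance(self, rng):
        pts = rng.normal(0, 200, size=(14, 2))
        base = cluster_hull_range(pts)
        for _ in range(5):
            assert cluster_hull_range(pts[rng.permutation(len(pts))]) == pytest.approx(base, rel=1e-9)

    def test_rotation_invariance(self, rng):
        pts = rng.normal(0, 200, size=(12, 2))
        theta = 0.7
        R = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
        assert cluster_hull_range(pts @ R.T) == pytest.approx(cluster_hull_range(pts), rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cluster_hull_range(np.zeros((4, 2)))


class TestMeanRangeSize:
    def test_identical_point_sets_give_zero_sem(self, small_binned):
        import pandas as pd

        from paleobeta.occurrences import BinnedDataset, TimeBinConfig, assign_time_bins

        traits = pd.DataFrame({"species_id": ["a", "b"], "order_name": "Rodentia",
                               "mass_kg": 1.0, "extinct": False})
        sites = [
            make_site(f"s{i}", {"a", "b"}, lon=-100.0 + i, lat=40.0 + (i % 3), age=12_000.0)
            for i in range(6)
        ]
        binned = assign_time_bins(sites, TimeBinConfig(edges=(15_000.0, 10_000.0), modern_bin=False), traits)
        tbl = mean_range_size(binned, GridSpec.north_america())
        assert tbl.loc[0, "sem_area_km2"] == 0.0
        assert tbl.loc[0, "n_species_area"] == 2

    def test_planar_scaling_quadruples_area(self, rng):
        pts = rng.normal(0, 150, size=(20, 2))
        assert cluster_hull_range(2 * pts) == pytest.approx(4 * cluster_hull_range(pts), rel=1e-9)


class TestDistanceDecay:
    def test_constant_similarity(self):
        fit = distance_decay([0.4] * 10, np.linspace(10, 2000, 10))
        assert fit.slope == pytest.approx(0.0, abs=1e-8)

    def test_exponential_recovery(self):
        d = np.linspace(50, 3000, 10)
        fit = distance_decay(np.exp(-d / 1000.0), d)
        assert fit.slope == pytest.approx(-0.001, abs=1e-5)
        assert fit.intercept == pytest.approx(0.0, abs=1e-4)

    def test_steeper_decay_more_negative(self):
        d = np.linspace(50, 3000, 12)
        shallow = distance_decay(np.exp(-d / 2000.0), d).slope
        steep = distance_decay(np.exp(-d / 500.0), d).slope
        assert steep < shallow < 0

    def test_ols_family(self):
        d = np.linspace(0, 10, 8)
        fit = distance_decay(0.9 - 0.05 * d, d, family="ols")
        assert fit.slope == pytest.approx(-0.05, abs=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            distance_decay([0.1, np.nan, 0.2], [1.0, 2.0, 3.0])


class TestDispersion:
    def test_zero_matrix(self):
        D = np.zeros((6, 6))
        disp = multivariate_dispersion(D, ["g1"] * 3 + ["g2"] * 3)
        assert disp == {"g1": 0.0, "g2": 0.0}

    def test_euclidean_isometry_oracle(self, rng):
        pts = rng.normal(size=(9, 2))
        groups = np.array(["a"] * 4 + ["b"] * 5)
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        disp = multivariate_dispersion(D, groups)
        for g in ("a", "b"):
            sub = pts[groups == g]
            direct = np.linalg.norm(sub - sub.mean(axis=0), axis=1).mean()
            assert disp[g] == pytest.approx(direct, rel=1e-9)

    def test_asymmetric_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            multivariate_dispersion(D, ["a", "b"])

    def test_non_negative_on_non_euclidean_input(self, rng):
        # Jaccard dissimilarities are generally non-Euclidean -> negative eigenvalues
        X = rng.random((8, 10)) < 0.4
        X[:, 0] = True
        inter = (X[:, None, :] & X[None, :, :]).sum(-1)
        union = (X[:, None, :] | X[None, :, :]).sum(-1)
        D = 1 - inter / union
        disp = multivariate_dispersion(D, ["a"] * 4 + ["b"] * 4)
        assert all(v >= 0 for v in disp.values())


class TestSpaceForTime:
    def _grid(self, ncols=8, nrows=6):
        x0, y0 = behrmann_project(-110.0, 30.0)
        return GridSpec(x0=float(x0), y0=float(y0), ncols=ncols, nrows=nrows, cell_km=100.0)

    def test_uniform_composition_is_one(self, rng):
        grid = self._grid()
        occ = np.ones((4, grid.n_cells), dtype=bool)
        vals = space_for_time_map(occ, grid, rng=rng)
        assert np.nanmin(vals) == 1.0

    def test_sharp_boundary_lowers_edge_cells(self, rng):
        grid = self._grid(ncols=10, nrows=2)
        occ = np.zeros((4, grid.n_cells), dtype=bool)
        col = np.arange(grid.n_cells) % grid.ncols
        occ[0:2, col < 5] = True  # west fauna
        occ[2:4, col >= 5] = True  # east fauna
        vals = space_for_time_map(occ, grid, window_km=250.0, rng=rng).ravel()
        interior = [v for c, v in zip(col, vals) if c in (0, 1, 8, 9) and np.isfinite(v)]
        boundary = [v for c, v in zip(col, vals) if c in (4, 5) and np.isfinite(v)]
        assert min(interior) == 1.0
        assert max(boundary) < 1.0

    def test_latitudinal_richness_gradient_raises_high_latitude_similarity(self, rng):
        grid = self._grid(ncols=6, nrows=9)
        row = np.arange(grid.n_cells) // grid.ncols
        occ = np.zeros((30, grid.n_cells), dtype=bool)
        gen = np.random.default_rng(0)
        for sp in range(30):
            # northern cells are occupied by broad-ranged species, southern by narrow endemics
            center = gen.integers(grid.n_cells)
            width = 1 + (row[center] >= 5) * 8
            r0, c0 = divmod(center, grid.ncols)
            rr, cc = divmod(np.arange(grid.n_cells), grid.ncols)
            occ[sp] = (np.abs(rr - r0) <= width) & (np.abs(cc - c0) <= width)
        vals = space_for_time_map(occ, grid, window_km=400.0, rng=rng)
        south = np.nanmean(vals[:3])
        north = np.nanmean(vals[6:])
        assert north > south
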