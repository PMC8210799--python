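"""Marine distances, Mantel tests and IBD regressions."""

import itertools

import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from seascape import seascape_ibd as ibd
from seascape import synth
from seascape.datatypes import DistanceMatrix, RasterGrid


class TestMarineDistance:
    def test_straight_corridor_close_to_great_circle(self):
        bathy = synth.synth_bathymetry("corridor", n_rows=10, n_cols=20,
                                       cell_size=0.5, xllcorner=0.0,
                                       yllcorner=-2.5)
        lat = 0.0  # corridor band straddles the equator
        pts = [("a", lat, 1.25), ("b", lat, 8.25)]
        d = ibd.marine_distance(bathy, pts)
        gc = ibd.great_circle_km(lat, 1.25, lat, 8.25)
        assert d.values[0, 1] == pytest.approx(gc, rel=0.05)

    def test_land_wall_forces_detour_or_infinity(self):
        wall = synth.synth_bathymetry("wall", n_rows=10, n_cols=20,
                                      cell_size=0.5, xllcorner=0.0,
                                      yllcorner=-2.5)
        pts = [("a", 0.0, 1.25), ("b", 0.0, 8.25)]
        d = ibd.marine_distance(wall, pts)
        assert np.isinf(d.values[0, 1])  # corridor fully blocked

    def test_deep_channel_excluded_by_depth_window(self):
        deep = synth.synth_bathymetry("deep_channel", n_rows=10, n_cols=20,
                                      cell_size=0.5, xllcorner=0.0,
                                      yllcorner=-2.5)
        pts = [("a", 0.0, 1.25), ("b", 0.0, 8.25)]
        d = ibd.marine_distance(deep, pts, depth_window=(-650, -10))
        assert np.isinf(d.values[0, 1])
        # widening the window to abyssal depth reconnects the basins
        d2 = ibd.marine_distance(deep, pts, depth_window=(-5000, -10))
        assert np.isfinite(d2.values[0, 1])

    def test_point_without_valid_cell_names_sample(self):
        bathy = synth.synth_bathymetry("corridor")
        with pytest.raises(ValueError, match="lost_sample"):
            ibd.marine_distance(bathy, [("lost_sample", -80.0, 100.0)],
                                snap_radius_km=50.0)

    def test_matches_floyd_warshall_on_toy_grid(self, rng):
        values = np.where(rng.random((20, 20)) < 0.7, -100.0, 10.0)
        bathy = RasterGrid(values, 0.5, 0.0, 0.0)
        graph = ibd.build_marine_graph(bathy)
        dense = graph.adjacency.toarray()
        dense[dense == 0] = np.inf
        np.fill_diagonal(dense, 0.0)
        fw = floyd_warshall(dense)
        nodes = [0, graph.n_nodes // 3, graph.n_nodes - 1]
        from scipy.sparse.csgraph import dijkstra

        dj = dijkstra(graph.adjacency.tocsr(), directed=False, indices=nodes)
        for a, node in enumerate(nodes):
            assert np.allclose(dj[a], fw[node], equal_nan=True)

    def test_marine_at_least_great_circle(self):
        bathy = synth.synth_bathymetry("corridor", n_rows=12, n_cols=30,
                                       cell_size=0.5, xllcorner=0.0,
                                       yllcorner=40.0)
        lat = 43.25
        pts = [(f"p{k}", lat, 2.0 + 3 * k) for k in range(4)]
        d = ibd.marine_distance(bathy, pts)
        for i, j in itertools.combinations(range(4), 2):
            gc = ibd.great_circle_km(pts[i][1], pts[i][2],
                                     pts[j][1], pts[j][2])
            assert d.values[i, j] >= gc - 1.0  # snap discretisation slack

    def test_triangle_inequality(self):
        bathy = synth.synth_bathymetry("corridor", n_rows=12, n_cols=30,
                                       cell_size=0.5, xllcorner=0.0,
                                       yllcorner=40.0)
        pts = [(f"p{k}", 43.25, 2.0 + 3 * k) for k in range(4)]
        d = ibd.marine_distance(bathy, pts).values
        for i, j, k in itertools.permutations(range(4), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-6


def labels(n):
    return [f"g{i}" for i in range(n)]


def random_dm(rng, n):
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(labels(n), v)


class TestMantel:
    def test_affine_identity_r_one_minimal_p(self, rng):
        a = random_dm(rng, 8)
        v = 2 * a.values + 3
        np.fill_diagonal(v, 0.0)
        b = DistanceMatrix(a.labels, v)
        res = ibd.mantel_test(a, b, n_perm=999, seed=0)
        assert res["r"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1 / 1000)

    def test_matches_exhaustive_enumeration_five_labels(self, rng):
        a = random_dm(rng, 5)
        b = random_dm(rng, 5)
        iu = np.triu_indices(5, 1)
        x = a.values[iu]
        obs = np.corrcoef(x, b.values[iu])[0, 1]
        count = 0
        total = 0
        for perm in itertools.permutations(range(5)):
            y = b.values[np.ix_(perm, perm)][iu]
            r = np.corrcoef(x, y)[0, 1]
            total += 1
            count += r >= obs - 1e-12
        exact_p = count / total
        res = ibd.mantel_test(a, b, n_perm=100_000, seed=3)
        # Monte-Carlo agreement with the exhaustive null (120 perms)
        assert res["p"] == pytest.approx(exact_p, abs=0.01)

    def test_affine_invariance_of_r(self, rng):
        a = random_dm(rng, 7)
        b = random_dm(rng, 7)
        r1 = ibd.mantel_test(a, b, n_perm=9, seed=0)["r"]
        v = 5 * b.values + 1
        np.fill_diagonal(v, 0.0)
        b2 = DistanceMatrix(b.labels, v)
        r2 = ibd.mantel_test(a, b2, n_perm=9, seed=0)["r"]
        assert r1 == pytest.approx(r2)

    def test_non_symmetric_rejected(self):
        v = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], v)


class TestIbdRegression:
    def test_exact_linear_input_recovers_slope(self, rng):
        n = 8
        km = random_dm(rng, n)
        km = DistanceMatrix(km.labels, km.values * 1000)
        slope = 1e-4
        f_over = slope * km.values
        fst = f_over / (1 + f_over)  # so that fst/(1-fst) is linear
        np.fill_diagonal(fst, 0.0)
        gen = DistanceMatrix(km.labels, fst, bounded=False)
        res = ibd.ibd_analysis(gen, km, n_perm=99, seed=1)
        assert res.slope == pytest.approx(slope, abs=1e-6)
        assert res.r_squared == pytest.approx(1.0)

    def test_transform_half_gives_one(self):
        assert ibd.linearised(np.array(0.5)) == pytest.approx(1.0)
        assert ibd.linearised(np.array(-0.3)) == 0.0

    def test_infinite_pairs_excluded(self, rng):
        km = random_dm(rng, 6)
        vals = km.values * 100
        vals[0, 5] = vals[5, 0] = np.inf
        geo = DistanceMatrix(km.labels, vals)
        gen = random_dm(rng, 6)
        gen = DistanceMatrix(gen.labels, gen.values * 0.1, bounded=False)
        res = ibd.ibd_analysis(gen, geo, n_perm=99, seed=1)
        assert res.n_pairs == 14

    def test_restricted_vs_panmictic_simulator_contrast(self):
        # restricted dispersal yields positive slope; near-panmictic
        # dispersal a slope near zero (single replicate each, seeded)
        from dataclasses import replace
        from scipy import stats as sps
        from seascape import popgen_nuclear as pn

        slopes = {}
        for tag, sigma in (("restricted", 0.5), ("panmictic", 8.0)):
            p = replace(synth.contrast_params(seed=5), sigma_f=sigma,
                        sigma_m=sigma, generations=400, deme_size=50,
                        sample_per_deme=20)
            res = synth.simulate_metapopulation(p)
            labs = res.metadata.group_labels(
                res.genotypes.individual_ids, "subgroup")
            fst, _ = pn.fst_matrix(res.genotypes, labs, min_size=5)
            lon = dict(zip(res.truth["deme_coords"]["subgroup"],
                           res.truth["deme_coords"]["lon"]))
            iu = np.triu_indices(fst.n, 1)
            x = np.array([abs(lon[fst.labels[i]] - lon[fst.labels[j]])
                          for i, j in zip(*iu)])
            y = ibd.linearised(fst.values[iu])
            slopes[tag] = sps.linregress(x, y).slope
        assert slopes["restricted"] > 0
        assert slopes["restricted"] > 5 * abs(slopes["panmictic"])

    def test_relatedness_declines_with_distance_sign_convention(self, rng):
        n = 7
        km = random_dm(rng, n)
        km = DistanceMatrix(km.labels, km.values * 1000)
        v = 0.2 - 1e-4 * km.values
        np.fill_diagonal(v, 0.0)
        rel = DistanceMatrix(km.labels, v, bounded=False)
        res = ibd.relatedness_vs_distance(rel, km, n_perm=999, seed=2)
        assert res.slope < 0
        assert res.p_value <= 0.05
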