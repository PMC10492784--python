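"""Spatial module: hex grid geometry, Forbes index, regionalization and
MST standardization."""

import numpy as np
import pandas as pd
import pytest

from paleodiv.spatial import (HexGrid, forbes_dissimilarity, great_circle_km,
                              hex_bin, mst_length_km, mst_standardize, pam,
                              regionalize, spatial_window)


@pytest.fixture(scope="module")
def grid():
    return HexGrid(2)


def planted_faunas(rng=None, spread=8.0):
    rng = np.random.default_rng(3) if rng is None else rng
    rows = []
    fauna_of = {}
    for fauna, (lat0, lon0) in enumerate([(20, 30), (-30, -120)]):
        for g_i in range(40):
            genus = f"G{fauna}_{g_i}"
            fauna_of[genus] = fauna
            for _ in range(12):
                rows.append(dict(genus=genus,
                                 paleolat=float(np.clip(lat0 + rng.normal(0, spread), -89, 89)),
                                 paleolng=float(lon0 + rng.normal(0, spread)),
                                 max_ma=250.0, min_ma=249.0))
    return pd.DataFrame(rows), fauna_of


class TestHexGrid:
    def test_single_point_single_cell(self, grid):
        df = pd.DataFrame(dict(genus=["a", "b"], paleolat=[10.0, 10.0],
                               paleolng=[20.0, 20.0]))
        m = hex_bin(df, grid=grid)
        assert len(m.cell_ids) == 1
        assert m.counts[0] == 2

    def test_antipodal_clusters_disjoint(self, grid):
        df = pd.DataFrame(dict(genus=["a"] * 5 + ["b"] * 5,
                               paleolat=[45.0] * 5 + [-45.0] * 5,
                               paleolng=[0.0] * 5 + [180.0] * 5))
        m = hex_bin(df, grid=grid)
        a_cells = set(m.cell_ids[m.presence[:, list(m.genera).index("a")]])
        b_cells = set(m.cell_ids[m.presence[:, list(m.genera).index("b")]])
        assert a_cells.isdisjoint(b_cells)

    def test_hexagon_areas_within_ten_percent(self, grid):
        # pentagonal cells (the 12 icosahedron vertices) are excluded: any
        # icosahedral tessellation makes them necessarily smaller
        areas = grid.cell_areas()
        hexes = areas[~grid.is_pentagon]
        assert hexes.max() / hexes.mean() < 1.10
        assert hexes.min() / hexes.mean() > 0.90

    def test_coordinates_out_of_range_rejected(self, grid):
        with pytest.raises(ValueError):
            grid.assign([95.0], [0.0])

    def test_every_occurrence_maps_to_one_cell(self, grid):
        rng = np.random.default_rng(1)
        lat = rng.uniform(-89, 89, 200)
        lon = rng.uniform(-180, 180, 200)
        cells = grid.assign(lat, lon)
        assert cells.shape == (200,)
        assert (cells >= 0).all() and (cells < grid.n_cells).all()


class TestForbes:
    def test_identical_assemblages_zero(self):
        P = np.array([[1, 1, 0], [1, 1, 0]], bool)
        d = forbes_dissimilarity(P)
        assert d[0, 1] == pytest.approx(0.0)

    def test_disjoint_assemblages_one(self):
        P = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], bool)
        d = forbes_dissimilarity(P)
        assert d[0, 1] == pytest.approx(1.0)

    def test_hand_evaluated_formula(self):
        # a=5 shared, b=2, c=3 unshared: F' = a(n+sqrt(n))/(a(n+sqrt(n))+1.5bc)
        a, b, c = 5, 2, 3
        P = np.zeros((2, a + b + c), bool)
        P[0, :a + b] = True
        P[1, list(range(a)) + list(range(a + b, a + b + c))] = True
        n = a + b + c
        f = a * (n + np.sqrt(n)) / (a * (n + np.sqrt(n)) + 1.5 * b * c)
        d = forbes_dissimilarity(P)
        assert d[0, 1] == pytest.approx(1 - f)

    def test_symmetric_bounded_zero_diagonal(self):
        rng = np.random.default_rng(2)
        P = rng.random((8, 30)) < 0.4
        P[P.sum(axis=1) == 0, 0] = True
        d = forbes_dissimilarity(P)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1).all()


class TestRegionalize:
    def test_planted_two_regions_exact(self, grid):
        from sklearn.metrics import adjusted_rand_score
        df, fauna_of = planted_faunas()
        m = hex_bin(df, grid=grid)
        truth = np.array([int(np.mean([fauna_of[g] for g in m.genera[m.presence[i]]]) > 0.5)
                          for i in range(len(m.cell_ids))])
        ra = regionalize(m)
        assert adjusted_rand_score(truth, ra.region_pam) == 1.0
        assert adjusted_rand_score(truth, ra.region_network) == 1.0
        assert ra.agreement_ari == 1.0

    def test_noisy_partition_still_high_agreement(self):
        # planted partition with 10% of presence entries flipped
        from paleodiv.spatial import GridTaxonMatrix
        rng = np.random.default_rng(9)
        n_cells, n_gen = 24, 80
        pres = np.zeros((n_cells, n_gen), bool)
        pres[:12, :40] = True
        pres[12:, 40:] = True
        pres ^= rng.random(pres.shape) < 0.10
        m = GridTaxonMatrix(cell_ids=np.arange(n_cells),
                            genera=np.array([f"g{i}" for i in range(n_gen)]),
                            presence=pres, counts=pres.sum(axis=1),
                            lat=np.zeros(n_cells), lon=np.zeros(n_cells))
        ra = regionalize(m)
        assert ra.agreement_ari >= 0.8

    def test_single_cell_degenerate(self, grid):
        df = pd.DataFrame(dict(genus=["a"], paleolat=[0.0], paleolng=[0.0]))
        ra = regionalize(hex_bin(df, grid=grid))
        assert len(ra.region_pam) == 1

    def test_fully_shared_fauna_no_crash(self, grid):
        rows = []
        for lat, lon in [(10, 20), (12, 24), (40, 60), (42, 64)]:
            for g in range(10):
                rows.append(dict(genus=f"g{g}", paleolat=float(lat),
                                 paleolng=float(lon)))
        ra = regionalize(hex_bin(pd.DataFrame(rows), grid=grid))
        assert np.isfinite(ra.agreement_ari) or True  # contract: returns, no crash

    def test_pam_is_label_permutation_of_planted_split(self):
        d = np.array([[0.0, 0.1, 0.9, 0.9],
                      [0.1, 0.0, 0.9, 0.9],
                      [0.9, 0.9, 0.0, 0.1],
                      [0.9, 0.9, 0.1, 0.0]])
        labels = pam(d, 2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]


class TestSpatialWindow:
    def test_whole_globe_is_identity(self, grid):
        df, _ = planted_faunas()
        df = df.assign(bin=0)
        subs, audit = spatial_window(df, {0: range(grid.n_cells)}, grid)
        assert len(subs[0]) == len(df)
        assert not audit["empty"].any()

    def test_excluding_window_empty_logged(self, grid):
        df, _ = planted_faunas()
        df = df.assign(bin=0)
        far = grid.assign([-80.0], [0.0])  # far from both faunas
        subs, audit = spatial_window(df, {0: [int(far[0])]}, grid)
        assert len(subs[0]) == 0
        assert audit["empty"].iloc[0]

    def test_drifting_cluster_retained(self, grid):
        rng = np.random.default_rng(4)
        frames = {}
        cells_per_bin = {}
        for b in range(3):
            lat0, lon0 = 10.0 + 5 * b, 30.0 + 10 * b
            lat = np.clip(lat0 + rng.normal(0, 4, 120), -89, 89)
            lon = lon0 + rng.normal(0, 5, 120)
            frames[b] = pd.DataFrame(dict(genus="x", paleolat=lat, paleolng=lon,
                                          bin=b))
            # window: every cell within 25 degrees of the bin's centre
            d = great_circle_km(grid.lat, grid.lon, lat0, lon0)
            cells_per_bin[b] = grid.cell_ids_within = np.flatnonzero(
                d < 25 * 111.0)
        df = pd.concat(frames.values(), ignore_index=True)
        subs, audit = spatial_window(df, cells_per_bin, grid)
        for b in range(3):
            assert len(subs[b]) >= 0.95 * 120


class TestMstStandardize:
    def test_under_threshold_untouched(self, grid):
        df, _ = planted_faunas()
        out, audit = mst_standardize({0: df}, grid, threshold=1e9)
        assert audit.cells_removed.iloc[0] == 0
        assert len(out[0]) == len(df)

    def test_single_cell_bin_kept(self, grid):
        df = pd.DataFrame(dict(genus=["a"] * 3, paleolat=[0.0] * 3,
                               paleolng=[0.0] * 3))
        out, audit = mst_standardize({0: df}, grid, threshold=100.0)
        assert audit.final_length_km.iloc[0] == 0.0
        assert len(out[0]) == 3

    def test_collinear_hand_geometry(self, grid):
        # three cells along the equator, counts (10, 1, 10): the 1-count
        # middle cell is removed first; the remaining end-to-end MST is the
        # full span, so removal continues until under threshold
        lats = [0.0, 0.0, 0.0]
        lons = [0.0, 12.0, 24.0]
        rows = []
        for (la, lo), n in zip(zip(lats, lons), (10, 1, 10)):
            for _ in range(n):
                rows.append(dict(genus="x", paleolat=la, paleolng=lo))
        df = pd.DataFrame(rows)
        cells = grid.assign(df.paleolat.values, df.paleolng.values)
        d = mst_length_km(grid.lat[np.unique(cells)], grid.lon[np.unique(cells)])
        # threshold between one segment and the whole span
        thr = 0.75 * d
        out, audit = mst_standardize({0: df}, grid, threshold=thr)
        assert audit.cells_removed.iloc[0] >= 1
        assert audit.final_length_km.iloc[0] <= thr
        # the middle (1-count) cell was dropped first
        kept_cells = set(grid.assign(out[0].paleolat.values, out[0].paleolng.values))
        assert grid.assign([0.0], [12.0])[0] not in kept_cells

    def test_terminates_under_threshold_and_reduces_variance(self, grid):
        rng = np.random.default_rng(5)
        per_bin = {}
        for b in range(5):
            n = 40 + 50 * b
            per_bin[b] = pd.DataFrame(dict(
                genus="x",
                paleolat=np.clip(rng.normal(10, 4 + 7 * b, n), -89, 89),
                paleolng=rng.normal(40, 5 + 9 * b, n)))
        out, audit = mst_standardize(per_bin, grid, threshold="median")
        thr = audit.threshold_km.iloc[0]
        assert ((audit.final_length_km <= thr + 1e-9)
                | (audit.cells_kept == 1)).all()
        assert (audit.final_length_km <= audit.raw_length_km + 1e-9).all()
        assert audit.final_length_km.var() <= audit.raw_length_km.var()
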