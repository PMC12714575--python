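import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from isozone.ecozones import (
    CWB_LEVELS,
    DEM_LEVELS,
    TMP_LEVELS,
    EcozoneRaster,
    assign_sites,
    fit_ecozones,
    label_clusters,
    ordinal_rank_groups,
    rasterize_labels,
    summarize_clusters,
)
from isozone.env_stack import CentroidSample, EnvLayer, EnvStack, lonlat_to_mercator
from isozone.reference import published_cluster_summary

from conftest import make_table


def sample_from(values, spacing=1000.0):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return CentroidSample(
        x=np.arange(n, dtype=float) * spacing,
        y=np.zeros(n),
        values=values,
        spacing=spacing,
    )


def two_blob_sample(rng=None, n=20, with_na=True):
    rng = rng or np.random.default_rng(0)
    a = rng.normal([-3, -3, -3], 0.1, size=(n, 3))
    b = rng.normal([3, 3, 3], 0.1, size=(n, 3))
    vals = np.vstack([a, b])
    planted = np.array([0] * n + [1] * n)
    if with_na:
        vals = np.vstack([vals, [[np.nan, np.nan, np.nan]] * 3])
        planted = np.concatenate([planted, [-1] * 3])
    return sample_from(vals), planted


class TestFit:
    def test_two_separated_blobs_recovered_exactly(self):
        sample, planted = two_blob_sample()
        model = fit_ecozones(sample, k=3, seed=0, n_init=5)
        labels = model.predict(sample.values)
        real = planted >= 0
        assert adjusted_rand_score(planted[real], labels[real]) == 1.0
        assert (labels[~real] == model.na_cluster_id).all()

    def test_k2_no_na_gives_single_label(self):
        sample, _ = two_blob_sample(with_na=False)
        model = fit_ecozones(sample, k=2, seed=0, n_init=2)
        labels = model.predict(sample.values)
        assert set(labels) == {1}

    def test_determinism_same_seed_identical_labels(self):
        sample, _ = two_blob_sample()
        m1 = fit_ecozones(sample, k=3, seed=11, n_init=4)
        m2 = fit_ecozones(sample, k=3, seed=11, n_init=4)
        assert np.array_equal(m1.centers, m2.centers)
        assert np.array_equal(m1.predict(sample.values), m2.predict(sample.values))

    def test_canonical_ids_ascend_in_mean_temperature(self):
        sample, _ = two_blob_sample()
        model = fit_ecozones(sample, k=3, seed=0, n_init=4)
        assert model.centers[0, 1] < model.centers[1, 1]  # column 1 = temperature

    def test_too_few_distinct_points_raises(self):
        sample = sample_from(np.zeros((5, 3)))
        with pytest.raises(ValueError, match="distinct"):
            fit_ecozones(sample, k=3, seed=0, n_init=1)

    def test_returned_model_beats_single_random_restart(self):
        rng = np.random.default_rng(5)
        sample = sample_from(rng.normal(size=(60, 3)))
        best = fit_ecozones(sample, k=5, seed=0, n_init=20)
        single = fit_ecozones(sample, k=5, seed=123, n_init=1)
        assert best.inertia <= single.inertia + 1e-9


class TestRasterize:
    def make_stack(self, data3):
        layers = [
            EnvLayer(kind=k, data=np.asarray(d, dtype=float), xmin=0.0,
                     ymax=np.asarray(d).shape[0] * 1000.0, dx=1000.0, dy=1000.0)
            for d, k in zip(data3, ("elevation", "temperature", "cmi"))
        ]
        return EnvStack(*layers)

    def test_cell_equal_to_centre_gets_that_cluster(self):
        sample, _ = two_blob_sample()
        model = fit_ecozones(sample, k=3, seed=0, n_init=3)
        c0 = model.centers[0]
        stack = self.make_stack([np.full((2, 2), c0[0]), np.full((2, 2), c0[1]),
                                 np.full((2, 2), c0[2])])
        ez = rasterize_labels(model, stack)
        assert (ez.grid == 1).all()

    def test_equidistant_cell_breaks_tie_to_lowest_id(self):
        sample, _ = two_blob_sample()
        model = fit_ecozones(sample, k=3, seed=0, n_init=3)
        mid = model.centers.mean(axis=0)
        stack = self.make_stack([np.full((1, 1), mid[0]), np.full((1, 1), mid[1]),
                                 np.full((1, 1), mid[2])])
        ez = rasterize_labels(model, stack)
        assert ez.grid[0, 0] == 1

    def test_matches_brute_force_nearest_centre_oracle(self):
        rng = np.random.default_rng(9)
        sample = sample_from(rng.normal(size=(80, 3)))
        model = fit_ecozones(sample, k=5, seed=1, n_init=5)
        data3 = rng.normal(size=(3, 6, 7))
        data3[0, 0, 0] = np.nan  # one NA cell
        stack = self.make_stack(list(data3))
        ez = rasterize_labels(model, stack)
        for i in range(6):
            for j in range(7):
                v = np.array([data3[0, i, j], data3[1, i, j], data3[2, i, j]])
                if not np.all(np.isfinite(v)):
                    assert ez.grid[i, j] == model.na_cluster_id
                else:
                    d2 = ((model.centers - v) ** 2).sum(axis=1)
                    assert ez.grid[i, j] == int(np.argmin(d2)) + 1

    def test_labels_partition_valid_cells(self):
        rng = np.random.default_rng(10)
        data3 = rng.normal(size=(3, 8, 8))
        data3[:, :2, :2] = np.nan
        stack = self.make_stack(list(data3))
        sample = sample_from(rng.normal(size=(50, 3)))
        model = fit_ecozones(sample, k=4, seed=2, n_init=4)
        ez = rasterize_labels(model, stack)
        na_cells = ez.grid == model.na_cluster_id
        assert np.array_equal(na_cells, ~stack.valid_mask)
        assert set(np.unique(ez.grid[~na_cells])) <= set(range(1, model.k))


class TestSummaries:
    def test_rescaled_means_hit_zero_and_one(self):
        sample, _ = two_blob_sample()
        model = fit_ecozones(sample, k=3, seed=0, n_init=3)
        df = summarize_clusters(model, sample)
        real = df[df["cluster_id"] != model.na_cluster_id]
        for var in ("tmp", "cwb", "dem"):
            assert real[f"mean_{var}"].min() == pytest.approx(0.0)
            assert real[f"mean_{var}"].max() == pytest.approx(1.0)

    def test_rescaling_matches_direct_formula(self):
        rng = np.random.default_rng(12)
        sample = sample_from(rng.normal(size=(120, 3)))
        model = fit_ecozones(sample, k=6, seed=3, n_init=5)
        labels = model.predict(sample.values)
        df = summarize_clusters(model, sample)
        raw_means = np.array([
            sample.values[labels == cid, 1].mean() for cid in range(1, model.k)
        ])
        expected = (raw_means - raw_means.min()) / (raw_means.max() - raw_means.min())
        real = df[df["cluster_id"] != model.na_cluster_id]
        assert np.allclose(real["mean_tmp"].to_numpy(), expected, atol=1e-12)

    def test_single_real_cluster_rescaling_degenerate(self):
        sample, _ = two_blob_sample(with_na=False)
        model = fit_ecozones(sample, k=2, seed=0, n_init=2)
        with pytest.raises(ValueError, match="rescale|2 populated"):
            summarize_clusters(model, sample)


class TestLabels:
    def test_labels_monotone_in_rescaled_means(self):
        rng = np.random.default_rng(13)
        sample = sample_from(rng.normal(size=(300, 3)))
        model = fit_ecozones(sample, k=10, seed=4, n_init=5)
        df = label_clusters(summarize_clusters(model, sample))
        real = df[df["cluster_id"] != model.na_cluster_id]
        for var, vocab in (("tmp", TMP_LEVELS), ("cwb", CWB_LEVELS), ("dem", DEM_LEVELS)):
            pos = {"tmp": 0, "cwb": 1, "dem": 2}[var]
            rank = real["description"].str.split("|").str[pos].map(vocab.index)
            order = real[f"mean_{var}"].argsort()
            assert rank.to_numpy()[order].tolist() == sorted(rank)

    def test_extreme_clusters_get_extreme_labels_on_published_means(self):
        """Regression on the published 20-cluster summary table."""
        pub = published_cluster_summary()
        real = pub[pub["mean_tmp"].notna()].copy()
        df = real.rename(columns={"cluster": "cluster_id"})
        df["n_cells"] = 100
        labelled = label_clusters(df)
        for var, vocab in (("tmp", TMP_LEVELS), ("cwb", CWB_LEVELS), ("dem", DEM_LEVELS)):
            pos = {"tmp": 0, "cwb": 1, "dem": 2}[var]
            got = labelled["description"].str.split("|").str[pos]
            means = labelled[f"mean_{var}"]
            assert got[means.idxmin()] == vocab[0]
            assert got[means.idxmax()] == vocab[-1]
            # monotone non-decreasing in the published rescaled means
            rank = got.map(vocab.index).to_numpy()
            assert (np.diff(rank[means.argsort()]) >= 0).all()

    def test_published_descriptions_are_monotone_in_published_means(self):
        """The printed descriptor table itself satisfies the monotonicity invariant."""
        pub = published_cluster_summary().dropna(subset=["mean_tmp"])
        for var, vocab in (("tmp", TMP_LEVELS), ("cwb", CWB_LEVELS), ("dem", DEM_LEVELS)):
            pos = {"tmp": 0, "cwb": 1, "dem": 2}[var]
            rank = pub["description"].str.split("|").str[pos].map(vocab.index).to_numpy()
            means = pub[f"mean_{var}"].to_numpy()
            assert (np.diff(rank[np.argsort(means)]) >= 0).all()

    def test_fewer_than_seven_clusters_coarser_with_warning(self):
        df = pd.DataFrame(
            dict(cluster_id=[1, 2, 3], n_cells=[5, 5, 5],
                 mean_tmp=[0.0, 0.5, 1.0], mean_cwb=[1.0, 0.0, 0.5],
                 mean_dem=[0.2, 0.9, 0.0], sd_tmp=0.1, sd_cwb=0.1, sd_dem=0.1)
        )
        with pytest.warns(UserWarning, match="coarser"):
            out = label_clusters(df)
        tmp_levels = out["description"].str.split("|").str[0]
        assert tmp_levels[0] == TMP_LEVELS[0] and tmp_levels[2] == TMP_LEVELS[-1]

    def test_rank_groups_sizes_differ_by_at_most_one(self):
        groups = ordinal_rank_groups(np.arange(19.0), 7)
        sizes = np.bincount(groups)
        assert sizes.sum() == 19 and sizes.max() - sizes.min() <= 1
        assert (np.diff(groups[np.argsort(np.arange(19.0))]) >= 0).all()


class TestAssignSites:
    def make_raster(self, grid, na_id=4, cell=1000.0, xmin=None, ymax=None):
        grid = np.asarray(grid, dtype=int)
        return EcozoneRaster(
            grid=grid,
            xmin=0.0 if xmin is None else xmin,
            ymax=grid.shape[0] * cell if ymax is None else ymax,
            dx=cell,
            dy=cell,
            crs="EPSG:3857",
            na_cluster_id=na_id,
        )

    def geo_raster_for(self, lon, lat, grid, na_id=4):
        """Raster whose extent covers the mercator image of (lon, lat)."""
        x, y = lonlat_to_mercator(lon, lat)
        g = np.asarray(grid, dtype=int)
        cell = 1000.0
        return self.make_raster(g, na_id=na_id, cell=cell,
                                xmin=float(x) - cell * 1.5,
                                ymax=float(y) + cell * 1.5)

    def test_site_in_labelled_cell(self):
        t = make_table([("A", "Greece", 22.0, 38.0, "Triticum", "C3", -23.0)])
        ez = self.geo_raster_for(22.0, 38.0, np.full((3, 3), 5), na_id=9)
        out = assign_sites(t, ez)
        assert (out["ecozone"] == 5).all()

    def test_na_cell_falls_back_to_nearest_valid_neighbour(self):
        t = make_table([("A", "Greece", 22.0, 38.0, "Triticum", "C3", -23.0)])
        grid = np.full((3, 3), 9)
        grid[0, 0] = 2  # the only valid cell
        ez = self.geo_raster_for(22.0, 38.0, grid, na_id=9)
        out = assign_sites(t, ez, fallback_radius=5000.0)
        assert (out["ecozone"] == 2).all()

    def test_na_cell_without_neighbour_left_unassigned(self):
        t = make_table([("A", "Greece", 22.0, 38.0, "Triticum", "C3", -23.0)])
        grid = np.full((3, 3), 9)
        grid[0, 0] = 2
        ez = self.geo_raster_for(22.0, 38.0, grid, na_id=9)
        with pytest.warns(UserWarning, match="unassigned"):
            out = assign_sites(t, ez, fallback_radius=100.0)
        assert out["ecozone"].isna().all()

    def test_outside_extent_raises(self):
        t = make_table([("A", "Greece", 22.0, 38.0, "Triticum", "C3", -23.0)])
        ez = self.make_raster(np.full((3, 3), 1), na_id=9)  # grid near origin
        with pytest.raises(ValueError, match="outside"):
            assign_sites(t, ez)

    def test_assignment_matches_point_in_cell_oracle(self):
        rng = np.random.default_rng(21)
        lons = rng.uniform(10, 11, 8)
        lats = rng.uniform(45, 45.5, 8)
        t = make_table([
            (f"S{i}", "Italy", float(lo), float(la), "Triticum", "C3", -23.0)
            for i, (lo, la) in enumerate(zip(lons, lats))
        ])
        x, y = lonlat_to_mercator(lons, lats)
        cell = 5000.0
        xmin, ymax = x.min() - cell, y.max() + cell
        grid = rng.integers(1, 4, size=(30, 30))
        ez = self.make_raster(grid, na_id=5, cell=cell, xmin=xmin, ymax=ymax)
        out = assign_sites(t, ez)
        for xi, yi, got in zip(x, y, out["ecozone"]):
            r = int(np.floor((ymax - yi) / cell))
            c = int(np.floor((xi - xmin) / cell))
            assert got == grid[r, c]
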