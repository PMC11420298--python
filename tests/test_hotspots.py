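"""Fishnet aggregation and Gi* hot/cold-spot statistics: geometric
contracts, brute-force formula equivalence, null calibration, and seeded
hotspot recovery on synthetic scenarios."""

import math

import numpy as np
import pandas as pd
import pytest

from airmob.aggregate import rolling_median_8s
from airmob.hotspots import (
    FishnetGrid,
    HotspotConfig,
    LocalProjection,
    build_fishnet,
    classify_bins,
    gi_star,
    hotspot_pipeline,
    to_geojson,
)
from airmob.synthetic import (
    BackgroundModel,
    PlumeModel,
    ScenarioConfig,
    default_route,
    generate_scenario,
)


def brute_force_gi_star(xs, ys, values, band):
    """Direct from-the-formula evaluation (independent of the implementation)."""
    n = len(values)
    xbar = float(np.mean(values))
    s = math.sqrt(float(np.mean((np.asarray(values) - xbar) ** 2)))
    zs = []
    for i in range(n):
        w = [1.0 if (xs[i] - xs[j]) ** 2 + (ys[i] - ys[j]) ** 2 <= band**2 else 0.0
             for j in range(n)]
        big_w = sum(w)
        w2 = sum(wi * wi for wi in w)
        num = sum(wi * v for wi, v in zip(w, values)) - xbar * big_w
        den = s * math.sqrt((n * w2 - big_w**2) / (n - 1))
        zs.append(num / den if den > 0 else 0.0)
    return np.array(zs)


def grid_cells(values, n_rows, n_cols, cell=100.0):
    grid = FishnetGrid(LocalProjection(53.35, -6.26), 0.0, 0.0, cell, n_rows, n_cols)
    cells = pd.DataFrame({"cell": np.arange(n_rows * n_cols), "count": 10,
                          "value": np.asarray(values, dtype=float)})
    cells["row"], cells["col"] = divmod(cells["cell"], n_cols)
    cells["analyzed"] = True
    return grid, cells


class TestFishnet:
    def test_identical_points_share_one_cell(self):
        pts = pd.DataFrame({"lat": [53.35] * 5, "lon": [-6.26] * 5, "NO2": [8.0] * 5})
        _, cells = build_fishnet(pts, 100.0, min_count=1, value_column="NO2")
        assert len(cells) == 1
        assert cells["count"].iloc[0] == 5
        assert cells["value"].iloc[0] == 8.0

    def test_separated_points_get_distinct_cells(self):
        dlon = 150.0 / (111_195.0 * math.cos(math.radians(53.35)))
        pts = pd.DataFrame({"lat": [53.35, 53.35], "lon": [-6.26, -6.26 + dlon],
                            "NO2": [1.0, 2.0]})
        _, cells = build_fishnet(pts, 100.0, min_count=1, value_column="NO2")
        assert len(cells) == 2

    def test_min_count_excludes_but_retains(self):
        pts = pd.DataFrame({"lat": [53.35] * 5 + [53.36],
                            "lon": [-6.26] * 5 + [-6.26],
                            "NO2": [8.0] * 5 + [99.0]})
        _, cells = build_fishnet(pts, 100.0, min_count=5, value_column="NO2")
        sparse = cells.loc[~cells["analyzed"]]
        assert len(sparse) == 1
        assert sparse["count"].iloc[0] == 1
        assert np.isnan(sparse["value"].iloc[0])

    def test_uniform_points_give_multinomial_counts(self):
        rng = np.random.default_rng(5)
        n, cells_per_side = 10_000, 10
        proj = LocalProjection(53.35, -6.26)
        grid = FishnetGrid(proj, 0.0, 0.0, 100.0, cells_per_side, cells_per_side)
        x = rng.uniform(0, 1000.0, n)
        y = rng.uniform(0, 1000.0, n)
        lat, lon = proj.inverse(x, y)
        pts = pd.DataFrame({"lat": lat, "lon": lon, "NO2": 1.0})
        _, cells = build_fishnet(pts, 100.0, min_count=1, value_column="NO2", grid=grid)
        assert len(cells) == cells_per_side**2
        expected = n / cells_per_side**2
        sigma = math.sqrt(n * (1 / 100) * (99 / 100))
        assert cells["count"].between(expected - 3 * sigma, expected + 3 * sigma).mean() > 0.97

    def test_nonpositive_cell_size_rejected(self):
        pts = pd.DataFrame({"lat": [53.35], "lon": [-6.26], "NO2": [1.0]})
        with pytest.raises(ValueError):
            build_fishnet(pts, 0.0)


class TestGiStar:
    def test_degenerate_equal_values(self):
        grid, cells = grid_cells([4.0] * 12, 3, 4)
        res = gi_star(cells, grid)
        assert (res["gi_z"] == 0.0).all()
        assert (res["p_value"] == 1.0).all()
        assert res["degenerate"].all()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        n_rows, n_cols = rng.integers(4, 6, 2)
        values = rng.lognormal(2, 0.8, n_rows * n_cols)
        grid, cells = grid_cells(values, int(n_rows), int(n_cols))
        res = gi_star(cells, grid)
        cx, cy = grid.cell_center(np.arange(n_rows * n_cols))
        expected = brute_force_gi_star(np.asarray(cx), np.asarray(cy), values, 150.0)
        np.testing.assert_allclose(res["gi_z"].to_numpy(), expected, rtol=1e-10)

    def test_affine_invariance_and_antisymmetry(self):
        rng = np.random.default_rng(3)
        values = rng.normal(10, 2, 25)
        grid, cells = grid_cells(values, 5, 5)
        z = gi_star(cells, grid)["gi_z"].to_numpy()
        _, cells_affine = grid_cells(7.0 * values + 3.0, 5, 5)
        np.testing.assert_allclose(gi_star(cells_affine, grid)["gi_z"], z, atol=1e-10)
        _, cells_neg = grid_cells(2 * values.mean() - values, 5, 5)
        np.testing.assert_allclose(gi_star(cells_neg, grid)["gi_z"], -z, atol=1e-10)

    def test_null_tail_rate_matches_normal_approximation(self):
        # iid values on a 10x10 grid: empirical P(|z| > 1.96) ~ 0.05.
        rng = np.random.default_rng(11)
        n_grids, n = 40, 100
        exceed = []
        for _ in range(n_grids):
            grid, cells = grid_cells(rng.normal(0, 1, n), 10, 10)
            z = gi_star(cells, grid)["gi_z"].to_numpy()
            exceed.append(np.abs(z) > 1.96)
        rate = np.concatenate(exceed).mean()
        total = n_grids * n
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / total)


class TestClassifyBins:
    def test_bh_adjustment_matches_stepup_oracle(self):
        grid, cells = grid_cells(np.arange(4.0), 2, 2)
        res = gi_star(cells, grid)
        res["p_value"] = [0.001, 0.01, 0.02, 0.5]
        out = classify_bins(res)
        # hand step-up: 0.001*4/1, 0.01*4/2, 0.02*4/3, 0.5*4/4, cummin from below
        np.testing.assert_allclose(
            out["p_adjusted"].to_numpy(), [0.004, 0.02, 0.02 * 4 / 3, 0.5], rtol=1e-12
        )

    def test_bin_categories(self):
        grid, cells = grid_cells(np.arange(4.0), 2, 2)
        res = gi_star(cells, grid)
        res["gi_z"] = [3.5, -3.0, 1.8, 0.1]
        res["p_value"] = [0.004, 0.004, 0.08, 0.9]
        out = classify_bins(res, correction="none")
        assert out["gi_bin"].tolist() == [3, -3, 1, 0]
        assert out["label"].tolist() == ["99% hot", "99% cold", "90% hot", "not significant"]

    def test_all_insignificant(self):
        grid, cells = grid_cells([1.0, 2.0, 3.0, 4.0], 2, 2)
        res = gi_star(cells, grid)
        res["p_value"] = 1.0
        out = classify_bins(res)
        assert (out["gi_bin"] == 0).all()


class TestHotspotPipeline:
    @staticmethod
    def scenario(seed, hotspot_cells=frozenset(), multiplier=1.0, n_days=1):
        cfg = ScenarioConfig(seed=seed, n_days=n_days, pollutants=("NO2",))
        obs, truth = generate_scenario(
            default_route(),
            BackgroundModel(14.0, ar1_coefficient=0.99, noise_sd=0.05),
            PlumeModel(60.0, 2.2, 0.5, decay_seconds=15.0,
                       hotspot_cells=hotspot_cells, hotspot_rate_multiplier=multiplier),
            cfg,
        )
        return rolling_median_8s(obs), truth

    def test_seeded_hotspot_block_flagged(self):
        hot = frozenset({44, 45, 54, 55})
        seg, truth = self.scenario(0, hot, 3.0, n_days=2)
        result = hotspot_pipeline(
            seg, sorted(set(seg.index.date)), "NO2", HotspotConfig(grid=truth.grid)
        )
        cells = result["pooled"]["cells"].set_index("cell")
        assert (cells.loc[sorted(hot), "gi_bin"] >= 2).all()

    def test_per_day_and_pooled_layers(self):
        seg, truth = self.scenario(1, n_days=2)
        days = sorted(set(seg.index.date))
        result = hotspot_pipeline(
            seg, days, "NO2", HotspotConfig(grid=truth.grid), per_day=True
        )
        assert len(result["per_day"]) == 2
        assert "pooled" in result

    def test_empty_day_subset_rejected(self):
        seg, truth = self.scenario(2)
        with pytest.raises(ValueError, match="no polluted days"):
            hotspot_pipeline(seg, [], "NO2", HotspotConfig(grid=truth.grid))

    def test_geojson_layer_structure(self):
        seg, truth = self.scenario(3)
        result = hotspot_pipeline(
            seg, sorted(set(seg.index.date)), "NO2", HotspotConfig(grid=truth.grid)
        )
        layer = result["pooled"]["geojson"]
        assert layer["type"] == "FeatureCollection"
        feature = layer["features"][0]
        assert feature["geometry"]["type"] == "Polygon"
        for key in ("count", "value", "gi_z", "p_adjusted", "gi_bin", "label"):
            assert key in feature["properties"]
        # polygon ring closes and sits near the route
        ring = feature["geometry"]["coordinates"][0]
        assert ring[0] == ring[-1]
        assert abs(ring[0][1] - 53.35) < 0.1
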