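"""Fishnet aggregation and Getis-Ord Gi* hot/cold-spot classification.

Point measurements (WGS84) are projected onto a locally centred tangent
plane, binned into a regular metric grid ("fishnet"), and each cell's mean
concentration is tested for local spatial clustering with the self-inclusive
Getis-Ord Gi* statistic:

    Gi* = (sum_j w_ij x_j - xbar W_i) / (S * sqrt[(n sum_j w_ij^2 - W_i^2)/(n-1)])

with w_ii = 1, W_i = sum_j w_ij, and xbar, S the global mean and population
standard deviation over the n analysed cells. Large positive z marks a hot
spot (cluster of high values), large negative a cold spot. p-values are
two-sided normal and Benjamini-Hochberg adjusted across cells before binning
into the conventional 90/95/99% confidence categories.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import box, mapping
from statsmodels.stats.multitest import multipletests

EARTH_RADIUS_M = 6_371_000.0

BIN_LABELS = {
    3: "99% hot",
    2: "95% hot",
    1: "90% hot",
    0: "not significant",
    -1: "90% cold",
    -2: "95% cold",
    -3: "99% cold",
}


@dataclass(frozen=True)
class LocalProjection:
    """Equirectangular tangent-plane projection centred on (lat0, lon0).

    x = R * (lon - lon0) * cos(lat0), y = R * (lat - lat0), in metres.
    Distortion is negligible at the city scales a fishnet covers.
    """

    lat0: float
    lon0: float

    def forward(self, lat, lon) -> tuple[np.ndarray, np.ndarray]:
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        coslat0 = math.cos(math.radians(self.lat0))
        x = EARTH_RADIUS_M * np.radians(lon - self.lon0) * coslat0
        y = EARTH_RADIUS_M * np.radians(lat - self.lat0)
        return x, y

    def inverse(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        coslat0 = math.cos(math.radians(self.lat0))
        lon = self.lon0 + np.degrees(x / (EARTH_RADIUS_M * coslat0))
        lat = self.lat0 + np.degrees(y / EARTH_RADIUS_M)
        return lat, lon


@dataclass(frozen=True)
class FishnetGrid:
    """Regular rectangular tessellation in the projected plane.

    Cells are indexed row-major (index = row * n_cols + col); each cell is
    the half-open square [x0 + col*s, x0 + (col+1)*s) x [y0 + row*s, ...).
    """

    projection: LocalProjection
    origin_x: float
    origin_y: float
    cell_size_m: float
    n_rows: int
    n_cols: int

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_index(self, x, y) -> np.ndarray:
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size_m).astype(int)
        row = np.floor((np.asarray(y) - self.origin_y) / self.cell_size_m).astype(int)
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row * self.n_cols + col

    def cell_index_for_latlon(self, lat, lon) -> np.ndarray:
        x, y = self.projection.forward(lat, lon)
        return self.cell_index(x, y)

    def cell_center(self, index: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        index = np.asarray(index)
        row, col = divmod(index, self.n_cols)
        cx = self.origin_x + (col + 0.5) * self.cell_size_m
        cy = self.origin_y + (row + 0.5) * self.cell_size_m
        return cx, cy

    def cell_polygon(self, index: int):
        row, col = divmod(int(index), self.n_cols)
        x0 = self.origin_x + col * self.cell_size_m
        y0 = self.origin_y + row * self.cell_size_m
        return box(x0, y0, x0 + self.cell_size_m, y0 + self.cell_size_m)


def build_fishnet(
    points: pd.DataFrame,
    cell_size_m: float = 100.0,
    min_count: int = 5,
    value_column: str | None = None,
    grid: FishnetGrid | None = None,
) -> tuple[FishnetGrid, pd.DataFrame]:
    """Bin points into a fishnet and aggregate their concentration values.

    Parameters
    ----------
    points
        DataFrame with ``lat``, ``lon`` and a concentration column.
    cell_size_m
        Side of the square cells, metres.
    min_count
        Cells with fewer points keep their count but get a NaN analysis
        value and are excluded from the Gi* computation.
    value_column
        Concentration column to aggregate (cell value = mean). If None,
        only counts are produced.
    grid
        Reuse an existing grid (e.g. the synthetic truth grid) instead of
        fitting one to the point cloud's bounding box.

    Returns
    -------
    (grid, cells) where ``cells`` has one row per non-empty cell:
    ``cell``, ``row``, ``col``, ``count``, ``value``, ``analyzed``.
    """
    if cell_size_m <= 0:
        raise ValueError("cell_size_m must be positive")
    if points.empty:
        raise ValueError("no points to grid")

    if grid is None:
        lat0 = float(points["lat"].mean())
        lon0 = float(points["lon"].mean())
        proj = LocalProjection(lat0, lon0)
        x, y = proj.forward(points["lat"].to_numpy(), points["lon"].to_numpy())
        # Snap the origin to the cell lattice so cells are stable under
        # point-order permutation; pad the max edge so it falls inside.
        x0 = math.floor(x.min() / cell_size_m) * cell_size_m
        y0 = math.floor(y.min() / cell_size_m) * cell_size_m
        n_cols = max(1, int(math.floor((x.max() - x0) / cell_size_m)) + 1)
        n_rows = max(1, int(math.floor((y.max() - y0) / cell_size_m)) + 1)
        grid = FishnetGrid(proj, x0, y0, cell_size_m, n_rows, n_cols)
    else:
        x, y = grid.projection.forward(
            points["lat"].to_numpy(), points["lon"].to_numpy()
        )

    idx = grid.cell_index(x, y)
    df = pd.DataFrame({"cell": idx})
    if value_column is not None:
        df["value"] = points[value_column].to_numpy()
        agg = df.groupby("cell")["value"].agg(["count", "mean"])
        cells = agg.rename(columns={"mean": "value"}).reset_index()
    else:
        cells = df.groupby("cell").size().rename("count").reset_index()
        cells["value"] = np.nan
    cells["row"], cells["col"] = divmod(cells["cell"], grid.n_cols)
    cells["analyzed"] = (cells["count"] >= min_count) & cells["value"].notna()
    cells.loc[~cells["analyzed"], "value"] = np.nan
    return grid, cells


def _distance_band_weights(
    centers_x: np.ndarray, centers_y: np.ndarray, band_m: float
) -> np.ndarray:
    """Binary self-inclusive distance-band weight matrix (n x n)."""
    dx = centers_x[:, None] - centers_x[None, :]
    dy = centers_y[:, None] - centers_y[None, :]
    return (dx * dx + dy * dy <= band_m * band_m).astype(float)


def gi_star(
    cells: pd.DataFrame,
    grid: FishnetGrid,
    band_distance_m: float | None = None,
) -> pd.DataFrame:
    """Compute the Gi* z-score and two-sided normal p per analysed cell.

    Neighbourhood: binary distance band on cell centres, self-inclusive;
    default band = 1.5 * cell size (rook + corner neighbours). Degenerate
    input (all values equal) yields z = 0, p = 1, flagged ``degenerate``.
    """
    analyzed = cells.loc[cells["analyzed"]].reset_index(drop=True)
    n = len(analyzed)
    if n < 3:
        raise ValueError("need at least 3 analysed cells for Gi*")
    if band_distance_m is None:
        band_distance_m = 1.5 * grid.cell_size_m

    cx, cy = grid.cell_center(analyzed["cell"].to_numpy())
    w = _distance_band_weights(np.asarray(cx), np.asarray(cy), band_distance_m)
    x = analyzed["value"].to_numpy(dtype=float)

    xbar = x.mean()
    s = x.std(ddof=0)  # population sd, per the statistic's definition
    w_sum = w.sum(axis=1)
    w_sq_sum = (w * w).sum(axis=1)
    result = analyzed[["cell", "row", "col", "count", "value"]].copy()
    if s == 0.0:
        result["gi_z"] = 0.0
        result["p_value"] = 1.0
        result["degenerate"] = True
        return result

    num = w @ x - xbar * w_sum
    den = s * np.sqrt((n * w_sq_sum - w_sum**2) / (n - 1))
    z = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    result["gi_z"] = z
    result["p_value"] = 2.0 * stats.norm.sf(np.abs(z))
    result["degenerate"] = False
    return result


def classify_bins(
    gi_results: pd.DataFrame,
    alpha_levels: Sequence[float] = (0.10, 0.05, 0.01),
    correction: str = "benjamini_hochberg",
) -> pd.DataFrame:
    """Attach FDR-adjusted p-values and the +/-3..0 confidence bin.

    gi_bin = sign(z) * (3 if p_adj < alpha99 else 2 if < alpha95 else
    1 if < alpha90 else 0), with default alphas (0.10, 0.05, 0.01).
    """
    a90, a95, a99 = sorted(alpha_levels, reverse=True)
    out = gi_results.copy()
    p = out["p_value"].to_numpy(dtype=float)
    if correction == "benjamini_hochberg":
        out["p_adjusted"] = multipletests(p, method="fdr_bh")[1] if len(p) else p
    elif correction == "none":
        out["p_adjusted"] = p
    else:
        raise ValueError(f"unknown correction {correction!r}")

    p_adj = out["p_adjusted"].to_numpy()
    magnitude = np.select(
        [p_adj < a99, p_adj < a95, p_adj < a90], [3, 2, 1], default=0
    )
    out["gi_bin"] = magnitude * np.sign(out["gi_z"]).astype(int)
    out["label"] = [BIN_LABELS[int(b)] for b in out["gi_bin"]]
    return out


@dataclass
class HotspotConfig:
    cell_size_m: float = 100.0
    band_distance_m: float | None = None  # default 1.5 * cell size
    min_count: int = 5
    alpha_levels: tuple[float, float, float] = (0.10, 0.05, 0.01)
    correction: str = "benjamini_hochberg"
    grid: FishnetGrid | None = field(default=None, repr=False)


def hotspot_pipeline(
    segments: pd.DataFrame,
    polluted_days: Sequence,
    pollutant: str,
    config: HotspotConfig | None = None,
    per_day: bool = False,
) -> dict:
    """Run fishnet -> Gi* -> bins on the selected high-pollution days.

    Parameters
    ----------
    segments
        Drive-pass records with a DatetimeIndex, ``lat``/``lon`` and the
        pollutant column (typically the 8-s rolling-median output).
    polluted_days
        Dates to pool (from the polluted-day selection rule).
    pollutant
        Concentration column to analyse.
    per_day
        Also emit one layer per selected day alongside the pooled layer.

    Returns
    -------
    ``{"pooled": {"grid": ..., "cells": DataFrame, "geojson": dict},
       "per_day": {date: {...}, ...}}``
    """
    if config is None:
        config = HotspotConfig()
    if pollutant not in segments.columns:
        raise KeyError(f"pollutant {pollutant!r} not in segment data")
    days = sorted({pd.Timestamp(d).date() for d in polluted_days})
    if not days:
        raise ValueError("no polluted days selected")
    mask = pd.Series(segments.index.date, index=segments.index).isin(days)
    subset = segments.loc[mask.to_numpy()]
    if subset.empty:
        raise ValueError("no polluted days selected")

    def _run(points: pd.DataFrame) -> dict:
        grid, cells = build_fishnet(
            points,
            cell_size_m=config.cell_size_m,
            min_count=config.min_count,
            value_column=pollutant,
            grid=config.grid,
        )
        gi = gi_star(cells, grid, band_distance_m=config.band_distance_m)
        classified = classify_bins(gi, config.alpha_levels, config.correction)
        return {
            "grid": grid,
            "cells": classified,
            "geojson": to_geojson(grid, classified),
        }

    result = {"pooled": _run(subset), "per_day": {}}
    if per_day:
        for day in days:
            day_points = subset.loc[
                pd.Series(subset.index.date, index=subset.index).eq(day).to_numpy()
            ]
            if len(day_points):
                result["per_day"][str(day)] = _run(day_points)
    return result


def to_geojson(grid: FishnetGrid, cells: pd.DataFrame) -> dict:
    """Cell polygons (WGS84) with count/value/z/p/bin properties."""
    features = []
    for _, rec in cells.iterrows():
        poly = grid.cell_polygon(int(rec["cell"]))
        xs, ys = poly.exterior.coords.xy
        lats, lons = grid.projection.inverse(np.asarray(xs), np.asarray(ys))
        geometry = mapping(poly)
        geometry["coordinates"] = [
            [[float(lo), float(la)] for lo, la in zip(lons, lats)]
        ]
        props = {
            "cell": int(rec["cell"]),
            "count": int(rec["count"]),
            "value": None if pd.isna(rec["value"]) else float(rec["value"]),
        }
        for key in ("gi_z", "p_value", "p_adjusted"):
            if key in rec:
                props[key] = None if pd.isna(rec[key]) else float(rec[key])
        if "gi_bin" in rec:
            props["gi_bin"] = int(rec["gi_bin"])
            props["label"] = str(rec["label"])
        features.append(
            {"type": "Feature", "geometry": geometry, "properties": props}
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(layer: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(layer, fh)
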