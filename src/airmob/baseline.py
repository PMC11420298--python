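"""Background / local-source decomposition of pollutant time series.

The observed concentration at each instant is split as

    C_t(k, j) = C_bg(k, j) + C_lc(k, j),        P_lc = C_lc / C_t,

for pollutant k at time j. The background C_bg — the slowly varying
component attributable to regional/urban-scale sources — is estimated as a
running low percentile (default: 5th percentile over a trailing 1-h window
of drive-pass values) or, alternatively, as block minima of block medians
(minimum hourly median per day, minimum 1-min median per hour), on the
hypothesis that the lowest values in a window are minimally influenced by
nearby plumes. The local remainder C_lc is then partitioned by time scale:
short-lived events (sub-hour plumes from individual sources) versus
longer-lived enhancements persisting on a daytime (~2-8 h) scale.

All components are clipped non-negative and re-summed so that the
decomposition conserves the total exactly at every timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BaselineSpec:
    """How to estimate the background.

    mode 'percentile': trailing-window running percentile.
    mode 'minima': per-block minimum of finer-block medians, interpolated
    linearly between block centres (constant at the edges).
    """

    mode: str = "percentile"
    percentile: float = 5.0
    window: str = "1h"          # trailing window (percentile mode)
    block: str = "1d"           # outer block (minima mode)
    sub_block: str = "1h"       # inner median resolution (minima mode)

    def __post_init__(self) -> None:
        if self.mode not in ("percentile", "minima"):
            raise ValueError(f"unknown baseline mode {self.mode!r}")
        if not 0 <= self.percentile <= 50:
            raise ValueError("baseline percentile must lie in [0, 50]")


@dataclass(frozen=True)
class EventScaleSpec:
    """Time scales separating short-lived from longer-lived local events."""

    short_lived_scale: str = "1h"
    longer_lived_scale: str = "1d"
    minute_scale: str | None = None  # optional third (finest) scale, off by default

    def __post_init__(self) -> None:
        if pd.Timedelta(self.short_lived_scale) >= pd.Timedelta(self.longer_lived_scale):
            raise ValueError("short-lived scale must be shorter than longer-lived")


def _check_series(series: pd.Series) -> pd.Series:
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("series must have a DatetimeIndex")
    if not series.index.is_monotonic_increasing:
        raise ValueError("series must be time-ordered")
    return series.astype(float)


def _percentile_baseline(series: pd.Series, spec: BaselineSpec) -> pd.Series:
    window = pd.Timedelta(spec.window)
    present = series.dropna()
    if len(present) >= 2:
        typical_step = np.median(np.diff(present.index.asi8)) / 1e9
        if window.total_seconds() < 2 * typical_step:
            raise ValueError(
                f"baseline window {spec.window} holds fewer than 2 samples"
            )
    return series.rolling(window, min_periods=1).quantile(
        spec.percentile / 100.0, interpolation="linear"
    )


def _minima_baseline(series: pd.Series, block: str, sub_block: str) -> pd.Series:
    """Per-block minimum of sub-block medians, interpolated between block
    centres; constant extrapolation beyond the first/last block centre."""
    sub_medians = series.resample(sub_block).median()
    block_min = sub_medians.resample(block).min().dropna()
    if block_min.empty:
        return pd.Series(np.nan, index=series.index)
    centers = block_min.index + pd.Timedelta(block) / 2
    xp = centers.asi8.astype(float)
    fp = block_min.to_numpy(dtype=float)
    x = series.index.asi8.astype(float)
    return pd.Series(np.interp(x, xp, fp), index=series.index)


def extract_baseline(series: pd.Series, spec: BaselineSpec | None = None) -> pd.Series:
    """Background estimate on the series' own timestamps.

    Clipped into [0, C_t] wherever the total is defined, so the implied
    local contribution is never negative.
    """
    if spec is None:
        spec = BaselineSpec()
    series = _check_series(series)
    if spec.mode == "percentile":
        baseline = _percentile_baseline(series, spec)
    else:
        baseline = _minima_baseline(series, spec.block, spec.sub_block)
    return baseline.clip(lower=0.0).clip(upper=series)


def decompose(series: pd.Series, baseline: pd.Series) -> pd.DataFrame:
    """Split total into background + local, with the local fraction P_lc.

    P_lc is defined as 0 where the total is 0 (no pollution, no local
    share). Requires identical timestamps on both inputs.
    """
    series = _check_series(series)
    if not series.index.equals(baseline.index):
        raise ValueError("series and baseline timestamps differ")
    background = baseline.clip(lower=0.0).clip(upper=series)
    local = series - background
    with np.errstate(invalid="ignore", divide="ignore"):
        p_local = np.where(series > 0, local / series, 0.0)
    return pd.DataFrame(
        {
            "total": series,
            "background": background,
            "local": local,
            "p_local": pd.Series(p_local, index=series.index).where(series.notna()),
        }
    )


def partition_event_scales(
    series: pd.Series, spec: EventScaleSpec | None = None
) -> pd.DataFrame:
    """Hierarchical scale split: background, longer-lived, short-lived.

    background   = daytime-scale baseline (min of hourly medians per day),
    longer_lived = hour-scale baseline (min of 1-min medians per hour)
                   minus background,
    short_lived  = total minus the hour-scale baseline.

    Baselines are clipped into [0, total] and ordered (day <= hour <=
    total) before differencing, so the three non-negative components sum
    to the total exactly at every timestamp.
    """
    if spec is None:
        spec = EventScaleSpec()
    series = _check_series(series)
    if series.dropna().index.normalize().nunique() < 1:
        raise ValueError("need at least one day of data")

    short_td = pd.Timedelta(spec.short_lived_scale)
    sub_for_short = "1min" if short_td >= pd.Timedelta("10min") else "1s"
    hour_base = _minima_baseline(series, spec.short_lived_scale, sub_for_short)
    day_base = _minima_baseline(series, spec.longer_lived_scale, spec.short_lived_scale)

    background = day_base.clip(lower=0.0).clip(upper=series)
    hour_base = hour_base.clip(lower=background).clip(upper=series)
    out = pd.DataFrame(
        {
            "total": series,
            "background": background,
            "longer_lived": hour_base - background,
            "short_lived": series - hour_base,
        }
    )
    if spec.minute_scale is not None:
        minute_base = _minima_baseline(series, spec.minute_scale, "1s")
        minute_base = minute_base.clip(lower=hour_base).clip(upper=series)
        out["short_lived"] = minute_base - hour_base
        out["sub_minute"] = series - minute_base
    with np.errstate(invalid="ignore", divide="ignore"):
        local = out["total"] - out["background"]
        out["p_local"] = pd.Series(
            np.where(out["total"] > 0, local / out["total"], 0.0), index=out.index
        ).where(out["total"].notna())
    return out


def component_fractions(partition: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Share of each component, both as ratio of means and mean of ratios.

    Whether published percentage contributions are time-averaged instant
    fractions or ratios of time averages is ambiguous in general, so both
    conventions are reported.
    """
    parts = [c for c in ("background", "longer_lived", "short_lived", "sub_minute")
             if c in partition.columns]
    total = partition["total"]
    mean_total = total.mean()
    out: dict[str, dict[str, float]] = {}
    for part in parts:
        with np.errstate(invalid="ignore", divide="ignore"):
            inst = np.where(total > 0, partition[part] / total, 0.0)
        out[part] = {
            "ratio_of_means": float(partition[part].mean() / mean_total)
            if mean_total > 0 else float("nan"),
            "mean_of_ratios": float(np.nanmean(np.where(total.notna(), inst, np.nan))),
        }
    return out


def diurnal_background_local(partition: pd.DataFrame) -> pd.DataFrame:
    """Hour-of-day means of background and short-lived local contribution.

    Also reports, per hour, local/background; the peak-hour ratio is the
    headline "rush-hour enhancement over background" number.
    """
    hod = partition.index.hour
    grouped = partition.groupby(hod)[["background", "short_lived"]].mean()
    grouped.columns = ["background_mean", "local_mean"]
    with np.errstate(invalid="ignore", divide="ignore"):
        grouped["local_over_background"] = (
            grouped["local_mean"] / grouped["background_mean"]
        ).replace([np.inf, -np.inf], np.nan)
    grouped.index.name = "hour_of_day"
    return grouped
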