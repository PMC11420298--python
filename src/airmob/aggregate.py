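"""Temporal aggregation hierarchy for drive-pass monitoring data.

1-s observations -> 8-s drive-pass rolling medians -> clock-hour medians ->
daytime (per-date) medians, plus 5-day moving averages and hour-of-day
(diurnal) box-plot profiles. Medians are used throughout as the central
estimate: with second-scale plumes riding on a smooth background, the
median of a short window is insensitive to any single spike (breakdown
property), which is the point of the "drive pass" aggregation.

All percentiles/quartiles here use linear interpolation between closest
ranks (numpy's default), stated because percentile conventions differ.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pollutants import POLLUTANTS, LodTable

#: Daytime window (hours, inclusive start / exclusive end) used for
#: diurnal profiles; sessions may legitimately extend later.
DAYTIME_HOURS = (7, 18)


def _pollutant_cols(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c in POLLUTANTS]


def _split_sessions(index: pd.DatetimeIndex, max_gap_s: float) -> np.ndarray:
    gaps = np.diff(index.asi8) / 1e9
    return np.concatenate([[0], np.cumsum(gaps > max_gap_s)])


def rolling_median_8s(
    obs: pd.DataFrame,
    lod_table: LodTable | None = None,
    window_s: int = 8,
    max_gap_s: float = 60.0,
) -> pd.DataFrame:
    """8-s right-aligned rolling medians stepping at the sampling cadence.

    Windows never span session gaps longer than ``max_gap_s``. The window
    median is over present values only; medians that land below the 8-s
    LOD are substituted with half that LOD. Output rows carry the window
    end time, centroid position of the window's samples, and the
    contributing-sample count per pollutant.
    """
    if obs.empty:
        return obs.iloc[0:0].copy()
    if not obs.index.is_monotonic_increasing:
        raise ValueError("observations must be time-ordered")
    cols = _pollutant_cols(obs)
    session = _split_sessions(obs.index, max_gap_s)
    pieces = []
    for _, chunk in obs.groupby(session):
        roll = chunk.rolling(f"{window_s}s", min_periods=1)
        out = pd.DataFrame(index=chunk.index)
        out["lat"] = roll["lat"].mean()
        out["lon"] = roll["lon"].mean()
        for c in cols:
            out[c] = roll[c].median()
            out[f"{c}_n"] = roll[c].count().astype(int)
        pieces.append(out)
    result = pd.concat(pieces)
    if lod_table is not None:
        for c in cols:
            lod = lod_table.lod(c, "8s")
            below = result[c].notna() & (result[c] < lod)
            result.loc[below, c] = lod / 2.0
    return result


def hourly_median(
    segments: pd.DataFrame, min_samples: int = 4
) -> pd.DataFrame:
    """Clock-hour medians of the segment series.

    Hours with fewer than ``min_samples`` segments are flagged incomplete
    and get NaN medians. ``completeness`` is the fraction of the hour's
    3600 possible 1-s windows that contributed.
    """
    if not segments.index.is_monotonic_increasing:
        raise ValueError("segments must be time-ordered")
    cols = _pollutant_cols(segments)
    grouper = segments.groupby(segments.index.floor("h"))
    med = grouper[cols].median()
    counts = grouper[cols].count()
    out = med.copy()
    out["n"] = grouper.size()
    out["completeness"] = (out["n"] / 3600.0).clip(upper=1.0)
    for c in cols:
        out.loc[counts[c] < min_samples, c] = np.nan
    out.index.name = "hour"
    return out


def daytime_summary(
    segments: pd.DataFrame,
    hourly: pd.DataFrame | None = None,
    min_hours: int = 3,
    source: str = "segments",
    o3_column: str = "O3",
) -> pd.DataFrame:
    """Per-date daytime medians; ozone uses the daily 1-h maximum instead.

    Non-ozone pollutants: median over the day's 8-s segment values
    (``source='segments'``, the default) or over its hourly medians
    (``source='hourly'``). Ozone: maximum of the day's hourly medians, the
    mobile proxy for the guideline's short-term metric. Days covering fewer
    than ``min_hours`` distinct hours are dropped.
    """
    if source not in ("segments", "hourly"):
        raise ValueError("source must be 'segments' or 'hourly'")
    if hourly is None:
        hourly = hourly_median(segments)
    cols = _pollutant_cols(segments)
    seg_date = pd.Index(segments.index.date, name="date")
    hour_date = pd.Index(hourly.index.date, name="date")

    hours_covered = hourly.groupby(hour_date).size()
    if source == "segments":
        daily = segments.groupby(seg_date)[cols].median()
    else:
        daily = hourly.groupby(hour_date)[cols].median()
    if o3_column in cols:
        daily[o3_column] = hourly.groupby(hour_date)[o3_column].max()
    daily["hours_covered"] = hours_covered.reindex(daily.index).fillna(0).astype(int)
    return daily.loc[daily["hours_covered"] >= min_hours]


def moving_average_5day(
    daily: pd.DataFrame | pd.Series,
    pollutant: str | None = None,
    window_days: int = 5,
    min_days: int = 3,
) -> pd.Series:
    """Centered 5-day moving average over available days.

    The date axis is made contiguous first, so absent days count against
    ``min_days`` and gaps propagate rather than being bridged silently.
    """
    series = daily[pollutant] if pollutant is not None else daily
    series = pd.Series(
        series.to_numpy(), index=pd.DatetimeIndex(pd.to_datetime(series.index))
    ).asfreq("D")
    return series.rolling(window_days, center=True, min_periods=min_days).mean()


def diurnal_profile(
    hourly: pd.DataFrame,
    pollutant: str,
    hours: tuple[int, int] = DAYTIME_HOURS,
) -> pd.DataFrame:
    """Box-plot statistics per hour-of-day across all days.

    Columns: p25, median, p75, whisker_low, whisker_high, n. Whiskers are
    the most extreme observed values within 1.5 x IQR of the quartiles.
    Hours with zero observations are omitted.
    """
    values = hourly[pollutant].dropna()
    rows = {}
    for hod, group in values.groupby(values.index.hour):
        if not hours[0] <= hod < hours[1]:
            continue
        v = group.to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        in_fence = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
        rows[hod] = {
            "p25": q1,
            "median": med,
            "p75": q3,
            "whisker_low": in_fence.min(),
            "whisker_high": in_fence.max(),
            "n": len(v),
        }
    profile = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    profile.index.name = "hour_of_day"
    return profile
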