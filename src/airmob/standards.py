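"""Air-quality guideline registry, exceedance accounting, and summaries.

Holds WHO 2021 Air Quality Guideline and EU limit values at the metrics a
daytime-only mobile campaign can evaluate: the daytime median stands in
for the 24-h averaging period (no nighttime coverage), and the daily
maximum hourly value proxies the ozone peak-season 8-h metric. Exceedance
is strict (value > threshold); boundary values comply.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats


@dataclass(frozen=True)
class Standard:
    pollutant: str
    metric: str       # daytime_median | hourly_median | daily_1h_max | annual_mean
    threshold: float
    unit: str
    authority: str    # WHO_AQG_2021 | EU

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class ExceedanceReport:
    standard: Standard
    n_exceed: int
    n_total: int
    precision: int = 1

    @property
    def percentage(self) -> float:
        return round(100.0 * self.n_exceed / self.n_total, self.precision)

    def to_dict(self) -> dict:
        return {
            **asdict(self.standard),
            "n_exceed": self.n_exceed,
            "n_total": self.n_total,
            "percentage": self.percentage,
        }


def builtin_standards() -> list[Standard]:
    """WHO AQG 2021 and EU values at this campaign's evaluable metrics."""
    return [
        Standard("PM2.5", "daytime_median", 15.0, "ug/m3", "WHO_AQG_2021"),
        Standard("NO2", "daytime_median", 25.0, "ug/m3", "WHO_AQG_2021"),
        Standard("NO2", "hourly_median", 200.0, "ug/m3", "EU"),
        Standard("O3", "daily_1h_max", 100.0, "ug/m3", "WHO_AQG_2021"),
        Standard("O3", "daily_1h_max", 120.0, "ug/m3", "EU"),
        Standard("CO", "daytime_median", 4.0, "ppm", "WHO_AQG_2021"),
        Standard("PM2.5", "annual_mean", 5.0, "ug/m3", "WHO_AQG_2021"),
        Standard("NO2", "annual_mean", 10.0, "ug/m3", "WHO_AQG_2021"),
    ]


def lookup_standard(
    pollutant: str, metric: str, authority: str, registry: Iterable[Standard] | None = None
) -> Standard:
    registry = builtin_standards() if registry is None else registry
    for std in registry:
        if (std.pollutant, std.metric, std.authority) == (pollutant, metric, authority):
            return std
    raise KeyError(f"no standard for ({pollutant}, {metric}, {authority})")


def standards_to_yaml(path, registry: Iterable[Standard] | None = None) -> None:
    registry = builtin_standards() if registry is None else registry
    with open(path, "w") as fh:
        yaml.safe_dump([asdict(s) for s in registry], fh, sort_keys=False)


def standards_from_yaml(path) -> list[Standard]:
    with open(path) as fh:
        return [Standard(**rec) for rec in yaml.safe_load(fh)]


def evaluate_exceedance(
    values: Sequence[float] | pd.Series,
    standard: Standard,
    precision: int = 1,
) -> ExceedanceReport:
    """Count strict exceedances of the standard among the summary values.

    ``values`` must already be at the standard's metric resolution (hourly
    medians for an hourly standard, daytime medians for a daily one);
    missing entries are excluded from both counts.
    """
    arr = pd.Series(values).dropna().to_numpy(dtype=float)
    if arr.size == 0:
        raise ValueError("no values to evaluate")
    return ExceedanceReport(
        standard=standard,
        n_exceed=int((arr > standard.threshold).sum()),
        n_total=int(arr.size),
        precision=precision,
    )


SUMMARY_ROWS = ("min", "p1", "p5", "p25", "median", "mean", "sd", "p75",
                "p95", "p99", "max", "n")


def summary_percentiles(values: Sequence[float] | pd.Series) -> dict[str, float]:
    """Order-statistic summary: min, 1/5/25/50/75/95/99th pct, mean, sd, max, n.

    Percentiles use linear interpolation between closest ranks.
    """
    arr = pd.Series(values).dropna().to_numpy(dtype=float)
    if arr.size == 0:
        raise ValueError("summary_percentiles requires nonempty input")
    p = np.percentile(arr, [1, 5, 25, 50, 75, 95, 99])
    return {
        "min": float(arr.min()),
        "p1": float(p[0]),
        "p5": float(p[1]),
        "p25": float(p[2]),
        "median": float(p[3]),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "p75": float(p[4]),
        "p95": float(p[5]),
        "p99": float(p[6]),
        "max": float(arr.max()),
        "n": int(arr.size),
    }


def summary_table(df: pd.DataFrame, pollutants: Sequence[str] | None = None) -> pd.DataFrame:
    """Summary-statistics table, one column per pollutant."""
    pollutants = list(df.columns) if pollutants is None else list(pollutants)
    table = {p: summary_percentiles(df[p]) for p in pollutants if df[p].notna().any()}
    return pd.DataFrame(table).reindex(list(SUMMARY_ROWS))


def select_polluted_days(
    daytime: pd.DataFrame,
    pm25_threshold: float = 15.0,
    no2_threshold: float = 25.0,
    pm25_column: str = "PM2.5",
    no2_column: str = "NO2",
) -> pd.DataFrame:
    """High-pollution days: daytime median above either guideline value.

    Selected when PM2.5 > 15 ug/m3 or NO2 > 25 ug/m3 (strict), returned
    ranked by NO2 from high to low — the ordering used to enumerate
    candidate days for hotspot analysis.
    """
    mask = (daytime[pm25_column] > pm25_threshold) | (daytime[no2_column] > no2_threshold)
    return daytime.loc[mask].sort_values(no2_column, ascending=False)


def spearman_matrix(series_map: Mapping[str, pd.Series], min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Spearman rank correlations between named series.

    Pairs with fewer than ``min_pairs`` complete observations get NaN with
    a warning. Symmetric, unit diagonal.
    """
    names = list(series_map)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            paired = pd.concat([series_map[a], series_map[b]], axis=1, keys=[a, b]).dropna()
            if len(paired) < min_pairs:
                warnings.warn(
                    f"fewer than {min_pairs} complete pairs for ({a}, {b}); "
                    "correlation undefined",
                    stacklevel=2,
                )
                rho = np.nan
            else:
                rho = stats.spearmanr(paired[a], paired[b]).statistic
            mat.loc[a, b] = mat.loc[b, a] = rho
    return mat
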