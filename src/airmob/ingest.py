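"""Raw-observation ingest and quality control.

Reads 1-s georeferenced multi-pollutant records from delimited text, applies
the half-LOD substitution for below-detection values, the NOx unit
conversion, and key-variable completeness filtering. QC never invents data:
missingness is monotone non-decreasing through every step here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pollutants import POLLUTANTS, LodTable

logger = logging.getLogger(__name__)

#: ppb -> ug/m3 for NOx expressed as NO2 at 20 degC and 760 mmHg,
#: i.e. molar mass of NO2 divided by the molar volume of an ideal gas
#: under those conditions. Held as the conventional printed constant.
NOX_PPB_TO_UGM3 = 1.9125

#: Molar mass of NO2 in g/mol.
NO2_MOLAR_MASS = 46.0055
#: Ideal-gas molar volume at 20 degC / 760 mmHg in L/mol.
MOLAR_VOLUME_20C = 24.055

MANDATORY_COLUMNS = ("time", "lat", "lon")


def nox_conversion_factor(
    molar_mass: float = NO2_MOLAR_MASS, molar_volume: float = MOLAR_VOLUME_20C
) -> float:
    """Derive the ppb -> ug/m3 factor for NOx-as-NO2 from first principles.

    1 ppb of a gas contributes molar_mass / molar_volume ug/m3. At 20 degC
    and 760 mmHg this evaluates to 1.9125 (4 d.p.) for NO2.
    """
    return molar_mass / molar_volume


@dataclass
class RetentionReport:
    """Bookkeeping from :func:`drop_missing_key_variables`."""

    n_input: int
    n_retained: int
    missing_fraction: dict[str, float]

    @property
    def retention(self) -> float:
        return self.n_retained / self.n_input if self.n_input else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "retention": self.retention,
            "missing_fraction": dict(self.missing_fraction),
        }


def read_observations(
    path,
    schema_spec: Mapping[str, str] | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read raw 1-s observations from delimited text.

    Parameters
    ----------
    path
        Delimited text file with one row per observation.
    schema_spec
        Optional mapping of file column name -> canonical name
        (``time``, ``lat``, ``lon``, pollutant names). Identity by default.
    sep
        Field separator.

    Returns
    -------
    DataFrame indexed by UTC ``time`` with ``lat``, ``lon`` and one column
    per pollutant present in the file. Unparseable pollutant cells become
    NaN; rows with unparseable time or coordinates are dropped (counted in
    the log). Duplicate timestamps keep the first occurrence with a warning.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    if schema_spec:
        raw = raw.rename(columns=dict(schema_spec))
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"mandatory column {col!r} missing from {path}")

    out = pd.DataFrame(index=raw.index)
    out["time"] = pd.to_datetime(raw["time"], errors="coerce", utc=True)
    out["lat"] = pd.to_numeric(raw["lat"], errors="coerce")
    out["lon"] = pd.to_numeric(raw["lon"], errors="coerce")
    pollutant_cols = [c for c in raw.columns if c in POLLUTANTS]
    for col in pollutant_cols:
        out[col] = pd.to_numeric(raw[col], errors="coerce")

    bad_coord = (
        out["time"].isna()
        | out["lat"].isna()
        | out["lon"].isna()
        | ~out["lat"].between(-90, 90)
        | ~out["lon"].between(-180, 180)
    )
    n_dropped = int(bad_coord.sum())
    if n_dropped:
        logger.info("dropped %d rows with malformed time/position", n_dropped)
    out = out.loc[~bad_coord]

    dup = out["time"].duplicated(keep="first")
    if dup.any():
        logger.warning(
            "dropped %d duplicate-timestamp rows (keeping first)", int(dup.sum())
        )
        out = out.loc[~dup]

    out = out.sort_values("time").set_index("time")
    # Replace non-finite pollutant values with NaN (missingness marker).
    for col in pollutant_cols:
        out.loc[~np.isfinite(out[col].astype(float)), col] = np.nan
    return out


def substitute_below_lod(
    obs: pd.DataFrame, lod_table: LodTable, resolution: str = "1s"
) -> pd.DataFrame:
    """Replace every present value strictly below the LOD by half the LOD.

    Values at or above the LOD are unchanged; missing values stay missing.
    Idempotent: LOD/2 is itself below the LOD and re-substitutes to LOD/2.
    """
    pollutants = [c for c in obs.columns if c in POLLUTANTS]
    for p in pollutants:
        if not lod_table.covers([p], resolution):
            raise KeyError(
                f"LOD table has no entry for pollutant {p!r} at {resolution}"
            )
    out = obs.copy()
    for p in pollutants:
        lod = lod_table.lod(p, resolution)
        below = out[p].notna() & (out[p] < lod)
        out.loc[below, p] = lod / 2.0
    return out


def convert_nox(no_ppb, no2_ppb, factor: float = NOX_PPB_TO_UGM3):
    """Combine NO and NO2 (ppb) into NOx expressed as NO2 in ug/m3.

    NOx [ug/m3] = (NO [ppb] + NO2 [ppb]) * 1.9125. Missing in, missing out;
    negative concentrations are physical nonsense and raise.
    """
    no_arr = np.asarray(no_ppb, dtype=float)
    no2_arr = np.asarray(no2_ppb, dtype=float)
    if np.any(no_arr[~np.isnan(no_arr)] < 0) or np.any(
        no2_arr[~np.isnan(no2_arr)] < 0
    ):
        raise ValueError("negative concentration passed to convert_nox")
    result = (no_arr + no2_arr) * factor
    if np.isscalar(no_ppb) and np.isscalar(no2_ppb):
        return float(result)
    return result


def forward_fill_o3(
    obs: pd.DataFrame, column: str = "O3", native_period_s: int = 3
) -> pd.DataFrame:
    """Hold the slower-cadence ozone channel forward onto the 1-s grid.

    The O3 sensor reports every ``native_period_s`` seconds; gaps shorter
    than one native period are filled with the last reading so all
    channels share one time base. Longer gaps remain missing.
    """
    if column not in obs.columns:
        return obs
    out = obs.copy()
    out[column] = out[column].ffill(limit=native_period_s - 1)
    return out


def drop_missing_key_variables(
    obs: pd.DataFrame, key_variables: Sequence[str] | None = None
) -> tuple[pd.DataFrame, RetentionReport]:
    """Remove rows missing any key variable; report per-variable missingness.

    Default key variables: position plus every pollutant column present.
    """
    if key_variables is None:
        key_variables = ["lat", "lon"] + [c for c in obs.columns if c in POLLUTANTS]
    key_variables = list(key_variables)
    if not key_variables:
        raise ValueError("key_variables must be nonempty")
    missing = {v: float(obs[v].isna().mean()) if len(obs) else 0.0 for v in key_variables}
    keep = obs[key_variables].notna().all(axis=1)
    filtered = obs.loc[keep]
    report = RetentionReport(
        n_input=len(obs), n_retained=len(filtered), missing_fraction=missing
    )
    return filtered, report
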