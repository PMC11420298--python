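"""Synthetic mobile-monitoring scenario generator with known ground truth.

Emulates a Google-Street-View-style campaign: a vehicle drives a fixed
route at ~1 Hz during daytime sessions, observing, per pollutant,

    observation = background + sum of plume events + instrument noise,

where the background varies smoothly (diurnal harmonics + seasonal term +
AR(1) wander) and plumes are Poisson-arriving spikes with instantaneous
rise and exponential decay, seconds-to-minutes long. A designated set of
fishnet cells ("hotspots") multiplies the local arrival rate. The full
decomposition, event list, and hotspot cell set are returned as
:class:`ScenarioTruth`, so every downstream stage (baseline extraction,
decomposition, hotspot detection) can be validated against known truth.

Censoring is not applied here: below-LOD values are emitted as drawn and
are the ingest stage's responsibility. Missing values are NaN.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hotspots import FishnetGrid, LocalProjection, build_fishnet
from .pollutants import LodTable

DEFAULT_SESSION = (dt.time(7, 0), dt.time(17, 0))


@dataclass(frozen=True)
class RouteModel:
    """Fixed drive route: waypoint polyline, speed, daily session windows.

    The vehicle moves at constant speed along the polyline and ping-pongs
    (reverses at the ends), keeping a continuous odometer across sessions.
    """

    waypoints: tuple[tuple[float, float], ...]
    speed_mps: float = 10.0
    session_windows: tuple[tuple[dt.time, dt.time], ...] = (DEFAULT_SESSION,)

    def __post_init__(self) -> None:
        if len(self.waypoints) < 2:
            raise ValueError("route needs at least 2 waypoints")
        for a, b in zip(self.waypoints, self.waypoints[1:]):
            if a == b:
                raise ValueError("consecutive waypoints must be distinct")
        if not self.speed_mps > 0:
            raise ValueError("speed must be positive")
        prev_end = None
        for start, end in self.session_windows:
            if start >= end:
                raise ValueError("session window start must precede end")
            if prev_end is not None and start < prev_end:
                raise ValueError("session windows must be ordered, non-overlapping")
            prev_end = end


@dataclass(frozen=True)
class BackgroundModel:
    """Smooth urban background for one pollutant.

    diurnal_harmonics: (period_hours, amplitude, peak_hour) cosine terms;
    the default pair (24 h, 12 h) reproduces a bimodal rush-hour shape.
    seasonal_amplitude peaks at ``seasonal_peak_doy`` (mid-January default,
    the winter heating season). AR(1) noise with innovation sd ``noise_sd``
    adds hour-scale wander; the realised series is clipped at zero.
    """

    mean_level: float
    diurnal_harmonics: tuple[tuple[float, float, float], ...] = ()
    seasonal_amplitude: float = 0.0
    seasonal_peak_doy: float = 15.0
    ar1_coefficient: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.mean_level > 0:
            raise ValueError("mean_level must be positive")
        if not abs(self.ar1_coefficient) < 1:
            raise ValueError("AR(1) coefficient must satisfy |phi| < 1")


@dataclass(frozen=True)
class PlumeModel:
    """Sporadic local emission events for one pollutant.

    Events arrive as a Poisson process at ``arrival_rate_per_hour``
    (optionally modulated by a 24-element hour-of-day profile), multiplied
    by ``hotspot_rate_multiplier`` while the vehicle is inside a hotspot
    cell. Each event contributes amplitude * exp(-dt/decay_seconds) for
    dt >= 0, with amplitude ~ lognormal.
    """

    arrival_rate_per_hour: float = 20.0
    amplitude_log_mean: float = 2.0
    amplitude_log_sd: float = 0.6
    decay_seconds: float = 60.0
    hotspot_cells: frozenset[int] = frozenset()
    hotspot_rate_multiplier: float = 1.0
    hourly_rate_profile: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.arrival_rate_per_hour < 0:
            raise ValueError("arrival rate must be >= 0")
        if not self.decay_seconds > 0:
            raise ValueError("decay_seconds must be positive")
        if self.hotspot_rate_multiplier < 1:
            raise ValueError("hotspot_rate_multiplier must be >= 1")
        if self.hourly_rate_profile is not None and len(self.hourly_rate_profile) != 24:
            raise ValueError("hourly_rate_profile needs 24 entries")


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int = 0
    n_days: int = 2
    start_date: dt.date = dt.date(2021, 5, 17)
    sample_period_s: int = 1
    pollutants: tuple[str, ...] = ("PM2.5", "NO2")
    missingness_fraction: float = 0.0
    instrument_noise_sd: Mapping[str, float] = field(default_factory=dict)
    cell_size_m: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.missingness_fraction < 1:
            raise ValueError("missingness_fraction must be in [0, 1)")
        if self.n_days < 1:
            raise ValueError("n_days must be positive")


@dataclass
class ScenarioTruth:
    """Ground truth for one generated scenario.

    observation (pre-censoring) = background + plumes + noise, columnwise.
    """

    track: pd.DataFrame
    background: pd.DataFrame
    background_noiseless: pd.DataFrame
    plumes: pd.DataFrame
    noise: pd.DataFrame
    events: pd.DataFrame
    hotspot_cells: frozenset[int]
    grid: FishnetGrid


def _polyline_geometry(route: RouteModel):
    lats = np.array([w[0] for w in route.waypoints])
    lons = np.array([w[1] for w in route.waypoints])
    proj = LocalProjection(float(lats.mean()), float(lons.mean()))
    x, y = proj.forward(lats, lons)
    seg = np.hypot(np.diff(x), np.diff(y))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return proj, x, y, cum


def session_timestamps(route: RouteModel, config: ScenarioConfig) -> pd.DatetimeIndex:
    """All sample instants (UTC) across the scenario's session windows."""
    times = []
    period = config.sample_period_s
    for day in range(config.n_days):
        date = config.start_date + dt.timedelta(days=day)
        for start, end in route.session_windows:
            t0 = dt.datetime.combine(date, start, tzinfo=dt.timezone.utc)
            t1 = dt.datetime.combine(date, end, tzinfo=dt.timezone.utc)
            n = int((t1 - t0).total_seconds() // period)
            times.append(pd.date_range(t0, periods=n, freq=f"{period}s"))
    if not times:
        raise ValueError("no sampling time: empty session windows")
    return times[0].append(times[1:]) if len(times) > 1 else times[0]


def simulate_route(route: RouteModel, config: ScenarioConfig) -> pd.DataFrame:
    """Timestamped GPS track: one position per sample period in session.

    Position = constant-speed linear interpolation along the waypoint
    polyline, reflecting at the endpoints, with a continuous odometer
    across sessions and days.
    """
    idx = session_timestamps(route, config)
    proj, x, y, cum = _polyline_geometry(route)
    length = cum[-1]
    odometer = np.arange(len(idx), dtype=float) * config.sample_period_s * route.speed_mps
    u = np.mod(odometer, 2 * length)
    dist = np.where(u <= length, u, 2 * length - u)
    px = np.interp(dist, cum, x)
    py = np.interp(dist, cum, y)
    lat, lon = proj.inverse(px, py)
    return pd.DataFrame({"lat": lat, "lon": lon}, index=idx.rename("time"))


def simulate_background(
    model: BackgroundModel,
    timestamps: pd.DatetimeIndex,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Background series on the given timestamps, with noiseless component.

    value = mean + diurnal harmonics + seasonal cosine + AR(1) noise,
    clipped at zero. The AR(1) process steps once per sample and starts
    from its stationary distribution.
    """
    if not timestamps.is_monotonic_increasing:
        raise ValueError("timestamps must be sorted")
    hour = timestamps.hour + timestamps.minute / 60 + timestamps.second / 3600
    doy = timestamps.dayofyear + hour / 24
    det = np.full(len(timestamps), model.mean_level, dtype=float)
    for period_h, amp, peak_h in model.diurnal_harmonics:
        det += amp * np.cos(2 * np.pi * (hour - peak_h) / period_h)
    if model.seasonal_amplitude:
        det += model.seasonal_amplitude * np.cos(
            2 * np.pi * (doy - model.seasonal_peak_doy) / 365.25
        )
    phi, sd = model.ar1_coefficient, model.noise_sd
    if sd > 0:
        eps = rng.normal(0.0, sd, size=len(timestamps))
        ar = np.empty(len(timestamps))
        ar[0] = eps[0] / math.sqrt(1 - phi**2) if phi else eps[0]
        for k in range(1, len(ar)):
            ar[k] = phi * ar[k - 1] + eps[k]
    else:
        ar = np.zeros(len(timestamps))
    return pd.DataFrame(
        {"value": np.clip(det + ar, 0.0, None), "noiseless": np.clip(det, 0.0, None)},
        index=timestamps,
    )


#: Decay horizon: an event is over once its amplitude has fallen below 1%.
DECAY_HORIZON_FACTOR = math.log(100.0)


def simulate_plumes(
    model: PlumeModel,
    track: pd.DataFrame,
    grid: FishnetGrid,
    rng: np.random.Generator,
) -> tuple[pd.Series, pd.DataFrame]:
    """Plume contribution series along the track, plus the true event list.

    Arrivals are simulated by per-sample Bernoulli thinning of the Poisson
    process (exact at rate * dt << 1); the rate is multiplied by the
    hotspot multiplier while the vehicle is inside a hotspot cell.
    """
    if track.empty:
        raise ValueError("track must be nonempty")
    times = track.index
    t_sec = times.asi8 / 1e9
    dt_s = np.diff(t_sec, prepend=t_sec[0] - (t_sec[1] - t_sec[0] if len(t_sec) > 1 else 1.0))
    cells = grid.cell_index_for_latlon(track["lat"].to_numpy(), track["lon"].to_numpy())
    rate = np.full(len(times), model.arrival_rate_per_hour / 3600.0)
    if model.hourly_rate_profile is not None:
        rate *= np.asarray(model.hourly_rate_profile)[times.hour]
    if model.hotspot_cells:
        in_hot = np.isin(cells, list(model.hotspot_cells))
        rate = np.where(in_hot, rate * model.hotspot_rate_multiplier, rate)

    series = np.zeros(len(times))
    hits = np.flatnonzero(rng.random(len(times)) < rate * np.abs(dt_s))
    amplitudes = rng.lognormal(model.amplitude_log_mean, model.amplitude_log_sd, size=len(hits))
    horizon = model.decay_seconds * DECAY_HORIZON_FACTOR
    records = []
    for k, amp in zip(hits, amplitudes):
        t0 = t_sec[k]
        stop = np.searchsorted(t_sec, t0 + horizon, side="right")
        delta = t_sec[k:stop] - t0
        series[k:stop] += amp * np.exp(-delta / model.decay_seconds)
        records.append(
            {
                "start": times[k],
                "end": times[k] + pd.Timedelta(seconds=horizon),
                "amplitude": amp,
                "lat": track["lat"].iloc[k],
                "lon": track["lon"].iloc[k],
                "cell": int(cells[k]),
            }
        )
    events = pd.DataFrame(
        records, columns=["start", "end", "amplitude", "lat", "lon", "cell"]
    )
    return pd.Series(series, index=times, name="plume"), events


def _as_mapping(model, pollutants: Sequence[str]) -> dict:
    if isinstance(model, Mapping):
        missing = set(pollutants) - set(model)
        if missing:
            raise ValueError(f"no model for pollutants {sorted(missing)}")
        return dict(model)
    return {p: model for p in pollutants}


def generate_scenario(
    route: RouteModel,
    background_model: BackgroundModel | Mapping[str, BackgroundModel],
    plume_model: PlumeModel | Mapping[str, PlumeModel],
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, ScenarioTruth]:
    """Full scenario: raw observation table plus ground truth.

    Observations = background + plumes + Gaussian instrument noise, then
    NaN missingness at ``missingness_fraction`` per pollutant. Below-LOD
    values are left as drawn (the ingest stage owns censoring). Identical
    config (incl. seed) yields identical output.
    """
    bg_models = _as_mapping(background_model, config.pollutants)
    pl_models = _as_mapping(plume_model, config.pollutants)

    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(4 * len(config.pollutants) )
    track = simulate_route(route, config)
    grid, _ = build_fishnet(track, cell_size_m=config.cell_size_m, min_count=1)

    hotspot_cells: set[int] = set()
    obs = track.copy()
    bg_frames, bg_det_frames, plume_frames, noise_frames = {}, {}, {}, {}
    event_frames = []
    for i, pollutant in enumerate(config.pollutants):
        rng_bg = np.random.default_rng(streams[4 * i])
        rng_pl = np.random.default_rng(streams[4 * i + 1])
        rng_noise = np.random.default_rng(streams[4 * i + 2])
        rng_miss = np.random.default_rng(streams[4 * i + 3])

        bg = simulate_background(bg_models[pollutant], track.index, rng_bg)
        plume, events = simulate_plumes(pl_models[pollutant], track, grid, rng_pl)
        sd = float(config.instrument_noise_sd.get(pollutant, 0.0))
        noise = rng_noise.normal(0.0, sd, size=len(track)) if sd > 0 else np.zeros(len(track))

        total = bg["value"].to_numpy() + plume.to_numpy() + noise
        if config.missingness_fraction > 0:
            drop = rng_miss.random(len(track)) < config.missingness_fraction
            total = np.where(drop, np.nan, total)
        obs[pollutant] = total
        bg_frames[pollutant] = bg["value"]
        bg_det_frames[pollutant] = bg["noiseless"]
        plume_frames[pollutant] = plume
        noise_frames[pollutant] = pd.Series(noise, index=track.index)
        events = events.assign(pollutant=pollutant)
        event_frames.append(events)
        hotspot_cells |= set(pl_models[pollutant].hotspot_cells)

    truth = ScenarioTruth(
        track=track,
        background=pd.DataFrame(bg_frames),
        background_noiseless=pd.DataFrame(bg_det_frames),
        plumes=pd.DataFrame(plume_frames),
        noise=pd.DataFrame(noise_frames),
        events=pd.concat(event_frames, ignore_index=True),
        hotspot_cells=frozenset(hotspot_cells),
        grid=grid,
    )
    return obs, truth


def default_route() -> RouteModel:
    """Lawnmower sweep over a ~1 km x 1 km urban block grid (Dublin-ish).

    Eleven west-east passes 100 m apart give dense, repeated coverage of a
    10 x 10 grid of 100-m fishnet cells within a daily session.
    """
    lat0, lon0 = 53.35, -6.26
    dlat = 100.0 / 111_195.0  # 100 m in degrees latitude
    dlon = 100.0 / (111_195.0 * math.cos(math.radians(lat0)))
    waypoints = []
    for i in range(11):
        lat = lat0 + i * dlat
        west, east = lon0, lon0 + 10 * dlon
        if i % 2 == 0:
            waypoints += [(lat, west), (lat, east)]
        else:
            waypoints += [(lat, east), (lat, west)]
    return RouteModel(waypoints=tuple(waypoints), speed_mps=8.0)


def default_background_models() -> dict[str, BackgroundModel]:
    """Plausible urban levels: bimodal rush-hour diurnal, winter-peaking
    season, slow AR(1) wander. Units: PM2.5/O3 ug/m3; NO/NO2 ppb; CO/CO2 ppm."""
    return {
        "PM2.5": BackgroundModel(7.0, ((24, 2.0, 8.0), (12, 1.0, 5.0)), 3.0, 15.0, 0.999, 0.05),
        "NO2": BackgroundModel(14.0, ((24, 4.0, 8.0), (12, 2.5, 5.0)), 4.0, 15.0, 0.999, 0.08),
        "NO": BackgroundModel(8.0, ((24, 3.0, 8.0), (12, 1.5, 5.0)), 2.0, 15.0, 0.999, 0.06),
        "O3": BackgroundModel(46.0, ((24, 12.0, 14.0),), -10.0, 15.0, 0.999, 0.15),
        "CO": BackgroundModel(0.3, ((24, 0.05, 8.0),), 0.05, 15.0, 0.999, 0.002),
        "CO2": BackgroundModel(440.0, ((24, 10.0, 7.0),), 5.0, 15.0, 0.999, 0.2),
    }


def default_plume_models(
    hotspot_cells: frozenset[int] = frozenset(),
    hotspot_rate_multiplier: float = 1.0,
) -> dict[str, PlumeModel]:
    """Traffic-plume defaults: tens of events per hour, ~1 min decay,
    lognormal amplitudes on the order of each pollutant's median level."""
    common = dict(
        decay_seconds=60.0,
        hotspot_cells=hotspot_cells,
        hotspot_rate_multiplier=hotspot_rate_multiplier,
    )
    return {
        "PM2.5": PlumeModel(20.0, 1.2, 0.7, **common),
        "NO2": PlumeModel(30.0, 2.2, 0.7, **common),
        "NO": PlumeModel(30.0, 2.0, 0.8, **common),
        "O3": PlumeModel(5.0, 1.0, 0.5, **common),
        "CO": PlumeModel(20.0, -2.0, 0.7, **common),
        "CO2": PlumeModel(20.0, 2.3, 0.6, **common),
    }


def write_scenario(
    obs: pd.DataFrame, truth: ScenarioTruth, out_dir, lod_table: LodTable | None = None
) -> None:
    """Write observations + sidecar truth as plain text (CSV/JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    obs.to_csv(out / "observations.csv", index_label="time")
    truth.background.to_csv(out / "truth_background.csv", index_label="time")
    truth.events.to_csv(out / "truth_events.csv", index=False)
    with open(out / "truth_hotspot_cells.json", "w") as fh:
        json.dump(sorted(truth.hotspot_cells), fh)
    if lod_table is not None:
        lod_table.to_yaml(out / "lod_table.yaml")
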