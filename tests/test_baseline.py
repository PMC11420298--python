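"""Baseline extraction and background/local decomposition: exactness on
constructed signals, conservation, and recovery of generator ground truth."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from airmob.aggregate import rolling_median_8s
from airmob.baseline import (
    BaselineSpec,
    EventScaleSpec,
    component_fractions,
    decompose,
    diurnal_background_local,
    extract_baseline,
    partition_event_scales,
)
from airmob.synthetic import (
    BackgroundModel,
    PlumeModel,
    RouteModel,
    ScenarioConfig,
    default_route,
    generate_scenario,
)

from conftest import seconds_index


def series_of(values, start="2021-05-17 07:00"):
    idx = pd.date_range(start, periods=len(values), freq="1s", tz="UTC")
    return pd.Series(np.asarray(values, dtype=float), index=idx, name="NO2")


def spiked_constant(c=20.0, n=4 * 3600, spike_every=3600, spike_len=60, amp=50.0):
    """Constant background with one 60-s spike per hour (occupancy 1.7%)."""
    values = np.full(n, c)
    for start in range(spike_every // 2, n - spike_len, spike_every):
        values[start: start + spike_len] += amp
    return series_of(values)


class TestExtractBaseline:
    @pytest.mark.parametrize("spec", [
        BaselineSpec(mode="percentile"),
        BaselineSpec(mode="minima", block="1h", sub_block="1min"),
    ])
    def test_constant_series_is_its_own_baseline(self, spec):
        s = series_of([6.0] * 7200)
        np.testing.assert_allclose(extract_baseline(s, spec).to_numpy(), 6.0)

    def test_low_occupancy_spikes_do_not_lift_percentile_baseline(self):
        s = spiked_constant()
        baseline = extract_baseline(s, BaselineSpec(mode="percentile"))
        np.testing.assert_array_equal(baseline.to_numpy(), 20.0)

    def test_percentile_zero_is_running_minimum(self):
        rng = np.random.default_rng(0)
        s = series_of(rng.lognormal(2, 0.5, 2000))
        baseline = extract_baseline(s, BaselineSpec(percentile=0.0, window="5min"))
        expected = s.rolling("5min", min_periods=1).min()
        np.testing.assert_allclose(baseline.to_numpy(), expected.to_numpy())

    def test_window_below_two_samples_rejected(self):
        s = series_of([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="2 samples"):
            extract_baseline(s, BaselineSpec(window="1s"))

    def test_percentile_monotonicity(self):
        rng = np.random.default_rng(1)
        s = series_of(rng.lognormal(2, 0.5, 3000))
        b5 = extract_baseline(s, BaselineSpec(percentile=5))
        b25 = extract_baseline(s, BaselineSpec(percentile=25))
        assert (b25 >= b5 - 1e-12).all()

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        s = series_of(rng.lognormal(2, 0.5, 3000))
        b = extract_baseline(s, BaselineSpec())
        b_shift = extract_baseline(s + 100.0, BaselineSpec())
        np.testing.assert_allclose(
            b_shift.to_numpy(), b.to_numpy() + 100.0, rtol=1e-12
        )


class TestDecompose:
    def test_forced_arithmetic(self):
        s = series_of([100.0])
        b = series_of([60.0])
        d = decompose(s, b)
        assert d["local"].iloc[0] == 40.0
        assert d["p_local"].iloc[0] == pytest.approx(0.4)

    def test_identity_baseline_gives_zero_local(self):
        s = series_of(np.linspace(5, 10, 100))
        d = decompose(s, s.copy())
        assert (d["local"] == 0.0).all()
        assert (d["p_local"] == 0.0).all()

    def test_zero_total_defines_zero_fraction(self):
        s = series_of([0.0, 4.0])
        d = decompose(s, series_of([0.0, 1.0]))
        assert d["p_local"].iloc[0] == 0.0

    def test_timestamp_mismatch_rejected(self):
        s = series_of([1.0, 2.0])
        b = series_of([1.0, 2.0], start="2021-05-17 08:00")
        with pytest.raises(ValueError, match="timestamps"):
            decompose(s, b)

    def test_recovered_local_mass_matches_injected_plumes(self):
        # Noise-free scenario: mean local over plume-active seconds within
        # 10% of the mean injected plume contribution.
        cfg = ScenarioConfig(seed=21, n_days=1, pollutants=("NO2",))
        obs, truth = generate_scenario(
            default_route(),
            BackgroundModel(14.0),
            PlumeModel(20.0, 2.2, 0.5, decay_seconds=30.0),
            cfg,
        )
        s = obs["NO2"]
        d = decompose(s, extract_baseline(s, BaselineSpec()))
        active = truth.plumes["NO2"] > 0.5
        recovered = d.loc[active.to_numpy(), "local"].mean()
        injected = truth.plumes.loc[active, "NO2"].mean()
        assert recovered == pytest.approx(injected, rel=0.10)


class TestPartition:
    def test_slow_sinusoid_has_negligible_short_lived(self):
        idx = pd.date_range("2021-05-17", periods=24 * 3600, freq="1s", tz="UTC")
        hours = (idx.asi8 - idx.asi8[0]) / 3.6e12
        s = pd.Series(50.0 + 3.0 * np.cos(2 * np.pi * hours / 24.0), index=idx)
        part = partition_event_scales(s)
        assert (part["short_lived"] <= 0.01 * part["total"]).all()

    def test_single_spike_lands_in_short_lived(self):
        s = spiked_constant(c=10.0, n=24 * 3600, spike_every=10**9, amp=0.0)
        values = s.to_numpy().copy()
        values[6 * 3600: 6 * 3600 + 30] += 80.0  # one 30-s spike
        s = pd.Series(values, index=s.index)
        part = partition_event_scales(s)
        spike_mass = part["short_lived"].sum()
        assert spike_mass == pytest.approx(30 * 80.0, rel=0.05)
        assert part["longer_lived"].abs().max() < 1e-9

    def test_zero_series_yields_zero_components(self):
        s = series_of([0.0] * (2 * 3600))
        part = partition_event_scales(s)
        for col in ("background", "longer_lived", "short_lived"):
            assert (part[col] == 0.0).all()

    def test_inverted_scales_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            EventScaleSpec(short_lived_scale="1d", longer_lived_scale="1h")

    @pytest.mark.parametrize("seed", range(10))
    def test_components_conserve_total_exactly(self, seed):
        cfg = ScenarioConfig(seed=seed, n_days=1, pollutants=("NO2",),
                             missingness_fraction=0.2)
        obs, _ = generate_scenario(
            default_route(),
            BackgroundModel(14.0, ((24, 4.0, 8.0),), ar1_coefficient=0.99, noise_sd=0.05),
            PlumeModel(30.0, 2.0, 0.6, decay_seconds=45.0),
            cfg,
        )
        seg = rolling_median_8s(obs)
        part = partition_event_scales(seg["NO2"].dropna())
        resid = part["background"] + part["longer_lived"] + part["short_lived"] - part["total"]
        assert resid.abs().max() < 1e-9
        for col in ("background", "longer_lived", "short_lived"):
            assert (part[col] >= -1e-12).all()


class TestDiurnal:
    @staticmethod
    def _rush_hour_scenario(seed, amplitude_log_mean=2.2):
        profile = tuple(6.0 if h in (8, 17) else 1.0 for h in range(24))
        route = RouteModel(
            default_route().waypoints, 8.0,
            session_windows=((dt.time(7, 0), dt.time(18, 0)),),
        )
        cfg = ScenarioConfig(seed=seed, n_days=3, pollutants=("NO2",))
        obs, truth = generate_scenario(
            route,
            BackgroundModel(14.0),
            PlumeModel(40.0, amplitude_log_mean, 0.5, decay_seconds=30.0,
                       hourly_rate_profile=profile),
            cfg,
        )
        return obs, truth

    def test_constant_background_no_plumes_has_zero_ratio(self):
        s = series_of([12.0] * (12 * 3600))
        part = partition_event_scales(s)
        diurnal = diurnal_background_local(part)
        assert (diurnal["local_over_background"].abs() < 1e-12).all()

    def test_rush_hour_schedule_recovered(self):
        obs, _ = self._rush_hour_scenario(seed=5)
        seg = rolling_median_8s(obs)
        part = partition_event_scales(seg["NO2"].dropna())
        diurnal = diurnal_background_local(part)
        assert set(diurnal["local_mean"].nlargest(2).index) == {8, 17}

    def test_local_means_scale_linearly_with_amplitude(self):
        # Doubling every plume amplitude (log-mean + ln 2) doubles the
        # hourly local means on noise-free data.
        obs1, _ = self._rush_hour_scenario(seed=7, amplitude_log_mean=1.5)
        obs2, _ = self._rush_hour_scenario(seed=7, amplitude_log_mean=1.5 + np.log(2))
        d1 = diurnal_background_local(partition_event_scales(obs1["NO2"]))
        d2 = diurnal_background_local(partition_event_scales(obs2["NO2"]))
        ratio = d2["local_mean"] / d1["local_mean"]
        np.testing.assert_allclose(ratio.to_numpy(), 2.0, rtol=0.05)


def test_component_fraction_conventions_agree_for_constant_share():
    # When local/total is constant in time, both reporting conventions match.
    idx = pd.date_range("2021-05-17", periods=3600, freq="1s", tz="UTC")
    total = pd.Series(10.0, index=idx)
    part = pd.DataFrame(
        {"total": total, "background": 0.75 * total,
         "longer_lived": 0.05 * total, "short_lived": 0.20 * total}
    )
    fractions = component_fractions(part)
    assert fractions["short_lived"]["ratio_of_means"] == pytest.approx(0.20)
    assert fractions["short_lived"]["mean_of_ratios"] == pytest.approx(0.20)
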