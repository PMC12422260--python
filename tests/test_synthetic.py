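"""Statistical structure of the synthetic campaign generator."""

import math
from dataclasses import replace

import numpy as np
import pytest

from ghgflux.errors import ConfigurationError
from ghgflux.synthetic import (
    DECAY_LENGTH_80PCT,
    PRESETS,
    ScenarioConfig,
    generate,
    generate_estuary_timeseries,
    generate_reservoir,
    generate_river_transect,
)


# --- determinism and physical bounds --------------------------------------


@pytest.mark.parametrize("preset", sorted(PRESETS))
def test_fixed_seed_reproduces_identical_tables(preset):
    cfg = replace(PRESETS[preset], seed=42)
    s1, w1 = generate(cfg)
    s2, w2 = generate(cfg)
    assert s1.equals(s2)
    assert w1.equals(w2)


@pytest.mark.parametrize("preset", sorted(PRESETS))
def test_physical_bounds(preset):
    samples, wind = generate(replace(PRESETS[preset], seed=7))
    assert samples["do_pct"].between(0.0, 120.0).all()
    assert samples["salinity"].between(0.0, 36.0).all()
    assert (samples["value"] > 0).all()
    assert (wind["speed_ms"] >= 0).all()


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        ScenarioConfig(waterbody="lagoon")
    with pytest.raises(ConfigurationError):
        ScenarioConfig(tide_range_m=0.0)


# --- reservoir ------------------------------------------------------------


def test_reservoir_stratification_and_hypoxia():
    cfg = replace(PRESETS["reservoir_dry"], seed=3, n_stations=5, n_depths=12)
    samples, _ = generate_reservoir(cfg)
    co2 = samples[samples.species == "CO2"]
    surface = co2[co2.depth_m <= 1.0]
    deep = co2[co2.depth_m >= 100.0]
    assert surface.temp_c.between(*cfg.surface_temp_range).all()
    # ~5 degC surface-bottom contrast
    assert surface.temp_c.mean() - deep.temp_c.mean() == pytest.approx(5.0, abs=1.0)
    assert deep.do_pct.mean() < 20.0  # hypoxic hypolimnion


def test_reservoir_bottom_ch4_distribution_clt():
    """10^4 hypolimnion draws land within 3 sigma/sqrt(n) of the 621 uM mean."""
    cfg = ScenarioConfig(waterbody="reservoir")
    rng = np.random.default_rng(11)
    from ghgflux.synthetic import _lognormal_from_mean_sd

    draws = _lognormal_from_mean_sd(
        rng, cfg.bottom_ch4_mean_um, cfg.bottom_ch4_sd_um, size=10_000
    )
    se = cfg.bottom_ch4_sd_um / math.sqrt(10_000)
    assert abs(draws.mean() - cfg.bottom_ch4_mean_um) < 3.0 * se
    # and the generated reservoir's own hypolimnion rows are on-distribution
    samples, _ = generate_reservoir(replace(cfg, seed=5, n_stations=10, n_depths=14))
    bottom = samples[(samples.species == "CH4") & (samples.depth_m >= cfg.hypoxia_depth_m)]
    n = len(bottom)
    assert n >= 20
    assert abs(bottom.value.mean() - 621.0) < 3.0 * 187.0 / math.sqrt(n)


def test_wet_season_wind_ratio():
    """Monthly wet:dry wind-speed means sit near the configured 1.3 ratio."""
    wet = replace(PRESETS["reservoir_wet"], seed=1, n_wind_days=2000)
    dry = replace(PRESETS["reservoir_dry"], seed=2, n_wind_days=2000)
    _, wind_wet = generate_reservoir(wet)
    _, wind_dry = generate_reservoir(dry)
    ratio = wind_wet.speed_ms.mean() / wind_dry.speed_ms.mean()
    assert ratio == pytest.approx(1.3, abs=0.05)


# --- river ----------------------------------------------------------------


def test_zero_noise_gives_exact_80pct_decline_by_station_4():
    cfg = ScenarioConfig(waterbody="river", noise_log_sd=0.0)
    samples, _ = generate_river_transect(cfg)
    ch4 = samples[samples.species == "CH4"].set_index("station")["value"]
    assert ch4["L4"] / ch4["L1"] == pytest.approx(0.2, rel=1e-12)


def test_no_hotspot_gives_monotone_profile():
    cfg = ScenarioConfig(
        waterbody="river", noise_log_sd=0.0, hotspot_ch4_um=0.0, hotspot_co2_um=0.0
    )
    samples, _ = generate_river_transect(cfg)
    for species in ("CH4", "CO2"):
        vals = samples[samples.species == species]["value"].to_numpy()
        assert (np.diff(vals) < 0).all()


def test_hotspot_raises_midriver_concentrations():
    flat = ScenarioConfig(waterbody="river", noise_log_sd=0.0, hotspot_ch4_um=0.0)
    bump = ScenarioConfig(waterbody="river", noise_log_sd=0.0, hotspot_ch4_um=4.0)
    ch4_flat, _ = generate_river_transect(flat)
    ch4_bump, _ = generate_river_transect(bump)
    get = lambda df, st: df[(df.species == "CH4") & (df.station == st)].value.iloc[0]
    assert get(ch4_bump, "L8") > get(ch4_flat, "L8")
    # bump is compactly supported: upstream stations untouched
    assert get(ch4_bump, "L4") == pytest.approx(get(ch4_flat, "L4"), rel=1e-12)


def test_ensemble_mean_recovers_decay_length():
    """Log-linear fit of the mean hotspot-free profile (stations 1-6) over
    500 noisy transects recovers the decay constant within 5%."""
    cfg = ScenarioConfig(waterbody="river", seed=9, n_transects=500)
    samples, _ = generate_river_transect(cfg)
    ch4 = samples[samples.species == "CH4"]
    prof = ch4.groupby("station")["value"].mean()
    stations = np.arange(1, 7)
    y = np.log([prof[f"L{i}"] for i in stations])
    slope = np.polyfit(stations - 1, y, 1)[0]
    recovered = -1.0 / slope
    assert recovered == pytest.approx(DECAY_LENGTH_80PCT, rel=0.05)


# --- estuary --------------------------------------------------------------


def test_pure_marine_endmember_returns_endmember_values():
    cfg = ScenarioConfig(
        waterbody="estuary", marine_weight=1.0, estuary_noise_log_sd=0.0
    )
    samples, _ = generate_estuary_timeseries(cfg)
    co2 = samples[samples.species == "CO2"]["value"]
    ch4 = samples[samples.species == "CH4"]["value"]
    assert np.allclose(co2, cfg.marine_co2_um)
    assert np.allclose(ch4, cfg.marine_ch4_um)
    assert np.allclose(samples["salinity"], cfg.marine_salinity)


def test_tide_range_matches_configuration():
    cfg = ScenarioConfig(waterbody="estuary", tide_range_m=2.9)
    samples, _ = generate_estuary_timeseries(cfg)
    tide = samples["tide_m"]
    assert tide.max() - tide.min() == pytest.approx(2.9, rel=1e-12)


def test_salinity_anticorrelated_with_gas():
    samples, _ = generate_estuary_timeseries(
        ScenarioConfig(waterbody="estuary", seed=4)
    )
    co2 = samples[samples.species == "CO2"]
    r = np.corrcoef(co2["salinity"], co2["value"])[0, 1]
    assert r < -0.8


def test_mixing_line_slope_recovery():
    """Pooled regression of CO2 on salinity over 200 series recovers the
    conservative-mixing slope within 5%."""
    cfg = ScenarioConfig(waterbody="estuary")
    sal_all, co2_all = [], []
    for seed in range(200):
        samples, _ = generate_estuary_timeseries(replace(cfg, seed=seed))
        co2 = samples[samples.species == "CO2"]
        sal_all.append(co2["salinity"].to_numpy())
        co2_all.append(co2["value"].to_numpy())
    sal = np.concatenate(sal_all)
    conc = np.concatenate(co2_all)
    slope = np.polyfit(sal, conc, 1)[0]
    expected = (cfg.marine_co2_um - cfg.river_end_co2_um) / cfg.marine_salinity
    assert slope == pytest.approx(expected, rel=0.05)


def test_two_hourly_cadence_over_24h():
    samples, _ = generate_estuary_timeseries(ScenarioConfig(waterbody="estuary"))
    times = samples[samples.species == "CO2"]["datetime"]
    assert len(times) == 13  # 0..24 h inclusive at 2-h cadence
    deltas = times.diff().dropna().dt.total_seconds() / 3600.0
    assert np.allclose(deltas, 2.0)
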