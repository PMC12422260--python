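"""Synthetic field campaigns with the statistical structure the pipeline assumes.

The generator is statistical, not mechanistic: it emulates the features of
a tropical reservoir-river-estuary continuum that the downstream analysis
depends on, so the whole chain is testable without the original raw data:

- a thermally stratified reservoir (~5 deg C surface-bottom contrast) with
  a hypoxic hypolimnion below ~40 m and a CH4-rich bottom layer
  (default mean 621 +/- 187 umol L^-1);
- exponential downstream decay of dam-outlet CH4 tuned so the fourth river
  station retains 20% of the outlet value (~80% loss), plus a mid-river
  concentration bump over the sand-extraction reach (stations 7-10);
- estuarine conservative mixing against a low-gas marine endmember under
  sinusoidal tidal forcing, sampled two-hourly over 24 h;
- seasonal wind regimes with a wet:dry monthly-mean ratio of 1.3.

Concentration noise is lognormal (right-skewed, strictly positive, mean
one), so ensemble means recover the deterministic skeleton.  All
randomness flows from a single integer seed through
``numpy.random.default_rng``; identical configs give identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .gas_physics import GasSpecies
from .headspace import equilibrate

__all__ = [
    "ScenarioConfig",
    "PRESETS",
    "generate",
    "generate_reservoir",
    "generate_river_transect",
    "generate_estuary_timeseries",
    "as_headspace_table",
]

#: Decay length (in station units) giving an exact 80% decline by station 4.
DECAY_LENGTH_80PCT = 3.0 / math.log(5.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of the campaign generator, with study-scale defaults."""

    waterbody: str = "reservoir"  # reservoir | river | estuary
    season: str = "dry"  # wet | dry
    seed: int = 0
    n_stations: int = 7
    n_depths: int = 8

    # reservoir concentration model (umol L^-1)
    surface_co2_mean_um: float = 230.0
    surface_co2_log_sd: float = 0.45
    surface_ch4_mean_um: float = 1.5
    surface_ch4_log_sd: float = 0.6
    bottom_ch4_mean_um: float = 621.0
    bottom_ch4_sd_um: float = 187.0

    # reservoir physics
    surface_temp_range: tuple[float, float] = (28.5, 30.5)
    stratification_delta_c: float = 5.0
    thermocline_depth_m: float = 20.0
    hypoxia_depth_m: float = 40.0
    min_station_depth_m: float = 40.0
    max_station_depth_m: float = 140.0

    # river transect model
    n_river_stations: int = 13
    n_transects: int = 1
    outlet_ch4_um: float = 20.0
    outlet_co2_um: float = 150.0
    baseline_co2_um: float = 90.0
    decay_length_stations: float = DECAY_LENGTH_80PCT
    hotspot_start: int = 7
    hotspot_end: int = 10
    hotspot_ch4_um: float = 4.0
    hotspot_co2_um: float = 60.0
    noise_log_sd: float = 0.3

    # wind model (monthly means at 10 m)
    dry_wind_mean_ms: float = 2.0
    wet_dry_wind_ratio: float = 1.3
    wind_sd_ms: float = 0.6
    wind_height_m: float = 10.0
    n_wind_days: int = 30

    # estuary / tide model
    tide_range_m: float = 1.85  # trough-to-crest
    tide_period_h: float = 12.42
    duration_h: float = 24.0
    sampling_interval_h: float = 2.0
    marine_salinity: float = 32.0
    marine_co2_um: float = 13.0
    marine_ch4_um: float = 0.005
    river_end_co2_um: float = 150.0
    river_end_ch4_um: float = 6.0
    estuary_noise_log_sd: float = 0.15
    marine_weight: float | None = None  # fix the mixing fraction (tests)

    def __post_init__(self) -> None:
        positive = (
            "surface_co2_mean_um", "surface_ch4_mean_um", "bottom_ch4_mean_um",
            "bottom_ch4_sd_um", "outlet_ch4_um", "outlet_co2_um",
            "baseline_co2_um", "decay_length_stations", "dry_wind_mean_ms",
            "wet_dry_wind_ratio", "wind_sd_ms", "wind_height_m",
            "tide_range_m", "tide_period_h", "marine_salinity",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.waterbody not in ("reservoir", "river", "estuary"):
            raise ConfigurationError(f"unknown waterbody {self.waterbody!r}")
        if self.season not in ("wet", "dry"):
            raise ConfigurationError(f"unknown season {self.season!r}")


#: Campaign presets named after the study design.
PRESETS: dict[str, ScenarioConfig] = {
    "reservoir_wet": ScenarioConfig(waterbody="reservoir", season="wet"),
    "reservoir_dry": ScenarioConfig(waterbody="reservoir", season="dry"),
    "river_high_discharge": ScenarioConfig(
        waterbody="river", season="wet", outlet_ch4_um=20.0, outlet_co2_um=150.0
    ),
    "river_low_discharge": ScenarioConfig(
        waterbody="river", season="dry", outlet_ch4_um=3.0, outlet_co2_um=120.0
    ),
    "estuary_spring": ScenarioConfig(waterbody="estuary", season="dry", tide_range_m=2.9),
    "estuary_neap": ScenarioConfig(waterbody="estuary", season="dry", tide_range_m=0.8),
}

_SEASON_MONTH = {"wet": 11, "dry": 5}


def _lognormal(rng: np.random.Generator, mean: float, log_sd: float, size=None):
    """Lognormal draws with the requested *arithmetic* mean."""
    mu = math.log(mean) - 0.5 * log_sd**2
    return rng.lognormal(mu, log_sd, size)


def _lognormal_from_mean_sd(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Lognormal draws matching an arithmetic mean and standard deviation."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _noise(rng: np.random.Generator, log_sd: float, size=None):
    """Mean-one multiplicative lognormal noise (deterministic 1 at sd=0)."""
    if log_sd == 0:
        return 1.0 if size is None else np.ones(size)
    return rng.lognormal(-0.5 * log_sd**2, log_sd, size)


def _wind_table(cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Daily wind speeds for the campaign month, truncated normal at zero."""
    mean = cfg.dry_wind_mean_ms * (cfg.wet_dry_wind_ratio if cfg.season == "wet" else 1.0)
    a = (0.0 - mean) / cfg.wind_sd_ms
    speeds = stats.truncnorm.rvs(
        a, np.inf, loc=mean, scale=cfg.wind_sd_ms, size=cfg.n_wind_days,
        random_state=rng,
    )
    month = _SEASON_MONTH[cfg.season]
    start = datetime(2018, month, 1)
    return pd.DataFrame(
        {
            "waterbody": cfg.waterbody,
            "datetime": [start + timedelta(days=int(d)) for d in range(cfg.n_wind_days)],
            "speed_ms": speeds,
            "height_m": cfg.wind_height_m,
        }
    )


def _sample_rows(station, waterbody, when, depth, temp, sal, do, conc_by_species):
    rows = []
    for species, value in conc_by_species.items():
        rows.append(
            {
                "station": station,
                "waterbody": waterbody,
                "datetime": when,
                "depth_m": depth,
                "temp_c": temp,
                "salinity": sal,
                "do_pct": do,
                "species": species,
                "value": value,
                "value_kind": "concentration_uM",
            }
        )
    return rows


def generate_reservoir(cfg: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Depth-profiled reservoir campaign plus its monthly wind table.

    Surface temperatures are uniform over the configured range; the
    thermocline is a logistic ramp losing ``stratification_delta_c`` by the
    bottom.  Oxygen saturation collapses below the hypoxia depth.  Surface
    CO2/CH4 are lognormal at the configured means; below the hypoxia depth
    CH4 switches to the hypolimnion distribution (mean 621, sd 187 by
    default).
    """
    rng = np.random.default_rng(cfg.seed)
    month = _SEASON_MONTH[cfg.season]
    when = datetime(2018, month, 15, 10, 0)
    bottom_depths = np.linspace(
        cfg.min_station_depth_m, cfg.max_station_depth_m, cfg.n_stations
    )
    rows: list[dict] = []
    for i, bottom in enumerate(bottom_depths, start=1):
        t_surf = rng.uniform(*cfg.surface_temp_range)
        do_surf = float(np.clip(rng.normal(95.0, 5.0), 0.0, 120.0))
        depths = np.linspace(0.5, bottom, cfg.n_depths)
        for z in depths:
            frac = 1.0 / (1.0 + math.exp(-(z - cfg.thermocline_depth_m) / 5.0))
            temp = t_surf - cfg.stratification_delta_c * frac
            do = do_surf / (1.0 + math.exp((z - cfg.hypoxia_depth_m) / 4.0))
            do = float(np.clip(do + rng.normal(0.0, 2.0), 0.0, 120.0))
            co2 = float(
                _lognormal(rng, cfg.surface_co2_mean_um * (1.0 + z / bottom), cfg.surface_co2_log_sd)
            )
            if z >= cfg.hypoxia_depth_m:
                ch4 = float(
                    _lognormal_from_mean_sd(rng, cfg.bottom_ch4_mean_um, cfg.bottom_ch4_sd_um)
                )
            else:
                ch4 = float(_lognormal(rng, cfg.surface_ch4_mean_um, cfg.surface_ch4_log_sd))
            rows.extend(
                _sample_rows(
                    f"S{i}", "reservoir", when, round(float(z), 2), temp, 0.0, do,
                    {"CO2": co2, "CH4": ch4},
                )
            )
    return pd.DataFrame(rows), _wind_table(cfg, rng)


def _hotspot_bump(i: int, start: int, end: int, amplitude: float) -> float:
    """Compactly supported raised-cosine bump over stations [start, end]."""
    if amplitude == 0 or not start <= i <= end:
        return 0.0
    phase = (i - start) / (end - start)
    return amplitude * 0.5 * (1.0 - math.cos(2.0 * math.pi * phase))


def generate_river_transect(cfg: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Surface transect(s) over the river stations L1..L13.

    The deterministic skeleton is an exponential decay from the dam-outlet
    value (CH4 falls to 20% of the outlet by station 4 at the default decay
    length) with an additive sand-extraction bump over stations 7-10; the
    bump is identically zero outside that reach, so a zero-amplitude
    configuration is strictly monotone decreasing.
    """
    rng = np.random.default_rng(cfg.seed)
    month = _SEASON_MONTH[cfg.season]
    rows: list[dict] = []
    for tr in range(cfg.n_transects):
        when = datetime(2018, month, 1, 9, 0) + timedelta(days=tr)
        for i in range(1, cfg.n_river_stations + 1):
            decay = math.exp(-(i - 1) / cfg.decay_length_stations)
            ch4_skeleton = cfg.outlet_ch4_um * decay + _hotspot_bump(
                i, cfg.hotspot_start, cfg.hotspot_end, cfg.hotspot_ch4_um
            )
            co2_skeleton = (
                cfg.baseline_co2_um
                + (cfg.outlet_co2_um - cfg.baseline_co2_um) * decay
                + _hotspot_bump(i, cfg.hotspot_start, cfg.hotspot_end, cfg.hotspot_co2_um)
            )
            ch4 = float(ch4_skeleton * _noise(rng, cfg.noise_log_sd))
            co2 = float(co2_skeleton * _noise(rng, cfg.noise_log_sd))
            temp = float(rng.uniform(27.0, 30.0))
            do = float(np.clip(72.0 - 31.0 * decay + rng.normal(0.0, 3.0), 0.0, 120.0))
            rows.extend(
                _sample_rows(
                    f"L{i}", "river", when, 0.5, temp, 0.0, do,
                    {"CO2": co2, "CH4": ch4},
                )
            )
    return pd.DataFrame(rows), _wind_table(cfg, rng)


def generate_estuary_timeseries(cfg: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """24-h estuary station under sinusoidal tidal forcing.

    Salinity tracks the tide through the marine mixing fraction; gas
    concentrations sit on the conservative mixing line between the river
    and marine endmembers (times mean-one lognormal noise).  The sampled
    tide heights are rescaled so the realized trough-to-crest range equals
    ``tide_range_m`` exactly.  Extra column ``tide_m`` carries the tide.
    """
    rng = np.random.default_rng(cfg.seed)
    times = np.arange(0.0, cfg.duration_h + 1e-9, cfg.sampling_interval_h)
    raw = np.sin(2.0 * math.pi * times / cfg.tide_period_h)
    span = raw.max() - raw.min()
    tide = (raw - raw.min()) / span * cfg.tide_range_m - cfg.tide_range_m / 2.0
    rows: list[dict] = []
    start = datetime(2019, 4 if cfg.season == "dry" else 8, 10, 0, 0)
    for t, h in zip(times, tide):
        if cfg.marine_weight is not None:
            f = cfg.marine_weight
        else:
            f = 0.5 + 0.45 * (2.0 * h / cfg.tide_range_m)
        f = float(np.clip(f, 0.0, 1.0))
        sal = f * cfg.marine_salinity
        co2 = (f * cfg.marine_co2_um + (1 - f) * cfg.river_end_co2_um) * float(
            _noise(rng, cfg.estuary_noise_log_sd)
        )
        ch4 = (f * cfg.marine_ch4_um + (1 - f) * cfg.river_end_ch4_um) * float(
            _noise(rng, cfg.estuary_noise_log_sd)
        )
        temp = float(rng.uniform(28.0, 31.0))
        do = float(np.clip(rng.normal(80.0, 10.0), 0.0, 120.0))
        when = start + timedelta(hours=float(t))
        for row in _sample_rows(
            "E1", "estuary", when, 0.5, temp, sal, do, {"CO2": co2, "CH4": ch4}
        ):
            row["tide_m"] = float(h)
            rows.append(row)
    return pd.DataFrame(rows), _wind_table(cfg, rng)


def generate(cfg: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dispatch to the generator for ``cfg.waterbody``."""
    if cfg.waterbody == "reservoir":
        return generate_reservoir(cfg)
    if cfg.waterbody == "river":
        return generate_river_transect(cfg)
    return generate_estuary_timeseries(cfg)


def as_headspace_table(
    samples: pd.DataFrame, equilibration_temperature: float = 25.0
) -> pd.DataFrame:
    """Forward-simulate headspacing of a concentration table.

    Replaces each ``concentration_uM`` value with the GC mole fraction
    (ppm) an equilibrated serum bottle would read, setting ``value_kind``
    to ``headspace_ppm``.  Used by the end-to-end round-trip tests and for
    exercising the raw-GC ingestion path.
    """
    out = samples.copy()
    ppm = []
    for row in out.itertuples(index=False):
        m = equilibrate(
            row.value,
            GasSpecies(row.species),
            equilibration_temperature=equilibration_temperature,
            equilibration_salinity=row.salinity,
        )
        ppm.append(m.headspace_mole_fraction)
    out["value"] = ppm
    out["value_kind"] = "headspace_ppm"
    return out
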