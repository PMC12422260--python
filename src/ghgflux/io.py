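"""Readers, writers and run configuration.

All tables are delimiter-separated text (CSV) with documented headers and
round-trip losslessly through the paired reader/writer.  The sample table
schema is::

    station, waterbody, datetime (ISO-8601), depth_m, temp_c, salinity,
    do_pct, species (CO2|CH4), value, value_kind

where ``value_kind`` is ``concentration_uM`` for a dissolved concentration
in umol L^-1 or ``headspace_ppm`` for a raw GC headspace mole fraction that
the pipeline routes through the headspace back-calculation.

Run configuration is a pydantic model loaded from YAML; unknown keys are
rejected and referenced paths must exist at load time.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .budget import GWP_CH4, Segment, WaterbodyGeometry
from .errors import ConfigurationError, SchemaError
from .fluxes import DEFAULT_ATM_PARTIAL_PRESSURE, DEFAULT_SURFACE_DEPTH_M

__all__ = [
    "SAMPLE_COLUMNS",
    "WIND_COLUMNS",
    "RunConfig",
    "read_samples",
    "write_samples",
    "read_wind",
    "write_wind",
    "read_geometry",
    "read_flux_table",
    "write_flux_table",
]

SAMPLE_COLUMNS = [
    "station", "waterbody", "datetime", "depth_m", "temp_c",
    "salinity", "do_pct", "species", "value", "value_kind",
]
WIND_COLUMNS = ["waterbody", "datetime", "speed_ms", "height_m"]

_VALUE_KINDS = {"concentration_uM", "headspace_ppm"}
_SPECIES = {"CO2", "CH4"}
_WATERBODIES = {"reservoir", "river", "estuary"}


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")


def read_samples(path: str | Path, skip_bad_rows: bool = False) -> pd.DataFrame:
    """Read and validate a sample table.

    Row-level problems (unparsable numbers or timestamps, unknown species
    or value kinds) are collected with their file line numbers; by default
    any bad row aborts the read, with ``skip_bad_rows`` they are dropped
    and reported in a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, SAMPLE_COLUMNS, path)
    if df.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
        return df.assign(
            **{c: pd.Series(dtype=float) for c in
               ("depth_m", "temp_c", "salinity", "do_pct", "value")}
        )

    errors: list[str] = []
    out = df.copy()
    numeric = ["depth_m", "temp_c", "salinity", "do_pct", "value"]
    for col in numeric:
        out[col] = pd.to_numeric(out[col], errors="coerce")
    out["datetime"] = pd.to_datetime(df["datetime"], errors="coerce", format="ISO8601")

    for idx in out.index:
        # +2: one for the header line, one for 0-based indexing
        line = idx + 2
        problems = [c for c in numeric if pd.isna(out.at[idx, c])]
        if pd.isna(out.at[idx, "datetime"]):
            problems.append("datetime")
        if df.at[idx, "species"] not in _SPECIES:
            problems.append("species")
        if df.at[idx, "value_kind"] not in _VALUE_KINDS:
            problems.append("value_kind")
        if df.at[idx, "waterbody"] not in _WATERBODIES:
            problems.append("waterbody")
        if problems:
            errors.append(f"line {line}: bad field(s) {problems}")

    if errors:
        summary = "; ".join(errors)
        if not skip_bad_rows:
            raise SchemaError(f"{path}: {summary}")
        warnings.warn(f"{path}: skipped rows -> {summary}", stacklevel=2)
        bad_lines = {int(e.split()[1].rstrip(":")) - 2 for e in errors}
        out = out.drop(index=sorted(bad_lines)).reset_index(drop=True)
    return out


def _iso_datetime(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["datetime"] = pd.to_datetime(out["datetime"], format="ISO8601").map(
        lambda t: t.isoformat()
    )
    return out


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    cols = SAMPLE_COLUMNS + [c for c in df.columns if c not in SAMPLE_COLUMNS]
    _iso_datetime(df).to_csv(path, index=False, columns=cols)


def read_wind(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, WIND_COLUMNS, path)
    df["datetime"] = pd.to_datetime(df["datetime"], format="ISO8601")
    return df


def write_wind(df: pd.DataFrame, path: str | Path) -> None:
    _iso_datetime(df).to_csv(path, index=False, columns=WIND_COLUMNS)


def read_geometry(path: str | Path) -> dict[str, WaterbodyGeometry]:
    """Load waterbody geometry (areas km^2, optional segment maps) from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: geometry file must map waterbody -> properties")
    geometry = {}
    for name, props in raw.items():
        segments = tuple(
            Segment(
                segment_id=str(s["id"]),
                stations=tuple(s["stations"]),
                source_class=s["source_class"],
                area_fraction=float(s["area_fraction"]),
            )
            for s in props.get("segments", [])
        )
        geometry[name] = WaterbodyGeometry(
            name=name,
            surface_area=float(props["surface_area_km2"]),
            segments=segments,
        )
    return geometry


FLUX_COLUMNS = [
    "station", "waterbody", "datetime", "species", "concentration_uM",
    "temp_c", "salinity", "u10_ms", "schmidt", "k600_codes", "n_exponent",
    "k_cm_h", "p_water_uatm", "p_atm_uatm", "flux_mmol_m2_d",
]


def read_flux_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, FLUX_COLUMNS, path)
    df["datetime"] = pd.to_datetime(df["datetime"], format="ISO8601")
    return df


def write_flux_table(df: pd.DataFrame, path: str | Path) -> None:
    _iso_datetime(df).to_csv(path, index=False, columns=FLUX_COLUMNS)


class Policies(BaseModel):
    """Per-run analysis policies with the package defaults."""

    model_config = ConfigDict(extra="forbid")

    k600: str = "auto"  # one code, comma list, or the per-waterbody policy
    atm_pco2_uatm: float = DEFAULT_ATM_PARTIAL_PRESSURE["CO2"]
    atm_pch4_uatm: float = DEFAULT_ATM_PARTIAL_PRESSURE["CH4"]
    gwp: float = GWP_CH4
    surface_depth_m: float = DEFAULT_SURFACE_DEPTH_M
    statistic: str = "mean"  # campaign central value: mean | median
    equilibration_temperature_c: float = 25.0

    @field_validator("statistic")
    @classmethod
    def _check_statistic(cls, v: str) -> str:
        if v not in ("mean", "median"):
            raise ValueError(f"statistic must be mean or median, got {v!r}")
        return v


class RunConfig(BaseModel):
    """Full pipeline configuration (paths + policies + reproducibility)."""

    model_config = ConfigDict(extra="forbid")

    samples: Path
    wind: Path
    geometry: Path
    registry: Path | None = None  # k600 registry override
    output_dir: Path | None = None
    policies: Policies = Field(default_factory=Policies)
    skip_bad_rows: bool = False
    seed: int = 0
    verbosity: int = 1

    @field_validator("samples", "wind", "geometry", "registry")
    @classmethod
    def _must_exist(cls, v: Path | None) -> Path | None:
        if v is not None and not Path(v).exists():
            raise ValueError(f"path does not exist: {v}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.model_validate(raw)
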