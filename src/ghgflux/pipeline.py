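"""The end-to-end computation chain: concentrations -> k -> flux -> budget.

Stage order and provenance: raw headspace rows are first back-calculated to
dissolved concentrations; the shallowest sample per station/cast supplies
the surface concentration; wind is matched by calendar month and
extrapolated to 10 m; the per-waterbody k600 policy and Schmidt-exponent
rule produce k_i; the bulk flux equation yields the per-station flux table;
campaign aggregates and waterbody areas close the CO2-equivalent budget.
Every flux row carries the parameterization codes and n exponent used.
Identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from . import io as ghg_io
from .budget import BudgetTable, catchment_budget, source_attribution
from .errors import ConfigurationError, GHGFluxError
from .fluxes import FluxEstimate, aggregate_campaign, diffusive_flux
from .gas_physics import (
    GasSpecies,
    WaterState,
    concentration_to_partial_pressure,
    schmidt_number,
    solubility,
)
from .headspace import HeadspaceMeasurement, dissolved_concentration
from .transfer_velocity import (
    DEFAULT_RULES,
    WindRecord,
    ensemble_k,
    extrapolate_u10,
    load_registry,
    params_for_waterbody,
)

__all__ = [
    "PipelineResult",
    "compute_concentrations",
    "compute_fluxes",
    "budget_from_fluxes",
    "run_pipeline",
]

log = logging.getLogger("ghgflux")


def compute_concentrations(
    samples: pd.DataFrame, equilibration_temperature: float = 25.0
) -> pd.DataFrame:
    """Convert any ``headspace_ppm`` rows to dissolved concentrations.

    Rows already expressed as ``concentration_uM`` pass through unchanged;
    headspace rows are back-calculated at the configured lab temperature
    and the sample's salinity.
    """
    out = samples.copy()
    mask = out["value_kind"] == "headspace_ppm"
    if mask.any():
        log.info("headspace back-calculation: %d rows at %s degC lab temperature",
                 int(mask.sum()), equilibration_temperature)
    values = []
    for row in out.loc[mask].itertuples(index=False):
        m = HeadspaceMeasurement(
            species=GasSpecies(row.species),
            headspace_mole_fraction=float(row.value),
            equilibration_temperature=equilibration_temperature,
            equilibration_salinity=float(row.salinity),
        )
        values.append(dissolved_concentration(m))
    out.loc[mask, "value"] = values
    out.loc[mask, "value_kind"] = "concentration_uM"
    return out


def _monthly_u10(wind: pd.DataFrame) -> pd.DataFrame:
    """Monthly-mean u10 per waterbody from a wind table."""
    u10 = [
        extrapolate_u10(WindRecord(speed=row.speed_ms, height=row.height_m))
        for row in wind.itertuples(index=False)
    ]
    monthly = wind.assign(u10=u10)
    monthly["month"] = monthly["datetime"].dt.to_period("M")
    return monthly.groupby(["waterbody", "month"], as_index=False)["u10"].mean()


def _select_params(policy: str, waterbody: str, registry):
    if policy == "auto":
        return params_for_waterbody(waterbody, registry)
    codes = [c.strip() for c in policy.split(",") if c.strip()]
    missing = [c for c in codes if c not in registry]
    if missing:
        raise ConfigurationError(
            f"k600 codes {missing} not in registry {sorted(registry)}"
        )
    return [registry[c] for c in codes]


def compute_fluxes(
    concentrations: pd.DataFrame,
    wind: pd.DataFrame,
    registry=None,
    k600_policy: str = "auto",
    atm_uatm: dict[str, float] | None = None,
    surface_depth_m: float = 1.0,
) -> pd.DataFrame:
    """Per-station diffusive fluxes from a concentration and a wind table.

    Surface concentration is the shallowest sample at or above
    ``surface_depth_m`` for each (station, species, timestamp).  Wind is
    matched by waterbody and calendar month, falling back to the
    waterbody's overall mean u10 when the month is absent.
    """
    from .fluxes import DEFAULT_ATM_PARTIAL_PRESSURE

    registry = registry if registry is not None else load_registry()
    atm = atm_uatm or DEFAULT_ATM_PARTIAL_PRESSURE
    monthly = _monthly_u10(wind)
    fallback_u10 = monthly.groupby("waterbody")["u10"].mean()

    surf = concentrations[
        (concentrations["value_kind"] == "concentration_uM")
        & (concentrations["depth_m"] <= surface_depth_m)
    ].copy()
    surf = (
        surf.sort_values("depth_m", kind="stable")
        .groupby(["waterbody", "station", "species", "datetime"], as_index=False)
        .first()
    )

    rows = []
    for row in surf.itertuples(index=False):
        waterbody = row.waterbody
        params = _select_params(k600_policy, waterbody, registry)
        month = pd.Period(row.datetime, freq="M")
        match = monthly[
            (monthly["waterbody"] == waterbody) & (monthly["month"] == month)
        ]
        if len(match):
            u10 = float(match["u10"].iloc[0])
        elif waterbody in fallback_u10.index:
            u10 = float(fallback_u10.loc[waterbody])
            log.info("no wind for %s %s; using waterbody mean u10", waterbody, month)
        else:
            raise ConfigurationError(f"no wind data for waterbody {waterbody!r}")

        species = GasSpecies(row.species)
        state = WaterState(temperature=row.temp_c, salinity=row.salinity)
        sc = schmidt_number(species, state)
        rule = DEFAULT_RULES[waterbody]
        ens = ensemble_k(params, u10, sc, rule)
        k_sol = solubility(species, state)
        p_water = concentration_to_partial_pressure(row.value, species, state)
        p_atm = atm[species.value]
        flux = diffusive_flux(ens.mean, k_sol, p_water, p_atm)
        rows.append(
            {
                "station": row.station,
                "waterbody": waterbody,
                "datetime": row.datetime,
                "species": species.value,
                "concentration_uM": row.value,
                "temp_c": row.temp_c,
                "salinity": row.salinity,
                "u10_ms": u10,
                "schmidt": sc,
                "k600_codes": "+".join(sorted(ens.members)),
                "n_exponent": ens.n_exponent,
                "k_cm_h": ens.mean,
                "p_water_uatm": p_water,
                "p_atm_uatm": p_atm,
                "flux_mmol_m2_d": flux,
            }
        )
    return pd.DataFrame(rows, columns=ghg_io.FLUX_COLUMNS)


def budget_from_fluxes(
    flux_table: pd.DataFrame,
    geometry,
    gwp: float,
    statistic: str = "mean",
) -> BudgetTable:
    """Aggregate a flux table per waterbody and close the catchment budget.

    Waterbodies whose geometry defines a segment map additionally get a
    source-class attribution computed from per-station mean fluxes.
    """
    areal: dict[str, dict[str, float]] = {}
    for (waterbody, species), group in flux_table.groupby(["waterbody", "species"]):
        estimates = [
            FluxEstimate(
                station=r.station,
                species=GasSpecies(species),
                flux=r.flux_mmol_m2_d,
                k_i=r.k_cm_h,
                p_water=r.p_water_uatm,
                p_atm=r.p_atm_uatm,
            )
            for r in group.itertuples(index=False)
        ]
        summary = aggregate_campaign(estimates, statistic=statistic)
        areal.setdefault(waterbody, {})[species] = summary.central

    result = catchment_budget(areal, geometry, gwp=gwp)

    attribution: dict[str, dict[str, float]] = {}
    for name, geom in geometry.items():
        if not geom.segments:
            continue
        sub = flux_table[flux_table["waterbody"] == name]
        for species in sub["species"].unique():
            per_station = (
                sub[sub["species"] == species]
                .groupby("station")["flux_mmol_m2_d"]
                .mean()
                .to_dict()
            )
            attribution[f"{name}/{species}"] = source_attribution(
                per_station, geom.segments
            )
    if attribution:
        result = replace(result, attribution_pct=attribution)
    return result


def _render_report(budget: BudgetTable) -> str:
    lines = ["# Catchment CO2-equivalent budget", ""]
    lines.append(budget.table.to_string(float_format=lambda v: f"{v:.4g}"))
    lines.append("")
    lines.append(f"Total: {budget.total_co2eq_gg_yr:.1f} Gg CO2-eq yr^-1 "
                 f"(GWP_CH4 = {budget.gwp:g}, mass basis, 365 d)")
    shares = ", ".join(f"{w} {s:.1f}%" for w, s in budget.shares_pct.items())
    lines.append(f"Waterbody shares: {shares}")
    split = ", ".join(f"{g} {s:.1f}%" for g, s in budget.gas_split_pct.items())
    lines.append(f"Gas split of CO2-eq: {split}")
    for key, attr in budget.attribution_pct.items():
        pretty = ", ".join(f"{c} {v:.1f}%" for c, v in attr.items())
        lines.append(f"Source attribution {key}: {pretty}")
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class PipelineResult:
    concentrations: pd.DataFrame
    fluxes: pd.DataFrame
    budget: BudgetTable
    report: str


def run_pipeline(cfg: "ghg_io.RunConfig") -> PipelineResult:
    """Run the full chain from a :class:`~ghgflux.io.RunConfig`.

    Writes ``concentrations.csv``, ``fluxes.csv``, ``budget.csv`` and
    ``report.txt`` into ``cfg.output_dir`` when set.  Failures surface as
    :class:`~ghgflux.errors.GHGFluxError` naming the failing stage.
    """
    pol = cfg.policies
    log.info(
        "run defaults: solubility CO2 Weiss-1974 / CH4 Wiesenburg-Guinasso-1979; "
        "pCO2_atm=%g uatm, pCH4_atm=%g uatm; GWP=%g (mass basis)",
        pol.atm_pco2_uatm, pol.atm_pch4_uatm, pol.gwp,
    )

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except GHGFluxError as exc:
            raise type(exc)(f"stage {name!r} failed: {exc}") from exc

    samples = _stage("read_samples", ghg_io.read_samples, cfg.samples, cfg.skip_bad_rows)
    wind = _stage("read_wind", ghg_io.read_wind, cfg.wind)
    geometry = _stage("read_geometry", ghg_io.read_geometry, cfg.geometry)
    registry = load_registry(cfg.registry) if cfg.registry else load_registry()

    conc = _stage(
        "concentrations", compute_concentrations, samples,
        pol.equilibration_temperature_c,
    )
    fluxes = _stage(
        "fluxes", compute_fluxes, conc, wind, registry,
        pol.k600, {"CO2": pol.atm_pco2_uatm, "CH4": pol.atm_pch4_uatm},
        pol.surface_depth_m,
    )
    budget = _stage(
        "budget", budget_from_fluxes, fluxes, geometry, pol.gwp, pol.statistic
    )
    report = _render_report(budget)

    if cfg.output_dir is not None:
        out = cfg.output_dir
        out.mkdir(parents=True, exist_ok=True)
        ghg_io.write_samples(conc, out / "concentrations.csv")
        ghg_io.write_flux_table(fluxes, out / "fluxes.csv")
        budget.table.to_csv(out / "budget.csv")
        (out / "report.txt").write_text(report)
    return PipelineResult(concentrations=conc, fluxes=fluxes, budget=budget, report=report)
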