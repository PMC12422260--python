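# Methods

This note documents the models, parameter choices and numerical decisions
behind `ghgflux`, and what the synthetic-data tests do and do not
demonstrate about real field data.

## Gas physics

**Solubility.** The flux equation needs the solubility constant
K (mol L⁻¹ atm⁻¹) of each gas at in-situ temperature and salinity. The
formulations are deliberately prominent because they are a modelling
choice, not a measurement: CO2 uses the Weiss (1974) fit (which yields K
directly), CH4 the Wiesenburg & Guinasso (1979) Bunsen-coefficient fit
divided by the 22.414 L mol⁻¹ ideal molar volume. Both share the form
`ln X = a1 + a2(100/T) + a3 ln(T/100) + S[b1 + b2(T/100) + b3(T/100)²]`
and live in `data/solubility_coefficients.csv` with citation strings, so
either can be swapped by pointing the loader at another table. Reference
values at 20 °C, S = 0: K(CO2) = 0.0391, K(CH4) = 1.55 × 10⁻³
mol L⁻¹ atm⁻¹.

**Schmidt numbers.** The cubic `Sc = A − Bt + Ct² − Dt³` with the
Wanninkhof (1992) coefficient sets for fresh water and 35-salinity
seawater, valid for 0–30 °C. Sc(CO2, fresh, 20 °C) = 599.42 — the anchor
of the k600 convention (600 by definition of the normalization); the CH4
freshwater value at 20 °C is 615.79. Intermediate salinities interpolate
linearly between the two coefficient sets, the only information the two
published endmember tables support. Temperatures slightly outside the fit
range (tropical surface water reaches ~30.5 °C) are **clamped** to the
nearest bound with a warning rather than extrapolating a cubic, whose
tails are not trustworthy; salinities above 35 use the seawater set.

**Unit policy.** All internal gas amounts are molar; mass appears only at
the budget boundary. Every conversion factor is defined once in
`ghgflux.units`, including the collapsed 0.24 factor of the flux unit
chain (cm h⁻¹ → m d⁻¹, mol L⁻¹ → mol m⁻³, µatm → atm, mol → mmol), which
the test suite validates against a long-form dimensional chain to 10⁻¹²
relative.

## Headspace equilibration

The protocol replaces one third of a 60 mL serum bottle with helium and
equilibrates at lab temperature (default 25 °C, configurable — field
records rarely state it). The back-calculation is a two-phase mass
balance: headspace moles by the ideal gas law at the equilibration
temperature, aqueous moles by Henry's law at the equilibrium partial
pressure, summed and divided by the water volume. Assumptions, all
documented rather than corrected for: ideal headspace behaviour (fugacity
corrections < 1% in the µatm regime), lossless preservation and
transport, no post-equilibration pressure correction. The forward
simulator `equilibrate` is a first-class operation (the synthetic module
and the round-trip tests both consume it); forward → inverse closes to
machine precision, far inside the 10⁻⁶ tolerance the tests assert.

## Transfer velocity

Wind is extrapolated to 10 m with the neutral log-profile bracket
`1 + (√0.0013/0.41)·ln(10/z)`; heights above 10 m legitimately shrink the
bracket below 1. k600(u10) relations are a plain-text registry. The
shipped defaults are **best-effort reconstructions** of the commonly used
lake and estuary relations — Cole & Caraco (1998) and Crusius &
Wanninkhof (2003) for lakes, Raymond & Cole (2001) and a wind-only Borges
et al. (2004) form for estuaries — and every equation is overridable via
a registry file, since the authoritative list for any given study is the
study's own supplement.

Per-waterbody policy (`auto`): the reservoir averages the lake relations,
the estuary averages the estuary relations, and the river uses Crusius &
Wanninkhof (2003) exclusively — it gives the highest k600 of the lake set
at moderate winds, a deliberately conservative upper limit where river
depth/velocity data for a proper river parameterization are missing.
Ensemble provenance retains every member value.

The Schmidt exponent is −2/3 for a smooth surface and −1/2 for a
turbulent one. Reservoir: smooth below u10 = 3.7 m s⁻¹ with a **strict**
`<` at the boundary (3.7 itself is turbulent), pinned by test. Rivers and
estuaries are always turbulent. Zero or negative-intercept winds are
evaluated as-is; no floor is imposed, preserving positive intercepts.

## Fluxes and budget

Diffusive flux `F = 0.24·k_i·K_i·(p_water − p_atm)` keeps its sign:
influx (undersaturation) is negative and never clipped. Default
atmospheric partial pressures are pCO2 = 410 µatm and pCH4 = 1.9 µatm,
configurable. The surface concentration of a station/cast is the
shallowest sample at ≤ 1 m (configurable). Campaign aggregation supports
both mean and median central values (field reports use both in different
tables); the choice is an explicit argument and is logged.

The budget multiplies per-waterbody mean areal fluxes by surface area,
annualizes over 365 days with no seasonal weighting (seasonal inputs are
averaged with a plain mean first; configurable weights are possible
upstream of the call), converts to gas mass and applies the CH4 GWP of 27
(IPCC AR6, 100-yr) **on a mass basis** — the standard convention. A molar
bridge (1 mol CH4 ≈ 9.84 mol CO2-eq) is provided for flux-space
comparisons but never used for the headline numbers. Headline percentages
round half-up at the reported precision (bankers' rounding would turn
0.075 Mmol d⁻¹ into 0.07 instead of the printed 0.08).

Source attribution sums per-station emissions within segments labelled
dam discharge / sand extraction / other, with equal per-station weights
by default (the original weighting is not published; this is a documented
reconstruction), normalized to 100%.

The packaged `field_summaries` module carries the published
campaign-level statistics of the Kenyir/Terengganu system (seasonal
reservoir means 97/54 mmol CO2 and 2/0.8 mmol CH4 m⁻² d⁻¹, river
campaign medians, estuary flow-regime means, areas 369/10/7.6 km²) as
*inputs*; the package does not re-derive them, since the underlying
station-level raw data are not distributed. The default recipe closes at
559.6 Gg CO2-eq yr⁻¹ with shares 94.6/0.8/4.6% and a CO2 share of 83.4%.

## Synthetic campaigns

The generator is statistical, not mechanistic, and its defaults encode
the study conditions: seven reservoir stations with logistic thermal
stratification (~5 °C contrast), hypoxia below 40 m and a hypolimnion CH4
distribution of mean 621, sd 187 µmol L⁻¹; a 13-station river transect
whose deterministic skeleton decays exponentially with decay length
3/ln 5 stations (so station 4 retains exactly 20% of the outlet value)
plus a compactly supported raised-cosine bump over stations 7–10 for the
sand-extraction reach; a 24-h estuary series sampled two-hourly under a
12.42-h tide with conservative mixing to a marine endmember (13 µM CO2,
0.005 µM CH4 at salinity 32); and truncated-normal monthly winds with a
wet:dry mean ratio of 1.3 (dry mean 2.0 m s⁻¹). Concentration noise is
mean-one lognormal, so ensemble means recover the skeleton and values are
strictly positive. The sampled tide heights are rescaled so the realized
trough-to-crest range equals the configured tidal range exactly.

What passing tests show: the computation chain is internally consistent —
headspace forward/inverse is the identity, parameter-recovery regressions
return the configured decay and mixing slopes, and the pipeline's mean
fluxes close on the analytically expected values within 3 standard
errors. What they do not show: agreement with any real station data, real
covariance between temperature, wind and concentration, bubble dynamics,
or hydrodynamics — the generator draws these independently.

## Problem sizes and numerical choices

Test and acceptance-script simulation sizes: 10⁴ draws for the
hypolimnion CLT check, 2 × 2000 wind days for the seasonal ratio, 500
transects for decay recovery, 200 series for the mixing slope, and 40
transects × 13 stations (520 casts) for end-to-end closure — sizes at
which the sampling error of each check is comfortably below its
tolerance. Oracle-equivalence checks (solubility, Schmidt, flux unit
chain against independently coded long-form implementations) run on 10³
random states at 10⁻¹² relative tolerance. All randomness flows from
integer seeds through `numpy.random.default_rng`; no time-based seeding
anywhere.

Degenerate inputs fail loudly with the offending field named: headspace
fractions of exactly 0 or 1, non-positive funnel areas or intervals,
empty aggregations and ensembles, unmapped stations, missing
waterbody/species flux combinations.

## Known limitations

- No carbonate-system speciation: CO2 is treated as a directly measured
  dissolved gas, appropriate for headspace GC but not for pH/alkalinity
  derived pCO2.
- k600 defaults are reconstructions; for published-study fidelity the
  registry should be replaced with the study's own equation list.
- No uncertainty propagation beyond member ranges and sample standard
  deviations; no GC calibration-curve fitting (input mole fractions are
  taken as calibrated); no bubble-dissolution or surface-renewal models.
- Wind-to-sample matching is by calendar month (mirroring the use of
  monthly model wind); sub-monthly covariance between wind and sampling
  is not represented.
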