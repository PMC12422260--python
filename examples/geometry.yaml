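# Waterbody geometry for the budget stage: surface areas (km^2) and,
# optionally, station segments with an anthropogenic source class for the
# attribution of river emissions.
reservoir:
  surface_area_km2: 369.0
river:
  surface_area_km2: 10.0
  segments:
    - id: upper
      stations: [L1, L2, L3, L4]
      source_class: dam_discharge
      area_fraction: 0.31
    - id: middle
      stations: [L5, L6, L7, L8, L9, L10]
      source_class: sand_extraction
      area_fraction: 0.46
    - id: lower
      stations: [L11, L12, L13]
      source_class: other
      area_fraction: 0.23
estuary:
  surface_area_km2: 7.6
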