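import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_sample_table():
    """Three valid concentration rows spanning the schema."""
    return pd.DataFrame(
        {
            "station": ["S1", "L1", "E1"],
            "waterbody": ["reservoir", "river", "estuary"],
            "datetime": ["2018-05-15T10:00:00", "2018-03-01T09:00:00", "2019-04-10T00:00:00"],
            "depth_m": [0.5, 0.5, 0.5],
            "temp_c": [29.0, 28.0, 29.5],
            "salinity": [0.0, 0.0, 12.0],
            "do_pct": [95.0, 41.0, 80.0],
            "species": ["CO2", "CH4", "CO2"],
            "value": [230.0, 15.0, 90.0],
            "value_kind": ["concentration_uM"] * 3,
        }
    )


@pytest.fixture
def wind_table():
    return pd.DataFrame(
        {
            "waterbody": ["reservoir", "river", "estuary"],
            "datetime": pd.to_datetime(
                ["2018-05-01", "2018-03-01", "2019-04-01"]
            ),
            "speed_ms": [2.0, 2.0, 3.0],
            "height_m": [10.0, 2.0, 10.0],
        }
    )


@pytest.fixture
def geometry_yaml(tmp_path):
    text = """\
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
"""
    path = tmp_path / "geometry.yaml"
    path.write_text(text)
    return path
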