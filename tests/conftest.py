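"""Shared fixtures: observation-frame builders and simulated surveys."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from reefspc.data_model import TABLE_COLUMNS, SpeciesTrait
from reefspc.synthetic_data import SimulationConfig, simulate_survey

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: Default cell values for a single synthetic observation row.
_ROW_DEFAULTS = {
    "region": "S.MARIAN", "island": "Saipan", "site": "SAI-01001",
    "latitude": 15.2, "longitude": 145.7, "reef_zone": "Forereef",
    "depth_bin": "mid", "sitevisitid": 1, "date": "2015-05-04",
    "obs_year": 2015, "diver": 1, "replicateid": 11, "rep": "A",
    "depth_m": 12.0, "hard_coral": 30.0, "ma": 10.0, "cca": 15.0,
    "sand": 25.0, "other": 20.0, "habitat_code": "AGR",
    "current_strength": "Slight", "visibility_m": 20.0,
    "min_depth_m": 11.0, "max_depth_m": 13.0, "complexity": None,
    "substrate_height_0": 40.0, "substrate_height_20": 25.0,
    "substrate_height_50": 20.0, "substrate_height_100": 10.0,
    "substrate_height_150": 5.0, "max_height": 80.0, "urchin_dacor": "O",
    "boring_urchin_dacor": "C", "species": "ABCD",
    "taxonname": "Genus abcd", "common_family": "Surgeonfish",
    "family": "Acanthuridae", "consumer_group": "Primary Consumer",
    "lw_a": 0.01, "lw_b": 3.0, "lmax": 60.0,
    "length_conversion_factor": 1.0, "count": 1, "size_tl_cm": 10.0,
    "obs_type": "I",
}


def obs_frame(rows: list[dict]) -> pd.DataFrame:
    """Build an observation frame from per-row overrides of the defaults."""
    full = [{**_ROW_DEFAULTS, **r} for r in rows]
    df = pd.DataFrame(full, columns=[c.lower() for c in TABLE_COLUMNS])
    df["date"] = pd.to_datetime(df["date"])
    for col in ("sitevisitid", "obs_year", "diver", "replicateid", "count",
                "complexity"):
        df[col] = df[col].astype("Int64")
    return df


@pytest.fixture
def make_obs():
    return obs_frame


@pytest.fixture
def trait():
    return SpeciesTrait(species="ABCD", lw_a=0.01, lw_b=3.0, lmax=60.0,
                        length_conversion_factor=1.0)


@pytest.fixture(scope="session")
def sim_survey():
    """A realistic stochastic survey of the default Saipan-like unit."""
    config = SimulationConfig()
    records, truth = simulate_survey(config, seed=42)
    return config, records, truth


@pytest.fixture(scope="session")
def noiseless_survey():
    config = SimulationConfig(noiseless=True)
    records, truth = simulate_survey(config, seed=7)
    return config, records, truth
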