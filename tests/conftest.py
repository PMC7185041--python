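import dataclasses

import pandas as pd
import pytest

from yearlings.synthetic import scenario_presets, simulate
from yearlings.table1 import load_table1


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return load_table1()


@pytest.fixture(scope="session")
def smoke_sim():
    """A miniature simulated dataset shared across tests."""
    return simulate(scenario_presets()["smoke"], seed=42)


@pytest.fixture(scope="session")
def smoke_config():
    return scenario_presets()["smoke"]


def make_config(**overrides):
    """Paper-like study conditions with explicit overrides."""
    return dataclasses.replace(scenario_presets()["paper-like"], **overrides)


def captures_frame(rows):
    """Capture DataFrame from (band, species, station, date, age) tuples,
    in the shape read_captures produces."""
    df = pd.DataFrame(rows, columns=["band_id", "species_code",
                                     "station_id", "date", "age"])
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    df = df.sort_values(["band_id", "year", "date"],
                        kind="stable").reset_index(drop=True)
    df["capture_index"] = df.groupby(["band_id", "year"]).cumcount()
    return df
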