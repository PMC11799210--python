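import numpy as np
import pandas as pd
import pytest

from thermobias import TimeBinSequence, WorldConfig, generate_world
from dataclasses import replace


@pytest.fixture(scope="session")
def seq() -> TimeBinSequence:
    return TimeBinSequence()


@pytest.fixture(scope="session")
def small_world_config() -> WorldConfig:
    """A reduced world for fast unit/integration tests."""
    return replace(WorldConfig(), n_species=150, n_localities=15, seed=7)


@pytest.fixture(scope="session")
def small_world(small_world_config):
    return generate_world(small_world_config)


@pytest.fixture(scope="session")
def tracking_run():
    """One full pipeline run on a reduced tracking world (shared, read-only)."""
    from thermobias import RunConfig, run_pipeline
    from thermobias.simulate import scenario_presets

    wc = replace(scenario_presets()["tracking"], n_species=150, n_localities=15)
    return run_pipeline(RunConfig(world=wc, seed=11))


def make_occurrence_frame(rows):
    """Build a minimal normalised occurrence frame from compact tuples
    (species, region_id, time_bin, temperature)."""
    df = pd.DataFrame(rows, columns=["species", "region_id", "time_bin", "temperature"])
    df["occurrence_id"] = [f"o{i}" for i in range(len(df))]
    df["clade"] = "Bivalvia"
    df["lith_category"] = "unknown"
    df["bath_category"] = "unknown"
    df["collection_id"] = "c0"
    return df
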