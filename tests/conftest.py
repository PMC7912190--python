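import numpy as np
import pandas as pd
import pytest

from shedclimate import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_farms():
    """Default 32-farm housing table (8 per region)."""
    return synthetic.generate_farms(synthetic.GeneratorConfig())


@pytest.fixture(scope="session")
def archetype_farms():
    """32-farm table from the 7 housing archetypes with true labels."""
    return synthetic.generate_archetype_farms(seed=1)


@pytest.fixture(scope="session")
def model_mode_merged():
    """Per-farm daily-mean responses merged with housing, 100 farms/region."""
    cfg = synthetic.GeneratorConfig(mode="model", n_farms_per_region=100, seed=11)
    farms = synthetic.generate_farms(cfg)
    resp = synthetic.generate_microclimate(farms, cfg)
    daily = resp.groupby("farm_id")[["AT", "AS", "HLI", "THI"]].mean().reset_index()
    return farms.merge(daily, on="farm_id")


@pytest.fixture
def toy_mixed_table():
    """Three-farm toy table with one quantitative and one qualitative column."""
    return pd.DataFrame({"q": [1.0, 2.0, 3.0], "c": ["x", "x", "y"]})
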