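import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import hetpower as hp

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_dataset() -> hp.Dataset:
    """Eight observations, two per cell, with additive cell means.

    Cell values: reference/control (1, 2), reference/treated (3, 4),
    variable/control (5, 6), variable/treated (7, 8).  Cell means are
    additive (1.5, 3.5, 5.5, 7.5), so the main-effects coefficients are
    exactly (1.5, 4, 2) and every residual is +-0.5.
    """
    frame = pd.DataFrame(
        {
            "sex": ["reference"] * 4 + ["variable"] * 4,
            "treatment": ["control", "control", "treated", "treated"] * 2,
            "response": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
        }
    )
    return hp.Dataset(frame=frame)


@pytest.fixture
def random_dataset() -> hp.Dataset:
    """A moderately sized heteroscedastic dataset with all effects present."""
    scen = hp.build_scenario(
        mu0=3.0, beta_trt=0.5, beta_sex=0.3, beta_int=0.2, sd_ratio=1.73,
        name="random",
    )
    return hp.simulate_dataset(scen, 48, seed=1234)


@pytest.fixture
def homoscedastic() -> hp.Scenario:
    return hp.get_preset("homoscedastic")


@pytest.fixture
def large_het() -> hp.Scenario:
    return hp.get_preset("large-het")
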