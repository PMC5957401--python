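import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mldendro.synthetic import SimDesign, gen_climate, gen_growth

settings.register_profile("repro", derandomize=True, database=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_design():
    """2 plots x 2 trees x 2 cores over 30 years: quick but structured."""
    return SimDesign(years=(1976, 2005), seed=42)


@pytest.fixture(scope="session")
def growth_series(small_design):
    series, _ = gen_growth(small_design)
    return series


@pytest.fixture(scope="session")
def radius_vector(small_design):
    _, radii = gen_growth(small_design)
    return radii


@pytest.fixture(scope="session")
def climate_tables(small_design):
    return gen_climate(small_design)


@pytest.fixture(scope="session")
def growth_frame(growth_series):
    from mldendro.frames import model_frame

    return model_frame(growth_series, log_t=True)


@pytest.fixture(scope="session")
def aridity_frame(climate_tables):
    from mldendro.frames import model_frame

    return model_frame(climate_tables)


@pytest.fixture()
def tiny_wide():
    """Wide growth table: 1 plot, 2 trees x 1 core, 5 years, one gap."""
    return pd.DataFrame(
        {
            "P1.1.a": [0.5, 0.6, np.nan, 0.7, 0.8],
            "P1.2.a": [0.4, 0.5, 0.6, 0.7, 0.6],
        },
        index=[1991, 1992, 1993, 1994, 1995],
    )
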