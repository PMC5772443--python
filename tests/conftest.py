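import logging

import numpy as np
import pytest

from sdmcontrast.grid import GridSpec
from sdmcontrast.synth import SyntheticConfig, generate_world

logging.getLogger("sdmcontrast").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(west=-80.0, south=-20.0, cell_size=0.5, n_cols=20,
                    n_rows=20)


@pytest.fixture(scope="session")
def world():
    """Mid-size synthetic world shared across tests (read-only)."""
    cfg = SyntheticConfig(
        grid=GridSpec(west=-80.0, south=-20.0, cell_size=0.5, n_cols=40,
                      n_rows=40),
        n_species=8,
        n_plots=250,
        records_per_species=90,
        seed=11,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def full_world():
    """The packaged demo conditions: 60x60 grid, 15 species, 400 plots."""
    return generate_world(SyntheticConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
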