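import dataclasses

import pytest

from epistrat.synthetic_data import default_config, generate_all_tables
from epistrat.tissue_growth import build_cell_number_series


@pytest.fixture(scope="session")
def config():
    """Default study conditions with a fixed seed."""
    return default_config(seed=123)


@pytest.fixture(scope="session")
def noise_free_config(config):
    """Same curves with every noise source switched off."""
    growth = {
        axis: dataclasses.replace(g, noise_sd_mm=0.0) for axis, g in config.growth.items()
    }
    curves = {
        key: dataclasses.replace(c, noise_sd=0.0)
        for key, c in config.density_curves.items()
    }
    return dataclasses.replace(config, growth=growth, density_curves=curves)


@pytest.fixture(scope="session")
def tables(config):
    return generate_all_tables(config)


@pytest.fixture(scope="session")
def series(tables):
    return build_cell_number_series(tables["density"], tables["growth"])
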