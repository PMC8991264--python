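import numpy as np
import pytest

import epferm as ep


@pytest.fixture(scope="session")
def fixture_design():
    return ep.load_design_fixture()


@pytest.fixture(scope="session")
def long_table(fixture_design):
    return ep.assemble_long_table(fixture_design)


@pytest.fixture(scope="session")
def fitted_model(long_table):
    return ep.fit_quadratic_model(long_table)


@pytest.fixture(scope="session")
def tested_ranges(long_table, fitted_model):
    return {
        f: (long_table[f].min(), long_table[f].max())
        for f in fitted_model.spec.all_factors
    }


@pytest.fixture(scope="session")
def default_kinetics():
    return ep.default_batch_params()


@pytest.fixture(scope="session")
def batch_grid():
    return np.linspace(0.0, 80.0, 21)
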