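import numpy as np
import pytest

from hybridpanel import growth, simulate


@pytest.fixture(scope="session")
def small_panel():
    """Small deterministic synthetic panel shared across tests."""
    return simulate.generate_panel(simulate.small_config(seed=11))


@pytest.fixture(scope="session")
def small_fits(small_panel):
    """Per-well Gompertz fits of the small panel."""
    return growth.fit_growth_table(small_panel.growth_data)


@pytest.fixture(scope="session")
def small_summaries(small_fits):
    return growth.summary_table(small_fits)


@pytest.fixture()
def time_grid():
    return np.arange(0.0, 96.1, 3.0)
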