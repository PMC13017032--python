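import pytest

import mosaicburden as mb


@pytest.fixture(scope="session")
def panel():
    """Default 7-gene synthetic panel shared across tests."""
    return mb.generate_panel(seed=1)


@pytest.fixture(scope="session")
def small_panel():
    """Two-gene panel for cohort-scale simulations."""
    return mb.generate_panel(["FUS", "TBK1"], seed=11)
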