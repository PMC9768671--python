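import numpy as np
import pytest

from asicca.synthetic import wt_asic3


@pytest.fixture(scope="session")
def wt_spec():
    return wt_asic3()


@pytest.fixture()
def ph_grid():
    """Standard activation grid, alkaline to acidic (pH 8.0 -> 5.0)."""
    return np.round(np.arange(8.0, 5.0 - 1e-9, -0.2), 10)
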