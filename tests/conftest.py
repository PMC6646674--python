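import numpy as np
import pytest

from canopytraits import canopy


@pytest.fixture(scope="session")
def default_lut() -> canopy.LookupTable:
    """Standard two-angle look-up table (built once per session)."""
    return canopy.build_lut(angles=(0.0, 45.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20170101)
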