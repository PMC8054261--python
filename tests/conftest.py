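import warnings

import numpy as np
import pytest

from ecmscreen import DiscSceneParams, gen_well_scene

# skimage deprecation chatter from dependencies is not under test
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic well scene shared by read-only tests."""
    return gen_well_scene(DiscSceneParams(seed=42))


@pytest.fixture
def disc_mask_20():
    """A hand-built 20x20 filled circle of radius 5 centred at (10, 10)."""
    rr, cc = np.mgrid[0:20, 0:20]
    return (rr - 10) ** 2 + (cc - 10) ** 2 <= 25
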