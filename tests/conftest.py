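import numpy as np
import pytest

import otodx
from otodx.filterbank import build_mr8_bank
from otodx.synthetic import phantom_seed

SMALL = (96, 96)  # (width, height) used for fast unit-test phantoms


@pytest.fixture(scope="session")
def bank():
    return build_mr8_bank()


@pytest.fixture(scope="session")
def small_phantoms():
    """A few small phantoms per class, keyed by class label."""
    out = {}
    for cls in otodx.CLASSES:
        out[cls] = [
            otodx.generate_phantom(
                otodx.PhantomSpec(cls, roi_size=SMALL, seed=phantom_seed(42, cls, i))
            )
            for i in range(4)
        ]
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
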