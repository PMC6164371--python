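import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # test-local helpers

from vrfrap.studies import extrapolation_study  # noqa: E402

ACCEPTANCE_SEED = 1


@pytest.fixture(scope="session")
def extrapolation_grid():
    """The inverse-radius extrapolation experiment over the full
    (alpha, D) grid at the desk scale (3 replicate curves of 2e5
    particles per radius), shared between the extrapolation-accuracy and
    underestimation tests."""
    return extrapolation_study(seed=ACCEPTANCE_SEED)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
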