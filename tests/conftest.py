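import numpy as np
import pytest

from opsinspec.photosim import rh7_like_pigments
from opsinspec.spectra import CANONICAL_GRID


@pytest.fixture(scope="session")
def grid() -> np.ndarray:
    return CANONICAL_GRID


@pytest.fixture(scope="session")
def rh7_pair():
    """Session-wide synthetic Rh7-like bistable pigment fixture."""
    return rh7_like_pigments()
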