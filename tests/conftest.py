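import numpy as np
import pytest

from colfold import build_reference_helix, Trajectory


@pytest.fixture(scope="session")
def reference():
    """The standard (Gly-Pro-Pro)5 ideal triple-helix reference."""
    return build_reference_helix(5)


@pytest.fixture(scope="session")
def reference_trajectory(reference):
    """A 60-frame trajectory of exact reference coordinates."""
    coords = np.repeat(reference.coords[None], 60, axis=0)
    return Trajectory(reference, coords, dt=50.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
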