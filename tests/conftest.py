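import numpy as np
import pytest

from dia3 import make_tensor, scheme_directions, synthesize_phantom
from dia3.tensor_simulator import REFERENCE_EIGENVALUES


@pytest.fixture(scope="session")
def reference_tensor():
    """Prolate tensor with eigenvalues [1, 0.3, 0.3]×10⁻³ mm²/s (FA 0.6444)."""
    return make_tensor(REFERENCE_EIGENVALUES)


@pytest.fixture(scope="session")
def axes_phantom(reference_tensor):
    """Noiseless 3-axis phantom of the reference tensor, b = 1000 s/mm²."""
    return synthesize_phantom(
        reference_tensor, scheme_directions(3), b=1000.0, S0=1000.0,
        shape=(4, 4, 2),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


def random_rotation(rng):
    from scipy.stats import special_ortho_group

    return special_ortho_group.rvs(3, random_state=rng)
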