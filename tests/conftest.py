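import numpy as np
import pytest

from quadhop import synthetic as syn
from quadhop import io as qio


@pytest.fixture(scope="session")
def reference_structure():
    """Idealized quadruplex built from the crystal-interface distance set."""
    return syn.gen_quadruplex(syn.REFERENCE_QUAD_SPEC, seed=0)


@pytest.fixture(scope="session")
def reference_sites(reference_structure):
    return qio.indole_sites(reference_structure[0])


@pytest.fixture(scope="session")
def shift_trajectory(reference_structure):
    """500+500-frame trajectory with a planted 0.15 Å bridging-water shift
    upon the forced 124A+ -> 122D+ hole transfer."""
    hyd = syn.HydrationSpec(n_waters=8, shift_magnitude=0.15, jitter_sigma=0.05, seed=11)
    return syn.gen_trajectory(reference_structure, hyd, 500, "122D+")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
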