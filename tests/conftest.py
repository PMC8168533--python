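import numpy as np
import pytest

from aslkid import (
    ASLProtocol,
    build_phantom,
    default_phantom_spec,
    simulate_asl_session,
)


@pytest.fixture(scope="session")
def small_protocol():
    """Three-slice, four-pair protocol matching the small test phantom."""
    return ASLProtocol(n_slices=3, n_pairs=4)


@pytest.fixture(scope="session")
def small_phantom():
    """20x20x3 kidney/tumor phantom with all five region labels."""
    return build_phantom(default_phantom_spec((20, 20, 3)))


@pytest.fixture(scope="session")
def noise_free_session(small_phantom, small_protocol):
    return simulate_asl_session(small_phantom, small_protocol, 0.0, seed=0)


@pytest.fixture(scope="session")
def single_slice_setup():
    """1-slice phantom/protocol pair used by the motion-rejection tests."""
    phantom = build_phantom(default_phantom_spec((16, 16, 1)))
    protocol = ASLProtocol(plds=(1000.0,), n_slices=1, n_pairs=10)
    return phantom, protocol
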