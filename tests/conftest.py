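import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture(scope="session")
def matrix():
    from betalattice import default_matrix

    return default_matrix()


@pytest.fixture(scope="session")
def zero_matrix():
    from betalattice import InteractionMatrix

    return InteractionMatrix.zero()


@pytest.fixture(scope="session")
def params():
    from betalattice import EnergyParams

    return EnergyParams()


def one_hb_system():
    """Two parallel 2-residue chains with exactly one hydrogen bond.

    Chains run along x on adjacent y rows; only the residues at x=1 are in
    the strand state, sharing the +z side-chain direction perpendicular to
    the y contact vector.  No steric pair, no amino-acid term with a zero
    matrix.
    """
    from betalattice import COIL, STRAND, Chain, System

    c1 = Chain("AA", [(1, 1, 1), (2, 1, 1)], [(0, 0, 1), (0, 0, -1)],
               [STRAND, COIL])
    c2 = Chain("AA", [(1, 2, 1), (2, 2, 1)], [(0, 0, 1), (0, 0, -1)],
               [STRAND, COIL])
    return System(8, [c1, c2])


def straight_three_mer(directions, states=None, seq="AAA", box=8):
    from betalattice import Chain, System

    chain = Chain(seq, [(1, 1, 1), (2, 1, 1), (3, 1, 1)], directions, states)
    return System(box, [chain])
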