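import numpy as np
import pytest

from ordentropy.egf import make_phi_a, make_phi_q, make_phi_shannon

# the EGFs used throughout the simulation work: a = 1 (Shannon), 3/2, 2, 5/2, q = 4
SHIPPED_EGFS = [
    make_phi_shannon(),
    make_phi_a(1.5),
    make_phi_a(2.0),
    make_phi_a(2.5),
    make_phi_q(4.0),
]

SMOOTH_EGFS = [e for e in SHIPPED_EGFS if e.smoothness_order >= 2]


def random_cdf(rng: np.random.Generator, m: int, interior: bool = True) -> np.ndarray:
    """A random strictly increasing CDF vector of length m.

    ``interior`` keeps all components safely inside (0, 1) so that
    boundary-divergent EGF derivatives stay finite.
    """
    cuts = np.sort(rng.uniform(0.05 if interior else 0.0, 0.95, size=m))
    return cuts


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
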