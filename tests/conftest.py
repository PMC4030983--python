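import numpy as np
import pytest

from cafold.fixtures import TopologySpec, synthetic_features, synthetic_native
from cafold.structures import CaTrace, random_extended_trace


@pytest.fixture(scope="session")
def mixed_spec():
    return TopologySpec((("helix", 12), ("coil", 4), ("strand", 8),
                         ("coil", 4), ("strand", 8)))


@pytest.fixture(scope="session")
def native_trace(mixed_spec):
    """A packed synthetic native with features attached (L = 36)."""
    return synthetic_features(synthetic_native(mixed_spec, seed=2), mixed_spec)


@pytest.fixture()
def random_trace():
    return random_extended_trace("ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY", 1)


def featured(trace: CaTrace) -> CaTrace:
    """Attach trivial all-coil/exposed features."""
    return CaTrace(trace.sequence, trace.coords, "C" * len(trace),
                   ("exposed",) * len(trace))


def random_rigid_motion(coords: np.ndarray, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, [0, 1]] = Q[:, [1, 0]]
    return coords @ Q.T + rng.normal(scale=10.0, size=3)
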