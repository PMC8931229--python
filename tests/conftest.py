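import numpy as np
import pytest

from loopforge.fixtures import FixtureSpec, make_fixture
from loopforge.structure import BackboneStructure, SegmentSpec, coords_from_torsions


def random_chain(seed: int, n: int = 12, phi_range=(-160, -40),
                 psi_range=(-70, 170)) -> BackboneStructure:
    """A single-chain backbone with random plausible torsions."""
    rng = np.random.default_rng(seed)
    tors = np.stack([rng.uniform(*phi_range, n), rng.uniform(*psi_range, n),
                     np.full(n, 180.0)], axis=1)
    anchor = np.array([[0.0, 0.0, 0.0], [1.329, 0.0, 0.0], [1.9, 1.3, 0.2]])
    coords = coords_from_torsions(anchor, tors)
    return BackboneStructure(coords, np.arange(1, n + 1),
                             np.array(["A"] * n), "A" * n)


@pytest.fixture(scope="session")
def helix_fixture():
    """Deterministic 6-residue-loop fixture shared across tests."""
    return make_fixture(FixtureSpec(6, "random-rama", seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
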