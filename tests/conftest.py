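import numpy as np
import pytest

from chromocg import FccLattice, init_conformation
from chromocg.engine import Trajectory


@pytest.fixture(scope="session")
def small_lattice():
    return FccLattice(S=4, b=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_static_trajectory(lattice, coords, n_snap=5, snapshot_every=100):
    """A trajectory whose snapshots all equal ``coords`` (unfolded grid)."""
    coords = np.asarray(coords, dtype=np.int64)
    pos = np.repeat(coords[None, :, :], n_snap, axis=0)
    return Trajectory(
        lattice=lattice,
        mcs=np.arange(n_snap, dtype=np.int64) * snapshot_every,
        positions=pos,
        energy=np.zeros(n_snap),
        seed=0,
        acceptance_rate=0.0,
    )


@pytest.fixture()
def straight_chain_traj(small_lattice):
    conf = init_conformation("line", 8, small_lattice)
    return make_static_trajectory(small_lattice, conf.unfolded)
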