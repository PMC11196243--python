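import numpy as np
import pytest

from vernalphylo.phylogeny import Phylogeny
from vernalphylo.simulate import SimulationConfig, simulate_dataset, simulate_tree


@pytest.fixture
def toy_tree() -> Phylogeny:
    """Three-tip tree with hand-computable PD/MPD/MNTD."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def tree42() -> Phylogeny:
    """One 42-tip simulated ultrametric tree shared across tests."""
    return simulate_tree(42, seed=7)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic study shared across tests."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
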