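import numpy as np
import pytest

from hostspec import HostTree
from hostspec.io import AnalysisConfig
from hostspec.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def three_tip_tree():
    return HostTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four_tip_tree():
    return HostTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def small_dataset():
    """Complete 40-species synthetic pool shared across tests."""
    return simulate_dataset(SimulationConfig(n_species=40, seed=202))


@pytest.fixture(scope="session")
def medium_dataset():
    """120-species pool for specificity-stage tests."""
    return simulate_dataset(SimulationConfig(n_species=120, seed=77))
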