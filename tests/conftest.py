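import numpy as np
import pytest

from pollenmorph import PhyloTree
from pollenmorph.oushifts import ShiftWorkspace
from pollenmorph.simulate import SimulationSpec, sim_tree


@pytest.fixture(scope="session")
def tree64():
    """One 64-tip Yule tree at the study's 116-Myr depth, shared by the
    simulation-heavy tests."""
    return sim_tree(SimulationSpec(seed=100, n_tips=64))


@pytest.fixture(scope="session")
def workspace64(tree64):
    return ShiftWorkspace(tree64)


@pytest.fixture
def balanced4():
    return PhyloTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture
def star4():
    return PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")


@pytest.fixture
def circle_points():
    t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    return np.column_stack([np.cos(t), np.sin(t)])
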