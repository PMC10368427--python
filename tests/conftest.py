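import numpy as np
import pytest

from cortasym.mesh import build_mesh
from cortasym.simulate import simulate_datasets


@pytest.fixture(scope="session")
def mesh_tiny():
    """42-vertex icosphere for brute-force oracles."""
    return build_mesh(1, 4 * np.pi)


@pytest.fixture(scope="session")
def mesh_small():
    """162-vertex icosphere for mid-sized checks."""
    return build_mesh(2, 9.0e4)


@pytest.fixture(scope="session")
def mesh_default():
    """2562-vertex icosphere at one-hemisphere area, the pipeline default."""
    return build_mesh(4, 9.0e4)


@pytest.fixture(scope="session")
def consensus_run(mesh_default):
    """Default 7-dataset simulation with the planted patch configuration."""
    datasets, truth = simulate_datasets(mesh_default, seed=7)
    return datasets, truth
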