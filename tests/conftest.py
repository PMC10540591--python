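import numpy as np
import pytest

import cortdecode as cd
from cortdecode.simulate import SimulationParams


@pytest.fixture(scope="session")
def icosahedron():
    return cd.make_synthetic_mesh(0, 10.0)


@pytest.fixture(scope="session")
def icosphere2():
    """162-vertex icosphere used as the small synthetic cortex."""
    return cd.make_synthetic_mesh(2, 12.0)


@pytest.fixture(scope="session")
def tetrahedron():
    verts = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    faces = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return cd.CorticalMesh(vertices=verts, faces=faces)


@pytest.fixture(scope="session")
def small_subject():
    """One small simulated subject: icosphere k=2, one session of two runs."""
    mesh, sim = cd.simulate_subject(
        subdivision_level=2, radius_mm=12.0, n_sessions=1, n_runs=2,
        params=SimulationParams(seed=3), seed=3,
    )
    return mesh, sim


@pytest.fixture(scope="session")
def small_samples(small_subject):
    """Block-averaged (BS5) samples for the small subject."""
    mesh, sim = small_subject
    return cd.extract_block_samples(
        sim.runs, mesh, sim.schedule, fwhm_mm=6.0, k_base=162, block_size=5
    )
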