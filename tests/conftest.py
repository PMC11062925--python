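import numpy as np
import pytest

from myoperf.core_model import LVMesh
from myoperf.synthetic_patient import (
    SyntheticPatientConfig,
    make_patient,
    table_targets,
)
from myoperf.tuning import stage1_tune


@pytest.fixture(scope="session")
def patient():
    """Default synthetic patient (seed 1, reference patient-2 targets)."""
    return make_patient(SyntheticPatientConfig(seed=1, patient=2))


@pytest.fixture(scope="session")
def stage1(patient):
    """Cheap Stage-1 fit (calibration only) shared across tests."""
    return stage1_tune(patient.targets, seed=1, nm_restarts=0)


@pytest.fixture(scope="session")
def steady_model(patient, stage1):
    from myoperf.cli_pipeline import build_steady_model

    return build_steady_model(patient, stage1)


@pytest.fixture(scope="session")
def trees_model(patient, stage1):
    """Hyperemic steady model with 500 grown synthetic outlets + territories."""
    import copy

    from myoperf.cli_pipeline import (
        build_steady_model,
        grow_synthetic_trees,
        synthetic_outlet_territories,
    )

    pat = copy.deepcopy(patient)
    model, r_tot = build_steady_model(pat, stage1)
    grow_synthetic_trees(pat, model, total_terminals=500, seed=1)
    tmap = synthetic_outlet_territories(pat, model)
    return pat, model, r_tot, tmap


def structured_cube_mesh(n: int, size: float = 1.0) -> LVMesh:
    """Unit-cube tet mesh (6 tets per hex) for verification problems."""
    xs = np.linspace(0.0, size, n + 1)
    pts = np.array([[x, y, z] for z in xs for y in xs for x in xs])

    def nid(i, j, k):
        return (k * (n + 1) + j) * (n + 1) + i

    hex_tets = [(0, 1, 3, 7), (0, 1, 7, 5), (0, 5, 7, 4),
                (1, 2, 3, 7), (1, 2, 7, 6), (1, 6, 7, 5)]
    tets = []
    for k in range(n):
        for j in range(n):
            for i in range(n):
                c = [nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k),
                     nid(i, j + 1, k), nid(i, j, k + 1), nid(i + 1, j, k + 1),
                     nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)]
                for t in hex_tets:
                    tets.append([c[m] for m in t])
    tets = np.array(tets, dtype=np.int64)
    p = pts[tets]
    vol6 = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                     np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]))
    tets[vol6 < 0] = tets[vol6 < 0][:, [0, 1, 3, 2]]
    return LVMesh(nodes=pts, tets=tets)


@pytest.fixture(scope="session")
def cube_mesh():
    return structured_cube_mesh(6)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
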