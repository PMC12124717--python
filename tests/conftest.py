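import numpy as np
import pytest

from metalff import MolecularGeometry, build_topology
from metalff.fixtures import SpringModel, make_ideal_complex, make_spring_hessian


@pytest.fixture
def water():
    return MolecularGeometry(
        elements=["O", "H", "H"],
        coordinates=np.array([[0.0, 0.0, 0.0],
                              [0.9572, 0.0, 0.0],
                              [-0.2399, 0.9266, 0.0]]),
        total_charge=0,
        title="water",
    )


@pytest.fixture
def water_topology(water):
    return build_topology(water, require_metal=False)


@pytest.fixture
def octahedral():
    return make_ideal_complex("octahedral")


@pytest.fixture
def octahedral_spring(octahedral):
    geom, topo = octahedral
    model = SpringModel.uniform(geom, topo, k_bond=0.25, k_perp=0.05)
    return geom, topo, model, make_spring_hessian(model)


@pytest.fixture
def tris_bidentate():
    return make_ideal_complex("tris_bidentate")


def random_rotation(rng):
    """Uniform-ish random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
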