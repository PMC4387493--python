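import numpy as np
import pytest

from hullmass.geometry import TriMesh
from hullmass.synth import SynthSkeletonSpec, box_mesh, make_skeleton

#: Unit-edge regular tetrahedron; volume sqrt(2)/12.
TETRA_VERTICES = np.array(
    [
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.5, np.sqrt(3.0) / 2.0, 0.0],
        [0.5, np.sqrt(3.0) / 6.0, np.sqrt(2.0 / 3.0)],
    ]
)
TETRA_FACES = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [2, 0, 3]])


@pytest.fixture
def cube_mesh() -> TriMesh:
    return box_mesh(1.0, 1.0, 1.0, center=(0.5, 0.5, 0.5), label="unit cube")


@pytest.fixture
def tetra_mesh() -> TriMesh:
    return TriMesh(TETRA_VERTICES.copy(), TETRA_FACES.copy(), label="tetra")


@pytest.fixture(scope="session")
def synth_skeleton(tmp_path_factory):
    """Default 16-unit synthetic skeleton written once per session."""
    outdir = tmp_path_factory.mktemp("skeleton")
    spec = SynthSkeletonSpec(seed=7)
    manifest, truth = make_skeleton(spec, outdir)
    return spec, manifest, truth, outdir


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
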