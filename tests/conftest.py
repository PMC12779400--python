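from __future__ import annotations

import numpy as np
import pytest

from craniogrowth.scheme import default_scheme
from craniogrowth.morpho.symmetry import reflect_relabel


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def symmetric_base_shape(scheme):
    """A fixed, bilaterally symmetric 18-landmark configuration (mm scale)."""
    r = np.random.default_rng(42)
    raw = r.normal(size=(scheme.n_landmarks, 3)) * 25.0
    return 0.5 * (raw + reflect_relabel(raw, scheme))


def random_rigid_motion(rng, scale: float = 1.0):
    """A proper rotation + translation, optionally with scaling."""
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(size=3) * 40.0
    return q * scale, t


@pytest.fixture(scope="session")
def small_head_mesh():
    from craniogrowth.synthetic.head import HeadGeometryParams, generate_head_mesh

    return generate_head_mesh(HeadGeometryParams(target_edge_length=8.0))


@pytest.fixture(scope="session")
def label_pair():
    from craniogrowth.synthetic.images import generate_label_images

    return generate_label_images(seed=11)


@pytest.fixture(scope="session")
def ball_mesh():
    """Voxel ball of cell-growth tissue for FE patch tests, with 3-2-1
    rigid-body constraints."""
    from craniogrowth.mesh import TetMesh
    from craniogrowth.synthetic.head import voxel_tet_mesh

    def ball(p):
        return np.where((p**2).sum(axis=1) <= 100.0, 1, -1)  # domain 1 = brain

    nodes, tets, dom = voxel_tet_mesh(ball, ((-12, 12), (-12, 12), (-12, 12)), 2.5)
    mesh = TetMesh(nodes=nodes, tets=tets, domain=dom)
    i0 = int(np.argmin((nodes**2).sum(axis=1)))
    ix = int(np.argmin(((nodes - [8, 0, 0]) ** 2).sum(axis=1)))
    iy = int(np.argmin(((nodes - [0, 8, 0]) ** 2).sum(axis=1)))
    fixed = np.array([3 * i0, 3 * i0 + 1, 3 * i0 + 2, 3 * ix + 1, 3 * ix + 2, 3 * iy + 2])
    return mesh, fixed
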