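import numpy as np
import pytest

from vtlocate import (
    MeshBuildConfig,
    TriMesh,
    build_generic_lv_mesh,
    make_forward_model,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def default_mesh():
    """The generic 238-triangle prolate LV surface."""
    return build_generic_lv_mesh()


@pytest.fixture(scope="session")
def sphere_mesh():
    """Same tessellation on a sphere (axis ratio 1)."""
    return build_generic_lv_mesh(MeshBuildConfig(axis_ratio=1.0))


@pytest.fixture(scope="session")
def noiseless_dataset(default_mesh):
    """Small dataset in the exact-recovery limit (no noise of any kind)."""
    model = make_forward_model(seed=7, noise_sd=0.0, jitter_sd=0.0, scatter_sd=0.0)
    return simulate_dataset(default_mesh, model, n_sites=150, seed=7)


@pytest.fixture(scope="session")
def default_dataset(default_mesh):
    """Default calibrated scenario at a pinned seed (1,012 sites)."""
    model = make_forward_model(seed=0)
    return simulate_dataset(default_mesh, model, n_sites=1012, seed=0)


@pytest.fixture
def two_triangle_mesh():
    """Two coplanar equilateral triangles (edge 6) sharing an edge.

    Centroids sit at (3, +/-sqrt(3), 0); the shared-edge midpoint (3, 0, 0)
    is exactly equidistant from both.
    """
    e = 6.0
    h = e * np.sqrt(3) / 2
    verts = np.array(
        [[0.0, 0.0, 0.0], [e, 0.0, 0.0], [e / 2, h, 0.0], [e / 2, -h, 0.0]]
    )
    faces = np.array([[0, 1, 2], [0, 1, 3]])
    return TriMesh(verts, faces, cavity_center=np.array([e / 2, 0.0, -10.0]))
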