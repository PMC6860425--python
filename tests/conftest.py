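import numpy as np
import pytest
import trimesh

import rbr


@pytest.fixture(scope="session")
def icosphere():
    """Unit icosphere (subdivision 2): closed topological sphere."""
    ico = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
    return rbr.SurfaceMesh(ico.vertices, ico.faces)


@pytest.fixture(scope="session")
def icosahedron():
    """Base icosahedron: every vertex has 5 symmetric incident faces."""
    ico = trimesh.creation.icosphere(subdivisions=0, radius=1.0)
    return rbr.SurfaceMesh(ico.vertices, ico.faces)


@pytest.fixture(scope="session")
def small_phantom():
    """Small gyrified-sphere phantom (2562 vertices) with its volume."""
    spec = rbr.PhantomSpec(
        subdivisions=4,
        radius=15.0,
        gyrification_amplitude=1.2,
        gyrification_frequency=7.5,
        voxel_size=1.0,
        seed=7,
    )
    mesh, volume = rbr.make_phantom(spec)
    return spec, mesh, volume


@pytest.fixture(scope="session")
def small_gold_standard(small_phantom):
    """Small phantom distorted along y (mean |displacement| 1.5 mm)."""
    spec, mesh, volume = small_phantom
    dspec = rbr.DistortionSpec(target_mean_abs=1.5, control_spacing=30.0, seed=3)
    field = rbr.make_distortion(dspec, volume, mesh)
    return rbr.GoldStandard(
        truth=mesh,
        distorted=rbr.distort_mesh(mesh, field),
        volume=volume,
        field=field,
    )


@pytest.fixture(scope="session")
def random_field_level():
    """A depth-2 lattice with a seeded smooth displacement field."""
    level = rbr.LatticeLevel(origin=np.array([-2.0, -1.0, 0.0]),
                             extent=np.array([8.0, 6.0, 4.0]), depth=2)
    rng = np.random.default_rng(11)
    m = level.n_nodes
    resolved = rng.normal(0.0, 0.15, size=(m, m, m, 3))
    return level, resolved


def step_volume(step_index=16, low=50.0, high=150.0, n=32, voxel=1.0):
    """Volume with an intensity step across a y-index plane.

    The world-space boundary sits between voxel centres, at
    y = (step_index - 0.5) * voxel.
    """
    data = np.full((n, n, n), low)
    data[:, step_index:, :] = high
    affine = np.diag([voxel, voxel, voxel, 1.0])
    return rbr.Volume(data, affine)
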