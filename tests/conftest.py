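import numpy as np
import pytest
import trimesh

from t3d.mesh_core import SurfaceMesh
from t3d.phantom import SpecimenShape, TumorShape, make_phantom
from t3d.specimen_frame import AnatomicalFrame, SpecimenModel


@pytest.fixture(scope="session")
def default_phantom():
    """Default 40x30x20 mm block with a centered 12x8x6 mm tumor."""
    return make_phantom(seed=1, with_ground_truth_margins=False)


@pytest.fixture(scope="session")
def sphere_tumor_phantom():
    """Default specimen with a centered r=6 mm spherical tumor."""
    return make_phantom(
        seed=1, tumor=TumorShape(semi_axes=(6.0, 6.0, 6.0)),
        with_ground_truth_margins=False,
    )


@pytest.fixture(scope="session")
def concentric_spheres():
    """Tumor sphere r=1 centered in specimen sphere r=2, as SpecimenModel + mesh."""
    ph = make_phantom(
        seed=7,
        specimen=SpecimenShape((2.0, 2.0, 2.0), 2.0),
        tumor=TumorShape(semi_axes=(1.0, 1.0, 1.0)),
        with_ground_truth_margins=False,
    )
    spec = SpecimenModel(
        mesh=ph.specimen_mesh(4),
        frame=AnatomicalFrame(np.eye(3), np.zeros(3)),
        fiducials=[],
        residual_mm=0.0,
    )
    return spec, ph.tumor_mesh(4)


@pytest.fixture
def icosphere_mesh():
    def make(subdivisions=3, radius=10.0):
        tm = trimesh.creation.icosphere(subdivisions, radius)
        return SurfaceMesh.from_trimesh(tm, "test")

    return make


@pytest.fixture
def unit_cube():
    tm = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return SurfaceMesh.from_trimesh(tm, "cube")


def identity_specimen(mesh):
    return SpecimenModel(
        mesh=mesh,
        frame=AnatomicalFrame(np.eye(3), np.zeros(3)),
        fiducials=[],
        residual_mm=0.0,
    )


@pytest.fixture
def as_specimen():
    return identity_specimen
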