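"""Directional margins and formalin-shrinkage correction."""

import numpy as np
import pytest

from t3d.errors import ParameterError
from t3d.margins_shrinkage import (
    DIRECTIONS,
    MarginReport,
    ShrinkageFactor,
    apply_shrinkage,
    directional_margins,
    label_faces,
)
from t3d.mesh_core import SurfaceMesh
from t3d.phantom import SpecimenShape, TumorShape, _random_rotation, make_phantom
from t3d.specimen_frame import AnatomicalFrame, SpecimenModel


def test_concentric_spheres_six_equal_margins(concentric_spheres):
    spec, tumor = concentric_spheres
    rep = directional_margins(tumor, spec)
    vals = np.array([rep.directional_margins_mm[d] for d in DIRECTIONS])
    # icosahedral symmetry: the six directions are exactly equivalent
    assert np.ptp(vals) < 1e-9
    assert rep.closest_margin_mm == pytest.approx(vals.min(), abs=1e-12)
    # the polyhedral gap equals the analytic 1 mm up to the sagitta
    assert vals[0] == pytest.approx(1.0, abs=5e-3)


def test_displaced_tumor_shifts_margins():
    ph = make_phantom(
        seed=11,
        specimen=SpecimenShape((2.0, 2.0, 2.0), 2.0),
        tumor=TumorShape(center=(0, 0, -0.5), semi_axes=(1.0, 1.0, 1.0)),
        with_ground_truth_margins=False,
    )
    spec = SpecimenModel(ph.specimen_mesh(4), AnatomicalFrame(np.eye(3), np.zeros(3)), [], 0.0)
    rep = directional_margins(ph.tumor_mesh(4), spec)
    assert rep.directional_margins_mm["deep"] == pytest.approx(0.5, abs=0.01)
    # the superior class extends to the 45-degree label boundary, whose
    # closest point to the displaced tumor is nearer than the pole's 1.5 mm:
    # min over the class is sqrt(2 + (sqrt(2)+0.5)^2) - 1 ~ 1.38 mm at the rim
    sup = rep.directional_margins_mm["superior"]
    assert 1.25 < sup < 1.45
    assert rep.closest_direction == "deep"
    assert rep.largest_direction == "superior"


def test_closest_equals_unrestricted_minimum(default_phantom):
    from _oracles import brute_min_distance

    spec = SpecimenModel(
        default_phantom.specimen_mesh(4),
        AnatomicalFrame(np.eye(3), np.zeros(3)),
        [],
        0.0,
    )
    tumor = default_phantom.tumor_mesh(4)
    rep = directional_margins(tumor, spec)
    free = min(
        brute_min_distance(tumor.vertices, spec.mesh.vertices[spec.mesh.faces]),
        brute_min_distance(spec.mesh.vertices, tumor.vertices[tumor.faces]),
    )
    assert rep.closest_margin_mm == pytest.approx(free, abs=1e-9)


def test_margins_invariant_under_common_rigid_motion(default_phantom):
    """Moving tumor and specimen together must not change any margin."""
    spec_mesh = default_phantom.specimen_mesh(4)
    tumor = default_phantom.tumor_mesh(4)
    base = directional_margins(
        tumor,
        SpecimenModel(spec_mesh, AnatomicalFrame(np.eye(3), np.zeros(3)), [], 0.0),
    )
    rng = np.random.default_rng(2)
    R = _random_rotation(rng)
    t = rng.uniform(-15, 15, 3)
    # classification must follow the anatomical frame, so the moved pair is
    # compared after mapping back into it
    moved = directional_margins(
        tumor.transformed(R, t).transformed(R.T, -R.T @ t),
        SpecimenModel(
            spec_mesh.transformed(R, t).transformed(R.T, -R.T @ t),
            AnatomicalFrame(np.eye(3), np.zeros(3)),
            [],
            0.0,
        ),
    )
    for d in DIRECTIONS:
        assert moved.directional_margins_mm[d] == pytest.approx(
            base.directional_margins_mm[d], abs=1e-9
        )


def test_face_labels_cover_all_directions(default_phantom):
    spec = SpecimenModel(
        default_phantom.specimen_mesh(4), AnatomicalFrame(np.eye(3), np.zeros(3)), [], 0.0
    )
    labels = label_faces(spec)
    assert set(np.unique(labels)) == set(range(6))


def test_protruding_tumor_reports_zero_with_warning():
    ph = make_phantom(
        seed=13,
        specimen=SpecimenShape((5.0, 5.0, 5.0), 2.0),
        tumor=TumorShape(center=(0, 0, 3.0), semi_axes=(2.0, 2.0, 2.5)),
        require_containment=False,
        with_ground_truth_margins=False,
    )
    spec = SpecimenModel(ph.specimen_mesh(4), AnatomicalFrame(np.eye(3), np.zeros(3)), [], 0.0)
    with pytest.warns(UserWarning, match="protrudes"):
        rep = directional_margins(ph.tumor_mesh(4), spec)
    assert rep.directional_margins_mm["superior"] == 0.0
    assert rep.closest_margin_mm == 0.0


class TestShrinkage:
    def test_zero_factor_is_identity(self, concentric_spheres):
        spec, tumor = concentric_spheres
        rep = directional_margins(tumor, spec)
        out = apply_shrinkage(rep, ShrinkageFactor(0.0))
        for d in DIRECTIONS:
            assert out.corrected_directional_margins_mm[d] == rep.directional_margins_mm[d]
        assert out.corrected_tumor_volume_mm3 == rep.tumor_volume_mm3

    @pytest.mark.parametrize("f", [0.14, 0.24])
    def test_isotropic_length_scaling(self, f):
        s = ShrinkageFactor(f)
        assert 10.0 * s.scale[0] == pytest.approx(10.0 / (1 - f), abs=1e-12)
        assert s.volume_scale == pytest.approx((1 / (1 - f)) ** 3, abs=1e-12)

    def test_mesh_volume_scales_by_cube_law(self, icosphere_mesh):
        from t3d.mesh_core import mesh_volume

        mesh = icosphere_mesh(3, 5.0)
        out = apply_shrinkage(mesh, ShrinkageFactor(0.24))
        assert mesh_volume(out) == pytest.approx(
            mesh_volume(mesh) / 0.76**3, rel=1e-12
        )

    def test_correction_commutes_with_measurement(self, concentric_spheres):
        """Scale-then-measure equals measure-then-scale (isotropic)."""
        spec, tumor = concentric_spheres
        f = ShrinkageFactor(0.14)
        rep_then_scale = apply_shrinkage(directional_margins(tumor, spec), f)
        scaled_spec = SpecimenModel(
            apply_shrinkage(spec.mesh, f), spec.frame, [], 0.0
        )
        scale_then_rep = directional_margins(apply_shrinkage(tumor, f), scaled_spec)
        for d in DIRECTIONS:
            assert rep_then_scale.corrected_directional_margins_mm[d] == pytest.approx(
                scale_then_rep.directional_margins_mm[d], abs=1e-9
            )

    def test_per_axis_mode(self):
        s = ShrinkageFactor((0.1, 0.2, 0.0), mode="per-axis")
        np.testing.assert_allclose(s.scale, [1 / 0.9, 1 / 0.8, 1.0])

    @pytest.mark.parametrize("f", [-0.01, 0.5, 0.9])
    def test_fraction_range_enforced(self, f):
        with pytest.raises(ParameterError):
            ShrinkageFactor(f)

    def test_report_serialization_roundtrip(self, concentric_spheres):
        import json

        spec, tumor = concentric_spheres
        rep = apply_shrinkage(directional_margins(tumor, spec), ShrinkageFactor(0.14))
        d = json.loads(rep.to_json())
        assert d["shrinkage_factor_applied"] == [0.14] * 3
        assert "corrected_closest_margin_mm" in d
        text = rep.to_text()
        assert "closest" in text and "mm" in text
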