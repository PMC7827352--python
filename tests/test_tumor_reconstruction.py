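"""Resampling, lofting, and cross-section consistency."""

import warnings

import numpy as np
import pytest

from t3d.contour_registration import PlacedContour
from t3d.errors import ParameterError, TopologyError
from t3d.geometry import lift_from_plane
from t3d.mesh_core import mesh_volume
from t3d.tumor_reconstruction import (
    ContourStack,
    cross_section_consistency,
    loft_contours,
    reconstruct_tumor,
    resample_contour,
)

W = np.array([0.0, 1.0, 0.0])


def contour(points2, y, label="X", index=0):
    v3 = lift_from_plane(np.asarray(points2, dtype=float), [0, y, 0], W)
    return PlacedContour(label, v3, [0, y, 0], W, index=index)


def circle(r, y, n=100, phase=0.0, center=(0.0, 0.0)):
    t = np.arange(n) * 2 * np.pi / n + phase
    return contour(
        np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)]), y
    )


def square(side, y, n=None):
    h = side / 2.0
    pts = np.array([[-h, -h], [h, -h], [h, h], [-h, h]])
    c = contour(pts, y)
    return resample_contour(c, n) if n else c


class TestResample:
    def test_square_to_8_hits_corners_and_midpoints(self):
        c = resample_contour(square(4.0, 0.0), 8)
        expected = np.array(
            [[-2, -2], [0, -2], [2, -2], [2, 0], [2, 2], [0, 2], [-2, 2], [-2, 0]],
            dtype=float,
        )
        np.testing.assert_allclose(c.vertices2, expected, atol=1e-12)

    def test_idempotent_on_uniform_polygon(self):
        c1 = resample_contour(circle(5.0, 0.0, 64), 64)
        c2 = resample_contour(c1, 64)
        np.testing.assert_allclose(c1.vertices, c2.vertices, atol=1e-9)

    def test_circle_perimeter_preserved(self):
        c = resample_contour(circle(5.0, 0.0, 720), 360)
        assert c.perimeter_mm == pytest.approx(2 * np.pi * 5, rel=1e-3)

    def test_orientation_and_area_kept(self):
        c0 = circle(3.0, 1.0, 50)
        c1 = resample_contour(c0, 200)
        assert np.sign(_signed_area(c1)) == np.sign(_signed_area(c0))
        assert c1.area_mm2 == pytest.approx(c0.area_mm2, rel=2e-3)

    def test_too_few_points(self):
        with pytest.raises(ParameterError):
            resample_contour(circle(1.0, 0.0), 2)


def _signed_area(c):
    from t3d.geometry import polygon_area

    return polygon_area(c.vertices2)


class TestLoft:
    def test_identical_squares_make_exact_prism(self):
        stack = ContourStack([square(10.0, 5.0), square(10.0, 0.0)])
        mesh = loft_contours(stack, end_cap="flat")
        assert mesh.is_watertight
        assert mesh_volume(mesh) == pytest.approx(500.0, abs=1e-9)

    def test_conical_frustum_volume(self):
        stack = ContourStack([circle(5.0, 4.0, 200), circle(3.0, 0.0, 200)])
        mesh = loft_contours(stack, end_cap="flat")
        analytic = np.pi * 4 / 3 * (25 + 15 + 9)
        assert mesh_volume(mesh) == pytest.approx(analytic, rel=0.02)

    def test_single_contour_extrudes_to_slab_thickness(self):
        stack = ContourStack([square(6.0, 2.0)], terminal_thickness_mm=3.0)
        mesh = loft_contours(stack)
        assert mesh_volume(mesh) == pytest.approx(36.0 * 3.0, abs=1e-9)

    def test_reversed_stack_same_volume(self):
        cs = [circle(5, 6.0), circle(6, 3.0), circle(4, 0.0)]
        v1 = mesh_volume(loft_contours(ContourStack(cs), end_cap="flat"))
        v2 = mesh_volume(loft_contours(ContourStack(cs[::-1]), end_cap="flat"))
        assert v1 == pytest.approx(v2, abs=1e-9)

    def test_rotation_equivariance(self):
        """Rotating every ring by one common in-plane angle leaves the body
        congruent (same volume and area)."""
        a = ContourStack([circle(5, 3.0, 80), circle(3, 0.0, 80)])
        b = ContourStack(
            [circle(5, 3.0, 80, phase=0.7), circle(3, 0.0, 80, phase=0.7)]
        )
        ma = loft_contours(a, end_cap="flat")
        mb = loft_contours(b, end_cap="flat")
        assert mesh_volume(ma) == pytest.approx(mesh_volume(mb), abs=1e-9)

    def test_shift_correspondence_handles_offset_start_points(self):
        a = ContourStack([circle(5, 3.0, 80), circle(5, 0.0, 80, phase=1.9)])
        mesh = loft_contours(a, end_cap="flat")
        # near-cylinder: twisting correspondence would lose volume
        assert mesh_volume(mesh) == pytest.approx(3 * np.pi * 25, rel=0.01)

    def test_unequal_counts_rejected(self):
        with pytest.raises(TopologyError):
            loft_contours(ContourStack([circle(5, 3.0, 80), circle(5, 0.0, 60)]))

    def test_apex_caps_add_cone_volume(self):
        stack = ContourStack([circle(5, 3.0, 100), circle(5, 0.0, 100)])
        flat = mesh_volume(loft_contours(stack, end_cap="flat"))
        apex = mesh_volume(loft_contours(stack, end_cap="apex"))
        cones = 2 * np.pi * 25 * 1.5 / 3
        assert apex - flat == pytest.approx(cones, rel=0.01)


class TestReconstruct:
    def test_disjoint_groups_become_components(self):
        prim = [
            circle(2, 3.0, 50, center=(-5, 0)),
            circle(2, 0.0, 50, center=(-5, 0)),
        ]
        for c in prim:
            c.index = 0
        other = [
            circle(1.5, 3.0, 50, center=(5, 0)),
            circle(1.5, 0.0, 50, center=(5, 0)),
        ]
        for c in other:
            c.index = 1
        tumor, report = reconstruct_tumor(prim + other, end_cap="flat")
        assert report["n_components"] == 2
        assert len(report["component_volumes_mm3"]) == 2

    def test_union_mode_falls_back_without_engine(self):
        prim = [circle(3, 3.0, 50), circle(3, 0.0, 50)]
        sec = [circle(3, 3.0, 50)]
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            tumor, report = reconstruct_tumor(prim, sec, mode="union", end_cap="flat")
        assert tumor.is_watertight
        if report["mode"] != "union":
            assert "fallback" in report["mode"]
            assert any("union" in str(x.message) for x in w)

    def test_primary_only_report_shape(self):
        prim = [circle(4, 4.0, 100), circle(4, 0.0, 100)]
        tumor, report = reconstruct_tumor(prim, None, end_cap="flat")
        assert report["secondary_overlap"] == {}
        assert report["n_components"] == 1


class TestCrossSection:
    def test_contour_equal_to_section_gives_one(self):
        stack = ContourStack([square(8.0, 4.0), square(8.0, 0.0)])
        mesh = loft_contours(stack, end_cap="flat")
        probe = square(8.0, 2.0)
        assert cross_section_consistency(mesh, probe) == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_contour_gives_zero(self):
        stack = ContourStack([square(8.0, 4.0), square(8.0, 0.0)])
        mesh = loft_contours(stack, end_cap="flat")
        probe = circle(1.0, 2.0, 30, center=(30.0, 0.0))
        assert cross_section_consistency(mesh, probe) == 0.0

    def test_plane_missing_tumor_warns_and_returns_zero(self):
        stack = ContourStack([square(8.0, 4.0), square(8.0, 0.0)])
        mesh = loft_contours(stack, end_cap="flat")
        probe = square(8.0, 25.0)
        with pytest.warns(UserWarning, match="misses"):
            assert cross_section_consistency(mesh, probe) == 0.0

    def test_offcenter_sphere_section_matches_analytic_circle(self, sphere_tumor_phantom):
        mesh = sphere_tumor_phantom.tumor_mesh(5)
        r = np.sqrt(36.0 - 9.0)
        probe = circle(r, 3.0, 200)
        assert cross_section_consistency(mesh, probe) >= 0.99


def test_loft_volume_converges_on_sphere_sections():
    """Finer slicing gives strictly smaller volume error for a sphere."""
    r = 6.0

    def loft_at(h):
        ys = np.arange(-r + h / 2, r, h)
        cs = [circle(np.sqrt(r * r - y * y), y, 100) for y in ys]
        return mesh_volume(loft_contours(ContourStack(cs), end_cap="apex"))

    analytic = 4 / 3 * np.pi * r**3
    errs = [abs(loft_at(h) - analytic) / analytic for h in (3.0, 1.0)]
    assert errs[1] < errs[0]
    assert errs[0] < 0.10
    assert errs[1] < 0.02
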