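"""Ink-line registration of slide outlines onto section planes."""

import numpy as np
import pytest

from t3d.contour_registration import (
    TumorContour,
    contours_from_records,
    load_contours,
    register_contour,
)
from t3d.errors import FlippedSlideError, FormatError, MisalignmentError
from t3d.grossing import GrossingPlan, plan_grossing
from t3d.phantom import grossing_plan_for, make_phantom, simulate_grossing
from t3d.specimen_frame import orient_specimen


@pytest.fixture(scope="module")
def oriented(default_phantom):
    ph = default_phantom
    spec = orient_specimen(ph.specimen_mesh(4), ph.fiducials("anatomical"))
    spec.ink_lines = ph.ink_lines
    return ph, spec


def phantom_case(ph, spec, spacing=3.0, **kw):
    plan = grossing_plan_for(ph, spacing_mm=spacing)
    slabs = plan_grossing(spec, plan)
    by = {s.label: s for s in slabs}
    contours = simulate_grossing(ph, plan, **kw)
    return contours, by


def test_identity_placement_zero_residual(oriented):
    ph, spec = oriented
    contours, by = phantom_case(ph, spec, slide_motion=False)
    placed = register_contour(contours[0], by[contours[0].slab_label], spec)
    assert placed.residual_mm == pytest.approx(0.0, abs=1e-12)
    # without slide motion the slide frame IS the plane frame
    np.testing.assert_allclose(placed.vertices2, _ccw(contours[0].vertices), atol=1e-9)


def _ccw(poly):
    from t3d.geometry import polygon_area

    return poly if polygon_area(poly) > 0 else poly[::-1]


def test_known_rigid_motion_recovered(oriented):
    """A rotated and shifted slide lands back on the analytic section."""
    ph, spec = oriented
    ref, by = phantom_case(ph, spec, slide_motion=False)
    moved, _ = phantom_case(ph, spec, slide_motion=True)
    for c0, c1 in zip(ref, moved):
        p0 = register_contour(c0, by[c0.slab_label], spec)
        p1 = register_contour(c1, by[c1.slab_label], spec)
        np.testing.assert_allclose(p0.vertices, p1.vertices, atol=1e-9)
        assert p1.residual_mm < 1e-9


def test_explicit_30deg_shift_recovered(oriented):
    ph, spec = oriented
    ref, by = phantom_case(ph, spec, slide_motion=False)
    c0 = ref[0]
    th = np.radians(30)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    t = np.array([4.0, -2.0])
    moved = TumorContour(
        c0.slab_label,
        c0.vertices @ R.T + t,
        {k: v @ R.T + t for k, v in c0.ink_marks.items()},
    )
    p0 = register_contour(c0, by[c0.slab_label], spec)
    p1 = register_contour(moved, by[c0.slab_label], spec)
    np.testing.assert_allclose(p0.vertices, p1.vertices, atol=1e-9)


def test_mirrored_slide_rejected(oriented):
    ph, spec = oriented
    ref, by = phantom_case(ph, spec, slide_motion=False)
    c0 = ref[0]
    M = np.array([[-1.0, 0.0], [0.0, 1.0]])
    flipped = TumorContour(
        c0.slab_label,
        c0.vertices @ M.T,
        {k: v @ M.T for k, v in c0.ink_marks.items()},
    )
    with pytest.raises(FlippedSlideError):
        register_contour(flipped, by[c0.slab_label], spec)


def test_area_and_perimeter_preserved(oriented):
    ph, spec = oriented
    contours, by = phantom_case(ph, spec)
    for c in contours:
        p = register_contour(c, by[c.slab_label], spec)
        assert p.area_mm2 == pytest.approx(c.area_mm2, abs=1e-9)
        assert p.perimeter_mm == pytest.approx(c.perimeter_mm, abs=1e-9)


def test_placed_contours_lie_on_analytic_cross_section(oriented):
    """With exact ink marks, placed vertices satisfy the tumor's ellipsoid
    equation restricted to the section plane."""
    ph, spec = oriented
    contours, by = phantom_case(ph, spec)
    M = ph.tumor.quadric
    for c in contours:
        p = register_contour(c, by[c.slab_label], spec)
        d = p.vertices - ph.tumor.center
        q = np.einsum("ij,jk,ik->i", d, M, d)
        np.testing.assert_allclose(q, 1.0, atol=1e-6)


def test_jitter_bounds_residual(oriented):
    ph, spec = oriented
    jitter = 0.4
    contours, by = phantom_case(ph, spec, ink_jitter_mm=jitter)
    for c in contours:
        p = register_contour(c, by[c.slab_label], spec)
        assert p.residual_mm <= 2 * jitter


def test_residual_tolerance_enforced(oriented):
    ph, spec = oriented
    contours, by = phantom_case(ph, spec, ink_jitter_mm=0.5)
    with pytest.raises(MisalignmentError):
        for c in contours:
            register_contour(c, by[c.slab_label], spec, residual_tol_mm=1e-6)


def test_vertices_on_section_plane(oriented):
    ph, spec = oriented
    contours, by = phantom_case(ph, spec)
    p = register_contour(contours[0], by[contours[0].slab_label], spec)
    dist = (p.vertices - p.plane_origin) @ p.plane_normal
    np.testing.assert_allclose(dist, 0.0, atol=1e-9)


class TestContourJSON:
    def good_record(self):
        t = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        return {
            "slab": "B",
            "polygon": np.column_stack([5 * np.cos(t), 5 * np.sin(t)]).tolist(),
            "ink_marks": {
                "dorsal_line": [[0.0, 6.0], [0.0, 4.0]],
                "perpendicular_line": [[-6.0, 0.0], [-4.0, 0.0]],
            },
            "index": 0,
        }

    def test_roundtrip(self, tmp_path):
        import json

        path = tmp_path / "c.json"
        path.write_text(json.dumps([self.good_record()]))
        (c,) = load_contours(path)
        assert c.slab_label == "B"
        assert len(c.vertices) == 50

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError, match="missing.json"):
            load_contours(tmp_path / "missing.json")

    def test_missing_ink_mark(self):
        rec = self.good_record()
        del rec["ink_marks"]["dorsal_line"]
        with pytest.raises(FormatError, match="dorsal_line"):
            contours_from_records([rec])

    def test_self_intersecting_polygon(self):
        rec = self.good_record()
        rec["polygon"] = [[0, 0], [2, 2], [2, 0], [0, 2]]
        with pytest.raises(FormatError, match="self-intersecting"):
            contours_from_records([rec])

    def test_non_perpendicular_ink_lines(self):
        rec = self.good_record()
        rec["ink_marks"]["perpendicular_line"] = [[0.0, 6.0], [2.0, 0.0]]
        with pytest.raises(FormatError, match="deg"):
            contours_from_records([rec])
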