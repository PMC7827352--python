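"""Phantom generator: determinism, closed forms, simulated scan/grossing."""

import numpy as np
import pytest

from t3d.errors import GenerationError
from t3d.geometry import points_to_triangles_distance
from t3d.grossing import GrossingPlan
from t3d.mesh_core import boundary_loops, mesh_volume
from t3d.phantom import (
    SpecimenShape,
    TumorShape,
    grossing_plan_for,
    make_phantom,
    make_random_phantom,
    simulate_grossing,
    simulate_scan,
)

from _oracles import column_volume


def test_default_tumor_volume_closed_form(default_phantom):
    assert default_phantom.ground_truth["tumor_volume_mm3"] == pytest.approx(
        4 / 3 * np.pi * 6 * 4 * 3, abs=1e-9
    )


def test_superellipsoid_volume_matches_column_oracle(default_phantom):
    mesh = default_phantom.specimen_mesh(5)
    assert mesh_volume(mesh) == pytest.approx(
        default_phantom.ground_truth["specimen_volume_mm3"], rel=0.005
    )
    assert mesh_volume(mesh) == pytest.approx(column_volume(mesh, 0.25), rel=0.01)


def test_same_seed_bit_identical():
    a = make_phantom(seed=5, with_ground_truth_margins=False)
    b = make_phantom(seed=5, with_ground_truth_margins=False)
    np.testing.assert_array_equal(a.scan_rotation, b.scan_rotation)
    sa = simulate_scan(a, holes=2, hole_diams_mm=[2, 4], noise_mm=0.2)
    sb = simulate_scan(b, holes=2, hole_diams_mm=[2, 4], noise_mm=0.2)
    np.testing.assert_array_equal(sa.vertices, sb.vertices)
    np.testing.assert_array_equal(sa.faces, sb.faces)
    plan = grossing_plan_for(a)
    ca = simulate_grossing(a, plan, 2.0, 0.3)
    cb = simulate_grossing(b, plan, 2.0, 0.3)
    for x, y in zip(ca, cb):
        np.testing.assert_array_equal(x.vertices, y.vertices)


def test_oversized_tumor_rejected():
    with pytest.raises(GenerationError, match="inside"):
        make_phantom(
            seed=0,
            tumor=TumorShape(semi_axes=(30.0, 4.0, 3.0)),
            with_ground_truth_margins=False,
        )


def test_random_phantoms_always_contained():
    for seed in range(5):
        ph = make_random_phantom(seed, with_ground_truth_margins=False)
        assert ph.ground_truth["tumor_max_implicit"] < 1.0


class TestSimulateScan:
    def test_clean_scan_watertight_with_accurate_volume(self, default_phantom):
        scan = simulate_scan(default_phantom, holes=0, noise_mm=0.0, subdivisions=5, coords="anatomical")
        assert scan.is_watertight
        assert mesh_volume(scan) == pytest.approx(
            default_phantom.ground_truth["specimen_volume_mm3"], rel=0.005
        )

    def test_requested_holes_become_boundary_loops(self, default_phantom):
        scan = simulate_scan(default_phantom, holes=3, hole_diams_mm=[1, 3, 5])
        assert len(boundary_loops(scan)) == 3

    def test_noise_bounded_in_hausdorff_distance(self, default_phantom):
        amp = 0.2
        clean = simulate_scan(default_phantom, noise_mm=0.0, coords="anatomical")
        noisy = simulate_scan(default_phantom, noise_mm=amp, coords="anatomical")
        d = points_to_triangles_distance(noisy.vertices, clean.vertices[clean.faces])
        assert d.max() <= amp + 1e-9

    def test_hole_count_validated(self, default_phantom):
        with pytest.raises(GenerationError):
            simulate_scan(default_phantom, holes=4, hole_diams_mm=[1, 1, 1, 1])

    def test_huge_hole_rejected(self, default_phantom):
        with pytest.raises(GenerationError, match="patch"):
            simulate_scan(default_phantom, holes=1, hole_diams_mm=[15.0])


class TestSimulateGrossing:
    def test_central_cut_through_sphere_gives_full_circle(self, sphere_tumor_phantom):
        ph = sphere_tumor_phantom
        b = ph.specimen.semi_axes[1]
        plan = GrossingPlan(cut_positions=[b])  # through y = 0
        (c,) = simulate_grossing(ph, plan, slide_motion=False)
        assert c.area_mm2 == pytest.approx(np.pi * 36, rel=1e-3)

    def test_cut_outside_tumor_yields_no_contour(self, sphere_tumor_phantom):
        ph = sphere_tumor_phantom
        b = ph.specimen.semi_axes[1]
        plan = GrossingPlan(cut_positions=[b - 10.0])  # y = +10, tumor ends at 6
        assert simulate_grossing(ph, plan) == []

    def test_plan_phased_to_straddle_tumor_center(self, sphere_tumor_phantom):
        ph = sphere_tumor_phantom
        plan = grossing_plan_for(ph, spacing_mm=3.0)
        b = ph.specimen.semi_axes[1]
        ys = b - np.asarray(plan.cut_positions)
        assert np.isclose(np.abs(ys) % 3.0, 1.5).all()

    def test_tilted_knife_changes_sections_within_bound(self, sphere_tumor_phantom):
        ph = sphere_tumor_phantom
        plan = grossing_plan_for(ph, spacing_mm=3.0)
        straight = simulate_grossing(ph, plan, knife_tilt_deg=0.0, slide_motion=False)
        tilted = simulate_grossing(ph, plan, knife_tilt_deg=3.0, slide_motion=False)
        assert len(straight) == len(tilted)
        # a tilted section of a sphere is still a circle of similar area
        for s, t in zip(straight, tilted):
            assert t.area_mm2 == pytest.approx(s.area_mm2, rel=0.1)
            assert not np.allclose(t.vertices, s.vertices)


def test_end_to_end_volume_error_decreases_with_spacing(sphere_tumor_phantom):
    """With straight cuts and exact ink marks, the only reconstruction error
    is the slicing discretization: halving the spacing shrinks it."""
    import warnings

    from t3d.contour_registration import register_contour
    from t3d.grossing import plan_grossing
    from t3d.specimen_frame import orient_specimen
    from t3d.tumor_reconstruction import reconstruct_tumor

    ph = sphere_tumor_phantom
    spec = orient_specimen(ph.specimen_mesh(4), ph.fiducials("anatomical"))
    spec.ink_lines = ph.ink_lines
    gt = ph.ground_truth["tumor_volume_mm3"]
    errs = []
    for h in (4.0, 2.0, 1.0):
        plan = grossing_plan_for(ph, spacing_mm=h)
        by = {s.label: s for s in plan_grossing(spec, plan)}
        contours = simulate_grossing(ph, plan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            placed = [register_contour(c, by[c.slab_label], spec) for c in contours]
        tumor, _ = reconstruct_tumor(placed, end_cap="apex")
        errs.append(abs(mesh_volume(tumor) - gt) / gt)
    assert errs[0] > errs[1] > errs[2]
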