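"""Synthetic specimen/tumor phantoms with analytic ground truth.

The digital stand-in for the test tissue block is a superellipsoid
(|x/a|^p + |y/b|^p + |z/c|^p = 1): at exponent p=2 an ellipsoid, at larger
p an increasingly box-like solid resembling a trimmed soft-tissue block.
A fictional tumor is an ellipsoid (center, semi-axes, rotation) placed
strictly inside it. Everything downstream of the scanner can then be
exercised with no external data, because the generator emits exactly the
pipeline's input formats — an STL "scan" (optionally with the blind-spot
holes and smooth surface noise a structured-light scan of moist tissue
shows), fiducial needles, ink-line definitions, and per-cut tumor
contours — while volumes, extents, and margins remain available in closed
form or from a dense, seeded sampling oracle.

The stated inaccuracy sources of manual grossing are reproducible on
demand: a knife tilted by a bounded random angle (the downstream pipeline
still assumes straight cuts) and ink marks jittered by a bounded amount.

All randomness derives from the single phantom seed; repeated calls with
the same seed give bit-identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from scipy.special import gamma

from .contour_registration import TumorContour, ink_trace
from .errors import GenerationError, PlanError
from .geometry import plane_basis, polygon_area
from .grossing import GrossingPlan, slab_labels
from .mesh_core import SurfaceMesh
from .specimen_frame import CONVENTION, Fiducial, InkLinePlane

log = logging.getLogger(__name__)

DEFAULT_SPECIMEN_SEMI_AXES = (20.0, 15.0, 10.0)  # 40 x 30 x 20 mm block
DEFAULT_SPECIMEN_EXPONENT = 4.0
DEFAULT_TUMOR_SEMI_AXES = (6.0, 4.0, 3.0)  # 12 x 8 x 6 mm
ORACLE_SAMPLES = 100_000

_DIRECTIONS = ("anterior", "posterior", "left", "right", "superior", "deep")


@dataclass
class SpecimenShape:
    """Superellipsoid specimen: semi-axes (mm) and exponent."""

    semi_axes: tuple = DEFAULT_SPECIMEN_SEMI_AXES
    exponent: float = DEFAULT_SPECIMEN_EXPONENT

    def __post_init__(self):
        self.semi_axes = tuple(float(a) for a in self.semi_axes)
        if min(self.semi_axes) <= 0 or self.exponent < 2:
            raise GenerationError("specimen semi-axes must be > 0 and exponent >= 2")

    def implicit(self, pts: np.ndarray) -> np.ndarray:
        """< 1 inside, 1 on the surface, > 1 outside."""
        a = np.asarray(self.semi_axes)
        return np.sum(np.abs(np.asarray(pts) / a) ** self.exponent, axis=-1)

    def radius(self, dirs: np.ndarray) -> np.ndarray:
        """Surface distance from the origin along unit directions."""
        return self.implicit(dirs) ** (-1.0 / self.exponent)

    def surface_points(self, dirs: np.ndarray) -> np.ndarray:
        return dirs * self.radius(dirs)[:, None]

    def normals(self, pts: np.ndarray) -> np.ndarray:
        a = np.asarray(self.semi_axes)
        p = self.exponent
        g = p * np.sign(pts) * np.abs(pts) ** (p - 1) / a**p
        return g / np.linalg.norm(g, axis=-1, keepdims=True)

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        p = self.exponent
        return 8.0 * a * b * c * gamma(1 + 1 / p) ** 3 / gamma(1 + 3 / p)


@dataclass
class TumorShape:
    """Ellipsoidal tumor: center, semi-axes (mm), rotation matrix."""

    center: tuple = (0.0, 0.0, 0.0)
    semi_axes: tuple = DEFAULT_TUMOR_SEMI_AXES
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.semi_axes = tuple(float(a) for a in self.semi_axes)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if min(self.semi_axes) <= 0:
            raise GenerationError("tumor semi-axes must be > 0")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise GenerationError("tumor rotation must be a proper rotation matrix")

    def surface_points(self, unit_sphere: np.ndarray) -> np.ndarray:
        a = np.asarray(self.semi_axes)
        return self.center + (unit_sphere * a) @ self.rotation.T

    @property
    def quadric(self) -> np.ndarray:
        """M with (x - c)^T M (x - c) = 1 on the surface."""
        a = np.asarray(self.semi_axes)
        return self.rotation @ np.diag(1.0 / a**2) @ self.rotation.T

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit directions."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@dataclass
class Phantom:
    """A synthetic case: shapes, ink lines, scan frame, and ground truth."""

    seed: int
    specimen: SpecimenShape
    tumor: TumorShape
    ink_lines: dict
    scan_rotation: np.ndarray
    scan_translation: np.ndarray
    ground_truth: dict

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])

    # -- meshes ------------------------------------------------------------
    def specimen_mesh(self, subdivisions: int = 5, coords: str = "anatomical") -> SurfaceMesh:
        base = trimesh.creation.icosphere(subdivisions, 1.0)
        dirs = np.asarray(base.vertices)
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        verts = self.specimen.surface_points(dirs)
        mesh = SurfaceMesh(verts, np.asarray(base.faces), provenance="phantom")
        if coords == "scan":
            mesh = mesh.transformed(self.scan_rotation, self.scan_translation)
        return mesh

    def tumor_mesh(self, subdivisions: int = 4) -> SurfaceMesh:
        base = trimesh.creation.icosphere(subdivisions, 1.0)
        dirs = np.asarray(base.vertices)
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        verts = self.tumor.surface_points(dirs)
        return SurfaceMesh(verts, np.asarray(base.faces), provenance="phantom tumor")

    def fiducials(self, coords: str = "scan") -> list[Fiducial]:
        """Needle markers at the six axis extreme points of the specimen."""
        out = []
        for label in _DIRECTIONS:
            d = CONVENTION[label]
            pos = self.specimen.surface_points(d[None])[0]
            if coords == "scan":
                pos = self.scan_rotation @ pos + self.scan_translation
            out.append(Fiducial(label, pos))
        return out


def make_phantom(
    seed: int = 0,
    specimen: SpecimenShape | None = None,
    tumor: TumorShape | None = None,
    require_containment: bool = True,
    oracle_samples: int = ORACLE_SAMPLES,
    with_ground_truth_margins: bool = True,
) -> Phantom:
    """Build a deterministic phantom with its ground-truth record.

    The scan frame (a random proper rigid motion emulating arbitrary
    placement on the scanner turntable) and all later randomness derive
    from ``seed``. Raises :class:`GenerationError` when containment is
    requested but the tumor pokes out of the specimen.
    """
    specimen = specimen or SpecimenShape()
    tumor = tumor or TumorShape()
    probe = tumor.surface_points(_fibonacci_sphere(4096))
    worst = float(specimen.implicit(probe).max())
    if require_containment and worst >= 1.0:
        raise GenerationError(
            f"tumor is not strictly inside the specimen (max implicit {worst:.3f})"
        )
    rng = np.random.default_rng([int(seed), 0])
    R0 = _random_rotation(rng)
    t0 = rng.uniform(-20.0, 20.0, size=3)
    a = specimen.semi_axes
    ink = {
        # antero-posterior stripe on the dorsal surface; its visible mark on
        # a slice face points from the dorsal edge into the tissue (-z)
        "dorsal_line": InkLinePlane(
            "dorsal_line",
            point=(0.25 * a[0], 0.0, 0.0),
            normal=(1.0, 0.0, 0.0),
            direction_hint=(0.0, 0.0, -1.0),
        ),
        # stripe along the left surface, perpendicular to the dorsal line on
        # the slice face; its mark points from the left edge inward (-x)
        "perpendicular_line": InkLinePlane(
            "perpendicular_line",
            point=(0.0, 0.0, -0.25 * a[2]),
            normal=(0.0, 0.0, 1.0),
            direction_hint=(-1.0, 0.0, 0.0),
        ),
    }
    gt = {
        "seed": int(seed),
        "specimen_volume_mm3": specimen.volume_mm3,
        "tumor_volume_mm3": tumor.volume_mm3,
        "extents_mm": {
            "left-right": 2 * a[0],
            "anterior-posterior": 2 * a[1],
            "superior-deep": 2 * a[2],
        },
        "tumor_max_implicit": worst,
    }
    ph = Phantom(
        seed=int(seed),
        specimen=specimen,
        tumor=tumor,
        ink_lines=ink,
        scan_rotation=R0,
        scan_translation=t0,
        ground_truth=gt,
    )
    if with_ground_truth_margins:
        gt["directional_margins_mm"] = oracle_margins(ph, oracle_samples)
        gt["oracle_samples"] = int(oracle_samples)
    return ph


def oracle_margins(phantom: Phantom, n: int = ORACLE_SAMPLES) -> dict:
    """Brute-force directional margins by dense sampling of the analytic
    surfaces (seeded). Each specimen sample is labeled by the dominant axis
    of its analytic outward normal; the margin toward a direction is the
    minimum sample-to-sample distance to the tumor surface."""
    rng = phantom._rng(1)
    sd = rng.normal(size=(n, 3))
    sd /= np.linalg.norm(sd, axis=1, keepdims=True)
    spts = phantom.specimen.surface_points(sd)
    normals = phantom.specimen.normals(spts)
    dirs = np.array([CONVENTION[d] for d in _DIRECTIONS])
    labels = np.argmax(normals @ dirs.T, axis=1)
    td = rng.normal(size=(n, 3))
    td /= np.linalg.norm(td, axis=1, keepdims=True)
    tpts = phantom.tumor.surface_points(td)
    tree = cKDTree(tpts)
    out = {}
    for i, name in enumerate(_DIRECTIONS):
        mask = labels == i
        if not mask.any():
            out[name] = None
            continue
        d, _ = tree.query(spts[mask], k=1)
        out[name] = float(d.min())
    return out


def make_random_phantom(seed: int, **kw) -> Phantom:
    """A phantom with a seeded random tumor (semi-axes, offset, rotation)
    strictly inside the default specimen; used for margin-recovery suites."""
    rng = np.random.default_rng([int(seed), 99])
    for _ in range(50):
        semi = rng.uniform(3.0, 7.0, size=3)
        center = rng.uniform([-4.0, -4.0, -2.5], [4.0, 4.0, 2.5])
        R = _random_rotation(rng)
        try:
            return make_phantom(
                seed=seed, tumor=TumorShape(center, tuple(semi), R), **kw
            )
        except GenerationError:
            continue
    raise GenerationError(f"could not place a random tumor for seed {seed}")


# ---------------------------------------------------------------------------
# simulated scanning
# ---------------------------------------------------------------------------

def simulate_scan(
    phantom: Phantom,
    holes: int = 0,
    hole_diams_mm=None,
    noise_mm: float = 0.0,
    subdivisions: int = 5,
    coords: str = "scan",
) -> SurfaceMesh:
    """Triangulate the specimen surface as a table scanner would deliver it.

    ``holes`` (0-3) blind-spot holes with the given diameters (1-5 mm) are
    punched at seeded random, well-separated sites; ``noise_mm`` adds a
    smooth radial perturbation of bounded amplitude emulating residual
    soft-tissue deformation and optic-spray texture.
    """
    if not (0 <= holes <= 3):
        raise GenerationError(f"holes must be 0-3, got {holes}")
    diams = list(hole_diams_mm or [])
    if holes and len(diams) != holes:
        raise GenerationError("hole_diams_mm must list one diameter per hole")
    if any(d > min(phantom.specimen.semi_axes) for d in diams):
        raise GenerationError("hole diameter exceeds the local surface patch")
    if noise_mm < 0:
        raise GenerationError("noise_mm must be >= 0")
    rng = phantom._rng(2)
    mesh = phantom.specimen_mesh(subdivisions=subdivisions, coords="anatomical")
    verts = mesh.vertices.copy()
    if noise_mm > 0:
        u = verts / np.linalg.norm(verts, axis=1, keepdims=True)
        g = np.zeros(len(verts))
        for _ in range(4):
            k = rng.normal(size=3) * 0.25
            phase = rng.uniform(0, 2 * np.pi)
            g += np.cos(verts @ k + phase)
        g /= max(float(np.abs(g).max()), 1e-12)
        verts = verts + noise_mm * g[:, None] * u
    faces = mesh.faces
    if holes:
        for attempt in range(30):
            centers = _hole_sites(phantom, rng, diams)
            keep = np.ones(len(faces), dtype=bool)
            centroids = verts[faces].mean(axis=1)
            for c, d in zip(centers, diams):
                keep &= np.linalg.norm(centroids - c, axis=1) > d / 2.0
            cand = SurfaceMesh(verts, faces[keep], provenance="phantom scan")
            from .mesh_core import boundary_loops

            try:
                loops = boundary_loops(cand)
            except Exception:
                continue
            if len(loops) == holes:
                mesh = cand
                break
        else:
            raise GenerationError("could not punch the requested holes cleanly")
    else:
        mesh = SurfaceMesh(verts, faces, provenance="phantom scan")
    if coords == "scan":
        mesh = mesh.transformed(phantom.scan_rotation, phantom.scan_translation)
    return mesh


def _hole_sites(phantom, rng, diams):
    sites = []
    guard = 0
    while len(sites) < len(diams):
        guard += 1
        if guard > 500:
            raise GenerationError("cannot separate hole sites")
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        p = phantom.specimen.surface_points(d[None])[0]
        d_new = diams[len(sites)]
        if all(
            np.linalg.norm(p - q) > (dq + d_new) / 2 + 4.0
            for q, dq in zip(sites, diams)
        ):
            sites.append(p)
    return sites


# ---------------------------------------------------------------------------
# simulated grossing
# ---------------------------------------------------------------------------

def simulate_grossing(
    phantom: Phantom,
    plan: GrossingPlan,
    knife_tilt_deg: float = 0.0,
    ink_jitter_mm: float = 0.0,
    n_points: int = 200,
    slide_motion: bool = True,
) -> list[TumorContour]:
    """Emit per-cut tumor outlines with ink marks, as slides would show them.

    Each cut plane intersects the analytic tumor ellipsoid; non-empty
    sections are polygonized (``n_points`` vertices) and expressed in a
    per-slide 2D frame (a seeded random proper rigid motion, unless
    ``slide_motion`` is off). With ``knife_tilt_deg`` > 0 the physical cut
    is tilted by a seeded random angle up to the bound before
    intersecting, while the emitted slab labels still claim straight cuts
    — reproducing the inaccuracy of manual knife work. Ink-mark endpoints
    are jittered by up to ``ink_jitter_mm``.
    """
    if plan.primary_axis != "anterior-posterior":
        # the phantom's ink-line layout is tied to AP sectioning
        raise PlanError("simulate_grossing supports the anterior-posterior axis")
    if knife_tilt_deg < 0 or ink_jitter_mm < 0:
        raise GenerationError("tilt and jitter bounds must be >= 0")
    rng = phantom._rng(3)
    b = phantom.specimen.semi_axes[1]
    extent = 2 * b
    labels = slab_labels(len(plan.cut_positions) + 1)
    contours: list[TumorContour] = []
    for i, s in enumerate(plan.cut_positions):
        if not (0 < s < extent):
            raise PlanError(f"cut at {s:g} mm is outside the specimen")
        y_c = b - s
        origin = np.array([0.0, y_c, 0.0])
        normal = np.array([0.0, 1.0, 0.0])
        # seeded knife tilt about a random in-plane axis
        tilt = np.radians(rng.uniform(0, knife_tilt_deg)) if knife_tilt_deg > 0 else 0.0
        phi = rng.uniform(0, 2 * np.pi)
        if tilt > 0:
            axis = np.array([np.cos(phi), 0.0, np.sin(phi)])
            normal = _rotate_about(normal, axis, tilt)
        ring2 = _ellipse_section(phantom.tumor, origin, normal, n_points)
        if ring2 is None:
            continue
        marks = {}
        for lab, ink in phantom.ink_lines.items():
            p2, d2 = ink_trace(ink, origin, normal)
            marks[lab] = np.vstack([p2 - 5.0 * d2, p2 + 5.0 * d2])
        if slide_motion:
            theta = rng.uniform(0, 2 * np.pi)
            shift = rng.uniform(-10.0, 10.0, size=2)
        else:
            theta, shift = 0.0, np.zeros(2)
        c, s_ = np.cos(theta), np.sin(theta)
        R2 = np.array([[c, -s_], [s_, c]])
        ring2 = ring2 @ R2.T + shift
        for lab in marks:
            seg = marks[lab] @ R2.T + shift
            if ink_jitter_mm > 0:
                for e in range(2):
                    r = ink_jitter_mm * np.sqrt(rng.uniform())
                    ang = rng.uniform(0, 2 * np.pi)
                    seg[e] += r * np.array([np.cos(ang), np.sin(ang)])
            marks[lab] = seg
        slab_label = labels[i + 1] if plan.section_face == "start" else labels[i]
        contours.append(
            TumorContour(
                slab_label=slab_label, vertices=ring2, ink_marks=marks, index=0
            )
        )
    log.info(
        "simulated grossing: %d cuts, %d tumor-positive slides",
        len(plan.cut_positions),
        len(contours),
    )
    return contours


def _rotate_about(v, axis, angle):
    axis = axis / np.linalg.norm(axis)
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * float(axis @ v) * (1 - np.cos(angle))
    )


def _ellipse_section(tumor: TumorShape, origin, normal, n_points: int):
    """Analytic tumor-plane intersection as a CCW 2D polygon, or None."""
    M = tumor.quadric
    u, v = plane_basis(normal)
    d = np.asarray(origin, dtype=float) - tumor.center
    A = np.array([[u @ M @ u, u @ M @ v], [v @ M @ u, v @ M @ v]])
    bb = np.array([u @ M @ d, v @ M @ d])
    c0 = float(d @ M @ d) - 1.0
    center2 = -np.linalg.solve(A, bb)
    gam = c0 + float(bb @ center2)
    if gam >= -1e-12:
        return None
    lam, Q = np.linalg.eigh(A)
    semi = np.sqrt(-gam / lam)
    t = np.arange(n_points) * 2 * np.pi / n_points
    ring = center2[None, :] + (np.column_stack([np.cos(t), np.sin(t)]) * semi) @ Q.T
    if polygon_area(ring) < 0:
        ring = ring[::-1]
    return ring


# ---------------------------------------------------------------------------
# complete fixture cases
# ---------------------------------------------------------------------------

def grossing_plan_for(
    phantom: Phantom,
    spacing_mm: float = 3.0,
    section_face: str = "start",
    border_margin_mm: float = 0.5,
) -> GrossingPlan:
    """A full antero-posterior grossing plan at the given slice spacing.

    Cuts are phased so the tumor center lies midway between two cuts: the
    slides then bracket the lesion symmetrically, which is how serial
    slices digitize a lesion with the least truncation at its poles.
    """
    if spacing_mm <= 0:
        raise PlanError("spacing must be > 0")
    b = phantom.specimen.semi_axes[1]
    cy = float(phantom.tumor.center[1])
    kmax = int(np.ceil(2 * b / spacing_mm)) + 1
    ys = cy + (np.arange(-kmax, kmax + 1) + 0.5) * spacing_mm
    s = np.sort(b - ys)
    s = s[(s > border_margin_mm) & (s < 2 * b - border_margin_mm)]
    return GrossingPlan(
        cut_positions=[float(v) for v in s], section_face=section_face
    )


def write_phantom_case(
    phantom: Phantom,
    outdir,
    spacing_mm: float = 3.0,
    holes: int = 3,
    hole_diams_mm=(1.0, 3.0, 5.0),
    noise_mm: float = 0.2,
    knife_tilt_deg: float = 0.0,
    ink_jitter_mm: float = 0.0,
    subdivisions: int = 5,
    facet_budget: int = 20_000,
    n_points: int = 100,
    end_cap: str = "apex",
):
    """Write a complete, self-consistent case directory for the pipeline.

    Emits scan.stl (scan coordinates, with holes/noise), fiducials.json
    (needles in scan coordinates + ink lines in anatomical coordinates),
    contours.json (per-cut slides), ground_truth.json, and case.yaml.
    Returns the path of the case.yaml.
    """
    import json as _json
    from pathlib import Path as _Path

    import yaml as _yaml

    from .contour_registration import dump_contours
    from .mesh_core import write_surface

    outdir = _Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scan = simulate_scan(
        phantom,
        holes=holes,
        hole_diams_mm=list(hole_diams_mm)[:holes],
        noise_mm=noise_mm,
        subdivisions=subdivisions,
        coords="scan",
    )
    write_surface(scan, outdir / "scan.stl")
    plan = grossing_plan_for(phantom, spacing_mm=spacing_mm)
    contours = simulate_grossing(
        phantom, plan, knife_tilt_deg=knife_tilt_deg, ink_jitter_mm=ink_jitter_mm
    )
    dump_contours(contours, outdir / "contours.json")
    fid_data = {
        "fiducials": [
            {"label": f.label, "xyz": f.position.tolist()}
            for f in phantom.fiducials(coords="scan")
        ],
        "ink_lines": [
            {
                "label": ink.label,
                "point": ink.point.tolist(),
                "normal": ink.normal.tolist(),
                "direction_hint": ink.direction_hint.tolist(),
            }
            for ink in phantom.ink_lines.values()
        ],
    }
    (outdir / "fiducials.json").write_text(
        _json.dumps(fid_data, indent=1, sort_keys=True)
    )
    (outdir / "ground_truth.json").write_text(
        _json.dumps(phantom.ground_truth, indent=1, sort_keys=True)
    )
    cfg = {
        "seed": int(phantom.seed),
        "paths": {
            "scan_stl": "scan.stl",
            "contours_json": "contours.json",
            "fiducials_json": "fiducials.json",
            "output_dir": "out",
        },
        "facet_budget": int(facet_budget),
        "grossing": {
            "primary_axis": plan.primary_axis,
            "cut_positions": plan.cut_positions,
            "section_face": plan.section_face,
        },
        "tolerances": {"registration_residual_mm": 1.0, "containment_mm": 2.0},
        "shrinkage": {"fraction": 0.0, "mode": "isotropic"},
        "reconstruction": {"mode": "validate", "end_cap": end_cap, "n_points": int(n_points)},
    }
    case_path = outdir / "case.yaml"
    case_path.write_text(_yaml.safe_dump(cfg, sort_keys=True))
    return case_path
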