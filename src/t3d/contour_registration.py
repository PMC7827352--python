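"""Rigid placement of 2D tumor outlines into 3D via ink-line fiducials.

Before grossing, two thin lines of different colors are drawn on the
specimen: one antero-posteriorly on the dorsal surface and one
perpendicular to it. On every slice face each line leaves a short colored
mark, so a slide showing the tumor outline can be oriented and placed on
its section plane without distortion: the dorsal mark's direction fixes
the in-plane rotation and the intersection point of the two (extended)
marks fixes the translation. Only a *proper* rigid motion is accepted — if
matching the marks would require a reflection, the slide was mounted
mirror-wise and an error is raised.

Slide coordinates and section-plane coordinates are both 2D millimetre
frames; ink marks are directed segments (drawing direction), which is what
makes the reflection detectable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import shapely.geometry as sg

from . import geometry
from .errors import FlippedSlideError, FormatError, MisalignmentError
from .grossing import Slab
from .specimen_frame import InkLinePlane, SpecimenModel

log = logging.getLogger(__name__)

INK_LABELS = ("dorsal_line", "perpendicular_line")
DEFAULT_RESIDUAL_TOL_MM = 1.0
DEFAULT_CONTAINMENT_TOL_MM = 2.0
INK_ANGLE_TOL_DEG = 15.0


@dataclass
class TumorContour:
    """A closed 2D tumor outline on one slide, with its two ink marks.

    ``index`` distinguishes disjoint outlines on the same slide (an uneven
    tumor border yields several separate blobs).
    """

    slab_label: str
    vertices: np.ndarray  # (n, 2), open ring, mm in slide coordinates
    ink_marks: dict  # label -> (2, 2) directed segment
    index: int = 0

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.vertices) < 3:
            raise FormatError(
                f"contour for slab {self.slab_label!r} has fewer than 3 vertices"
            )
        # stored as an open ring; drop an explicitly repeated closing vertex
        if np.allclose(self.vertices[0], self.vertices[-1]):
            self.vertices = self.vertices[:-1]
        if not geometry.polygon_is_simple(self.vertices):
            raise FormatError(
                f"contour for slab {self.slab_label!r} is self-intersecting"
            )
        marks = {}
        for lab in INK_LABELS:
            if lab not in self.ink_marks:
                raise FormatError(f"contour for slab {self.slab_label!r} lacks {lab}")
            seg = np.asarray(self.ink_marks[lab], dtype=float).reshape(2, 2)
            if np.linalg.norm(seg[1] - seg[0]) < 1e-9:
                raise FormatError(f"{lab} mark is degenerate (zero length)")
            marks[lab] = seg
        self.ink_marks = marks
        d0 = _unit(self.ink_marks["dorsal_line"][1] - self.ink_marks["dorsal_line"][0])
        d1 = _unit(
            self.ink_marks["perpendicular_line"][1]
            - self.ink_marks["perpendicular_line"][0]
        )
        ang = np.degrees(np.arccos(np.clip(abs(float(d0 @ d1)), 0.0, 1.0)))
        if abs(90.0 - ang) > INK_ANGLE_TOL_DEG:
            raise FormatError(
                f"ink lines of slab {self.slab_label!r} meet at {ang:.1f} deg; "
                f"expected 90 +/- {INK_ANGLE_TOL_DEG:g}"
            )

    @property
    def area_mm2(self) -> float:
        return abs(geometry.polygon_area(self.vertices))

    @property
    def perimeter_mm(self) -> float:
        return geometry.polygon_perimeter(self.vertices)


@dataclass
class PlacedContour:
    """A tumor outline rigidly placed on its 3D section plane.

    Vertices are counter-clockwise when viewed from the plane's view side
    (the anterior side for the default grossing axis).
    """

    slab_label: str
    vertices: np.ndarray  # (n, 3)
    plane_origin: np.ndarray
    plane_normal: np.ndarray
    index: int = 0
    residual_mm: float = 0.0

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.plane_origin = np.asarray(self.plane_origin, dtype=float).reshape(3)
        self.plane_normal = np.asarray(self.plane_normal, dtype=float).reshape(3)

    @property
    def vertices2(self) -> np.ndarray:
        return geometry.project_to_plane(
            self.vertices, self.plane_origin, self.plane_normal
        )

    @property
    def plane_coordinate(self) -> float:
        """Position of the plane along its normal (signed)."""
        return float(self.plane_origin @ self.plane_normal)

    @property
    def area_mm2(self) -> float:
        return abs(geometry.polygon_area(self.vertices2))

    @property
    def perimeter_mm(self) -> float:
        return geometry.polygon_perimeter(self.vertices2)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _cross2(a, b) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def _line_intersection(p0, d0, p1, d1) -> np.ndarray:
    den = _cross2(d0, d1)
    if abs(den) < 1e-12:
        raise MisalignmentError("ink lines are parallel; cannot fix translation")
    t = _cross2(p1 - p0, d1) / den
    return p0 + t * d0


def ink_trace(
    ink: InkLinePlane, plane_origin, plane_normal
) -> tuple[np.ndarray, np.ndarray]:
    """Trace of an ink stripe in a section plane: (point2, unit direction2).

    The stripe plane intersects the section plane in a line; its direction
    sign follows the stripe's drawing direction hint.
    """
    o = np.asarray(plane_origin, dtype=float)
    w = _unit(plane_normal)
    d3 = np.cross(w, ink.normal)
    n3 = np.linalg.norm(d3)
    if n3 < 1e-9:
        raise MisalignmentError(
            f"{ink.label} plane is parallel to the section plane: no trace"
        )
    d3 /= n3
    if float(d3 @ ink.direction_hint) < 0:
        d3 = -d3
    u, v = geometry.plane_basis(w)
    d2 = _unit([float(d3 @ u), float(d3 @ v)])
    # point on the trace: solve (p - q) . m = 0 within the plane
    n2 = np.array([float(u @ ink.normal), float(v @ ink.normal)])
    c = float((ink.point - o) @ ink.normal)
    p2 = n2 * c / float(n2 @ n2)
    return p2, d2


def register_contour(
    contour: TumorContour,
    slab: Slab,
    specimen: SpecimenModel,
    residual_tol_mm: float = DEFAULT_RESIDUAL_TOL_MM,
    containment_tol_mm: float = DEFAULT_CONTAINMENT_TOL_MM,
) -> PlacedContour:
    """Place a slide outline on its slab's section plane.

    Solves the unique proper rigid 2D motion mapping the slide's ink-mark
    pair onto the section-plane traces of the specimen's ink lines, applies
    it to the outline, and lifts the result to 3D. The registration
    residual is the RMS perpendicular distance of the mapped mark endpoints
    to their trace lines.
    """
    origin, normal = slab.section_plane()
    traces = {}
    for lab in INK_LABELS:
        if lab not in specimen.ink_lines:
            raise MisalignmentError(f"specimen carries no {lab} ink line")
        traces[lab] = ink_trace(specimen.ink_lines[lab], origin, normal)

    slide_dir = {
        lab: _unit(contour.ink_marks[lab][1] - contour.ink_marks[lab][0])
        for lab in INK_LABELS
    }
    slide_mid = {lab: contour.ink_marks[lab].mean(axis=0) for lab in INK_LABELS}

    handed_slide = np.sign(
        _cross2(slide_dir["dorsal_line"], slide_dir["perpendicular_line"])
    )
    handed_trace = np.sign(
        _cross2(traces["dorsal_line"][1], traces["perpendicular_line"][1])
    )
    if handed_slide != handed_trace:
        raise FlippedSlideError(
            f"slide for slab {contour.slab_label!r} is mirror-mounted: matching "
            "its ink marks to the specimen requires a reflection"
        )

    td, dd = traces["dorsal_line"]
    theta = np.arctan2(dd[1], dd[0]) - np.arctan2(
        slide_dir["dorsal_line"][1], slide_dir["dorsal_line"][0]
    )
    rot = geometry.rigid_2d(theta, [0.0, 0.0])
    x_slide = _line_intersection(
        slide_mid["dorsal_line"],
        slide_dir["dorsal_line"],
        slide_mid["perpendicular_line"],
        slide_dir["perpendicular_line"],
    )
    x_trace = _line_intersection(
        td, dd, traces["perpendicular_line"][0], traces["perpendicular_line"][1]
    )
    t = x_trace - rot(x_slide[None])[0]
    motion = geometry.rigid_2d(theta, t)

    # residual: mapped mark endpoints vs their trace lines
    sq = []
    for lab in INK_LABELS:
        p2, d2 = traces[lab]
        n2 = np.array([-d2[1], d2[0]])
        for end in motion(contour.ink_marks[lab]):
            sq.append(float((end - p2) @ n2) ** 2)
    residual = float(np.sqrt(np.mean(sq)))
    if residual > residual_tol_mm:
        raise MisalignmentError(
            f"registration residual {residual:.3f} mm for slab "
            f"{contour.slab_label!r} exceeds tolerance {residual_tol_mm:g} mm"
        )

    poly2 = motion(contour.vertices)
    if geometry.polygon_area(poly2) < 0:
        poly2 = poly2[::-1]
    _check_containment(poly2, specimen, origin, normal, containment_tol_mm, contour)
    verts3 = geometry.lift_from_plane(poly2, origin, normal)
    log.info(
        "registered slab %s contour %d: rotation %.2f deg, residual %.4f mm",
        contour.slab_label,
        contour.index,
        np.degrees(theta),
        residual,
    )
    return PlacedContour(
        slab_label=contour.slab_label,
        vertices=verts3,
        plane_origin=origin,
        plane_normal=normal,
        index=contour.index,
        residual_mm=residual,
    )


def _check_containment(poly2, specimen, origin, normal, tol_mm, contour):
    """Warn if the placed contour pokes out of the specimen cross-section."""
    from .tumor_reconstruction import planar_section_polygon

    section = planar_section_polygon(specimen.mesh.as_trimesh(), origin, normal)
    if section is None or section.is_empty:
        warnings.warn(
            f"section plane of slab {contour.slab_label!r} misses the specimen",
            stacklevel=3,
        )
        return
    outline = sg.Polygon(poly2)
    if not outline.within(section.buffer(tol_mm)):
        excess = outline.difference(section).area
        warnings.warn(
            f"contour of slab {contour.slab_label!r} extends outside the specimen "
            f"cross-section by more than {tol_mm:g} mm (excess area "
            f"{excess:.2f} mm^2)",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# contour-JSON
# ---------------------------------------------------------------------------

def contours_from_records(records) -> list[TumorContour]:
    out = []
    for i, rec in enumerate(records):
        if not isinstance(rec, dict):
            raise FormatError(f"contour record {i} is not an object")
        try:
            slab = rec["slab"]
            polygon = rec["polygon"]
            marks = rec["ink_marks"]
        except KeyError as exc:
            raise FormatError(f"contour record {i} lacks key {exc}") from exc
        out.append(
            TumorContour(
                slab_label=str(slab),
                vertices=np.asarray(polygon, dtype=float),
                ink_marks={k: np.asarray(v, dtype=float) for k, v in marks.items()},
                index=int(rec.get("index", 0)),
            )
        )
    return out


def load_contours(path) -> list[TumorContour]:
    """Read a contour-JSON file: a list of
    ``{"slab", "polygon": [[x,y],...], "ink_marks": {"dorsal_line": [[x,y],[x,y]],
    "perpendicular_line": ...}, "index"}`` records (mm, slide coordinates).
    """
    try:
        with open(path) as fh:
            data = json.load(fh)
    except FileNotFoundError:
        raise FormatError(f"contour file not found: {path!r}") from None
    except json.JSONDecodeError as exc:
        raise FormatError(f"contour file {path!r} is not valid JSON: {exc}") from exc
    if not isinstance(data, list):
        raise FormatError(f"contour file {path!r} must contain a JSON list")
    return contours_from_records(data)


def dump_contours(contours: list[TumorContour], path) -> None:
    records = [
        {
            "slab": c.slab_label,
            "polygon": c.vertices.tolist(),
            "ink_marks": {k: v.tolist() for k, v in c.ink_marks.items()},
            "index": c.index,
        }
        for c in contours
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1, sort_keys=True)
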