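"""Surface-mesh I/O, validation, watertight repair, simplification, and
measurement.

The specimen shell arrives from a structured-light table scanner as an STL
surface in millimetres. Scanner blind spots leave a few small holes (typical
scans show two to three, 1–5 mm across); these are closed with near-planar
patches, mirroring what scanner software does when it builds a "watertight"
model — the holes become smooth, solid planes, which loses fine detail but
yields a closed solid. The mesh is then decimated to a fixed facet budget
(20,000 by default) so downstream CAD-style operations stay tractable.

STL files carry no units; this package fixes millimetres by convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from . import geometry
from .decimate import quadric_decimate
from .errors import FormatError, ParameterError, PreconditionError, RepairError

log = logging.getLogger(__name__)

DEFAULT_FACET_BUDGET = 20_000
WELD_TOL_MM = 1e-6


@dataclass
class SurfaceMesh:
    """A triangulated surface in specimen coordinates (mm).

    Used both for the scanned specimen shell and for the reconstructed
    tumor body. ``provenance`` is a free-text tag ("scan", "tumor",
    "phantom", ...).
    """

    vertices: np.ndarray
    faces: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, provenance: str = "") -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces), provenance)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def is_watertight(self) -> bool:
        return len(boundary_edges(self)) == 0 and self.as_trimesh().is_watertight

    @property
    def extents(self) -> np.ndarray:
        """(min, max) corner pair, shape (2, 3)."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "SurfaceMesh":
        """Rigidly transformed copy: x -> R x + t."""
        return replace(self, vertices=self.vertices @ np.asarray(R).T + np.asarray(t))


@dataclass
class BoundaryLoop:
    """An open-edge cycle of a non-watertight mesh (a scan hole)."""

    vertex_indices: np.ndarray
    diameter_mm: float = field(default=0.0)

    def __len__(self):
        return len(self.vertex_indices)


def read_surface(path, provenance: str = "scan") -> SurfaceMesh:
    """Read an ASCII or binary STL file (millimetres).

    Duplicate vertices are welded (tolerance 1e-6 mm) and zero-area faces
    dropped with a warning.
    """
    try:
        tm = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - re-raise as format error naming path
        raise FormatError(f"cannot read STL file {path!r}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise FormatError(f"STL file {path!r} contains no triangles")
    mesh = validate(SurfaceMesh.from_trimesh(tm, provenance))
    log.info(
        "read %s: %d vertices, %d faces (units: mm)", path, mesh.n_vertices, mesh.n_faces
    )
    return mesh


def write_surface(mesh: SurfaceMesh, path) -> None:
    """Write binary STL."""
    data = mesh.as_trimesh().export(file_type="stl")
    with open(path, "wb") as fh:
        fh.write(data)
    log.info("wrote %s: %d faces (units: mm)", path, mesh.n_faces)


def validate(mesh: SurfaceMesh) -> SurfaceMesh:
    """Weld duplicate vertices, drop degenerate faces, check indices."""
    v, f = mesh.vertices, mesh.faces
    if len(f) and (f.min() < 0 or f.max() >= len(v)):
        raise FormatError("face index out of range")
    # weld: snap to a 1e-6 mm grid and merge
    key = np.round(v / WELD_TOL_MM).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    v2 = v[first]
    f2 = inverse[f]
    # drop degenerate faces (repeated vertex or zero area)
    tri = v2[f2]
    area2 = np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    distinct = (
        (f2[:, 0] != f2[:, 1]) & (f2[:, 1] != f2[:, 2]) & (f2[:, 0] != f2[:, 2])
    )
    good = distinct & (area2 > 1e-14)
    dropped = int(len(f2) - good.sum())
    if dropped:
        log.warning("dropped %d degenerate faces", dropped)
    return SurfaceMesh(v2, f2[good], mesh.provenance)


def boundary_edges(mesh: SurfaceMesh) -> np.ndarray:
    """Directed edges that belong to exactly one face, shape (k, 2)."""
    f = mesh.faces
    e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    es = np.sort(e, axis=1)
    _, inv, counts = np.unique(es, axis=0, return_inverse=True, return_counts=True)
    return e[counts[inv] == 1]


def boundary_loops(mesh: SurfaceMesh) -> list[BoundaryLoop]:
    """Enumerate open-edge cycles, each a hole in the scan."""
    be = boundary_edges(mesh)
    succ: dict[int, int] = {}
    for a, b in be:
        a, b = int(a), int(b)
        if a in succ:
            raise RepairError(
                f"non-manifold boundary at vertex {a}: cannot chain boundary loops"
            )
        succ[a] = b
    loops = []
    seen: set[int] = set()
    for start in sorted(succ):
        if start in seen:
            continue
        cycle = [start]
        seen.add(start)
        cur = succ[start]
        while cur != start:
            if cur in seen or cur not in succ:
                raise RepairError(f"open boundary chain at vertex {cur}")
            cycle.append(cur)
            seen.add(cur)
            cur = succ[cur]
        pts = mesh.vertices[cycle]
        diam = 0.0
        if len(pts) > 1:
            c = pts.mean(axis=0)
            diam = 2.0 * float(np.linalg.norm(pts - c, axis=1).max())
        loops.append(BoundaryLoop(np.asarray(cycle, dtype=np.int64), diam))
    return loops


def make_watertight(mesh: SurfaceMesh) -> SurfaceMesh:
    """Close every boundary loop with a near-planar patch.

    Each hole's rim is projected onto its best-fit plane and ear-clipped,
    reproducing the "smooth, solid plane" repair that scanner software
    applies; curvature across the hole is deliberately not reconstructed.
    Idempotent: a watertight mesh is returned unchanged.
    """
    mesh = validate(mesh)
    loops = boundary_loops(mesh)
    if not loops:
        log.info("make_watertight: already watertight, 0 holes filled")
        return mesh
    new_faces = [mesh.faces]
    for loop in loops:
        pts = mesh.vertices[loop.vertex_indices]
        origin, normal = geometry.fit_plane(pts)
        flat = geometry.project_to_plane(pts, origin, normal)
        if not geometry.polygon_is_simple(flat):
            raise RepairError(
                f"boundary loop of {len(loop)} vertices self-intersects when "
                "projected to its best-fit plane"
            )
        tris = geometry.ear_clip(flat)
        # the boundary cycle follows face winding; the patch must be wound
        # the opposite way to keep edge orientation consistent
        patch = loop.vertex_indices[tris][:, ::-1]
        new_faces.append(patch)
    out = SurfaceMesh(mesh.vertices.copy(), np.vstack(new_faces), mesh.provenance)
    tm = out.as_trimesh()
    trimesh.repair.fix_normals(tm)
    if tm.volume < 0:
        tm.invert()
    out = SurfaceMesh.from_trimesh(tm, mesh.provenance)
    if not out.is_watertight:
        raise RepairError("hole filling did not produce a watertight mesh")
    log.info(
        "make_watertight: filled %d holes (diameters %s mm)",
        len(loops),
        ", ".join(f"{lo.diameter_mm:.2f}" for lo in loops),
    )
    return out


def simplify(
    mesh: SurfaceMesh,
    facet_budget: int = DEFAULT_FACET_BUDGET,
    log_hausdorff: bool = False,
) -> SurfaceMesh:
    """Decimate to at most ``facet_budget`` faces by quadric edge collapse.

    The default budget of 20,000 facets keeps the shell fine enough for
    modeling the tumor while remaining workable in CAD software. A mesh
    already under budget is returned unchanged. Watertightness is
    preserved.
    """
    if facet_budget < 4:
        raise ParameterError(f"facet_budget must be >= 4, got {facet_budget}")
    if mesh.n_faces <= facet_budget:
        return mesh
    if not mesh.is_watertight:
        raise PreconditionError("simplify requires a watertight mesh; repair first")
    v, f = quadric_decimate(mesh.vertices, mesh.faces, facet_budget)
    out = SurfaceMesh(v, f, mesh.provenance)
    if log_hausdorff:
        d = geometry.points_to_triangles_distance(
            out.vertices, mesh.vertices[mesh.faces]
        )
        log.info(
            "simplify: %d -> %d faces, one-sided Hausdorff %.4f mm",
            mesh.n_faces,
            out.n_faces,
            float(d.max()),
        )
    else:
        log.info("simplify: %d -> %d faces", mesh.n_faces, out.n_faces)
    return out


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume (mm^3) by the divergence theorem; requires watertight."""
    if not mesh.is_watertight:
        raise PreconditionError("mesh_volume requires a watertight mesh")
    vol = float(mesh.as_trimesh().volume)
    if vol < 0:
        raise PreconditionError("mesh is inward-oriented (negative signed volume)")
    return vol
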