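"""Shared low-level geometry: plane bases, polygon triangulation, rigid fits,
and point-to-triangle distance queries.

All lengths are millimetres. Functions here are deterministic: identical
inputs produce identical outputs, including tie-breaks.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError, RepairError

__all__ = [
    "plane_basis",
    "project_to_plane",
    "lift_from_plane",
    "polygon_area",
    "polygon_perimeter",
    "polygon_is_simple",
    "ear_clip",
    "fit_plane",
    "kabsch",
    "rigid_2d",
    "points_to_triangles_distance",
    "mesh_min_distance",
]

_Z = np.array([0.0, 0.0, 1.0])
_X = np.array([1.0, 0.0, 0.0])


def plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane orthonormal basis (u, v) with u x v = normal.

    For a non-vertical normal, v is the steepest-ascent ("up") direction so
    that +v in plane coordinates points toward +z; for a +/-z normal, the
    basis is (x, +/-y).
    """
    w = np.asarray(normal, dtype=float)
    w = w / np.linalg.norm(w)
    if abs(w[2]) > 0.999999:
        u = _X.copy()
        v = np.cross(w, u)
    else:
        u = np.cross(_Z, w)
        u /= np.linalg.norm(u)
        v = np.cross(w, u)
    return u, v


def project_to_plane(points: np.ndarray, origin, normal) -> np.ndarray:
    """Project 3D points into 2D plane coordinates (u, v) about *origin*."""
    u, v = plane_basis(normal)
    d = np.asarray(points, dtype=float) - np.asarray(origin, dtype=float)
    return np.column_stack([d @ u, d @ v])


def lift_from_plane(points2: np.ndarray, origin, normal) -> np.ndarray:
    """Inverse of :func:`project_to_plane`: lift (u, v) coordinates to 3D."""
    u, v = plane_basis(normal)
    p = np.asarray(points2, dtype=float)
    return np.asarray(origin, dtype=float) + np.outer(p[:, 0], u) + np.outer(p[:, 1], v)


def polygon_area(poly: np.ndarray) -> float:
    """Signed shoelace area of a closed 2D polygon (positive = CCW)."""
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_perimeter(poly: np.ndarray) -> float:
    p = np.asarray(poly, dtype=float)
    return float(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1).sum())


def polygon_is_simple(poly: np.ndarray) -> bool:
    """True if the closed polygon does not self-intersect."""
    import shapely.geometry as sg

    ring = sg.LinearRing(np.asarray(poly, dtype=float))
    return bool(ring.is_simple and ring.is_valid)


def ear_clip(poly: np.ndarray) -> np.ndarray:
    """Triangulate a simple 2D polygon by ear clipping.

    Returns (m, 3) index triples into *poly*, wound the same way as the
    input polygon. Deterministic: the lowest-index valid ear is clipped
    first. Intended for the small boundary loops and section outlines this
    package handles, not for huge polygons.
    """
    pts = np.asarray(poly, dtype=float)
    n = len(pts)
    if n < 3:
        raise GeometryError(f"cannot triangulate a polygon with {n} vertices")
    if n == 3:
        return np.array([[0, 1, 2]])
    ccw = polygon_area(pts) > 0
    idx = list(range(n))
    tris: list[list[int]] = []

    def cross(o, a, b):
        return (pts[a][0] - pts[o][0]) * (pts[b][1] - pts[o][1]) - (
            pts[a][1] - pts[o][1]
        ) * (pts[b][0] - pts[o][0])

    def is_ear(i):
        m = len(idx)
        o, a, b = idx[(i - 1) % m], idx[i], idx[(i + 1) % m]
        c = cross(o, a, b)
        if (c <= 0) if ccw else (c >= 0):
            return False  # reflex or degenerate corner
        # no other active vertex strictly inside the candidate ear
        tri = pts[[o, a, b]]
        v0, v1 = tri[1] - tri[0], tri[2] - tri[0]
        den = v0[0] * v1[1] - v0[1] * v1[0]
        for j in idx:
            if j in (o, a, b):
                continue
            d = pts[j] - tri[0]
            s = (d[0] * v1[1] - d[1] * v1[0]) / den
            t = (v0[0] * d[1] - v0[1] * d[0]) / den
            if s > 1e-12 and t > 1e-12 and s + t < 1 - 1e-12:
                return False
        return True

    guard = 0
    while len(idx) > 3:
        guard += 1
        if guard > 2 * n * n:
            raise RepairError("ear clipping failed: polygon is likely self-intersecting")
        clipped = False
        for i in range(len(idx)):
            if is_ear(i):
                m = len(idx)
                tris.append([idx[(i - 1) % m], idx[i], idx[(i + 1) % m]])
                del idx[i]
                clipped = True
                break
        if not clipped:
            raise RepairError("ear clipping failed: no ear found (self-intersecting loop?)")
    tris.append(list(idx))
    return np.asarray(tris, dtype=int)


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through 3D points: returns (centroid, unit normal).

    The normal's sign is fixed deterministically (largest-magnitude component
    positive).
    """
    p = np.asarray(points, dtype=float)
    c = p.mean(axis=0)
    _, _, vt = np.linalg.svd(p - c, full_matrices=False)
    n = vt[-1]
    k = int(np.argmax(np.abs(n)))
    if n[k] < 0:
        n = -n
    return c, n


def kabsch(source: np.ndarray, target: np.ndarray, allow_reflection: bool = False):
    """Least-squares rotation R with R @ source[i] ~ target[i] (both centered).

    Returns (R, required_reflection). When the unconstrained orthogonal
    Procrustes optimum is a reflection, ``required_reflection`` is True and R
    is the best *proper* rotation.
    """
    P = np.asarray(source, dtype=float)
    T = np.asarray(target, dtype=float)
    H = T.T @ P
    U, _, Vt = np.linalg.svd(H)
    d = np.linalg.det(U @ Vt)
    D = np.diag([1.0, 1.0, np.sign(d)])
    R = U @ D @ Vt
    return R, bool(d < 0)


def rigid_2d(theta: float, t: np.ndarray):
    """2D rotation-by-theta-then-translate as a function on (n, 2) arrays."""
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    t = np.asarray(t, dtype=float)

    def apply(pts):
        return np.asarray(pts, dtype=float) @ R.T + t

    apply.R = R
    apply.t = t
    return apply


# ---------------------------------------------------------------------------
# point / triangle distance
# ---------------------------------------------------------------------------

def _point_triangle_distance(points, tri_a, tri_b, tri_c):
    """Vectorized exact distance from points[i] to triangle i (Ericson's method)."""
    p = points
    a, b, c = tri_a, tri_b, tri_c
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex a
    closest[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)  # vertex b
    closest[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)  # vertex c
    closest[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    if m.any():
        v = d1[m] / (d1[m] - d3[m])
        closest[m] = a[m] + v[:, None] * ab[m]
        done |= m
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    if m.any():
        w = d2[m] / (d2[m] - d6[m])
        closest[m] = a[m] + w[:, None] * ac[m]
        done |= m
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    if m.any():
        w = (d4[m] - d3[m]) / ((d4[m] - d3[m]) + (d5[m] - d6[m]))
        closest[m] = b[m] + w[:, None] * (c[m] - b[m])
        done |= m
    m = ~done  # face interior
    if m.any():
        denom = 1.0 / (va[m] + vb[m] + vc[m])
        v = (vb[m] * denom)[:, None]
        w = (vc[m] * denom)[:, None]
        closest[m] = a[m] + v * ab[m] + w * ac[m]
    return np.linalg.norm(p - closest, axis=1), closest


def points_to_triangles_distance(points, triangles, k: int = 32, return_closest: bool = False):
    """Exact minimum distance from each point to a triangle soup.

    Candidate triangles are pre-filtered with a KD-tree on triangle
    centroids (the *k* nearest per point, widened by a triangle-radius
    bound so the exact nearest triangle is never pruned). Returns an array
    of per-point distances, or ``(distances, triangle_index, closest_point)``
    when ``return_closest`` is set.
    """
    pts = np.asarray(points, dtype=float)
    tris = np.asarray(triangles, dtype=float)
    nt = len(tris)
    if nt == 0:
        out = np.full(len(pts), np.inf)
        if return_closest:
            return out, np.full(len(pts), -1), np.full((len(pts), 3), np.nan)
        return out
    centroids = tris.mean(axis=1)
    # circumradius bound: max centroid-to-vertex distance over the soup
    rmax = float(np.linalg.norm(tris - centroids[:, None, :], axis=2).max())
    tree = cKDTree(centroids)
    k = min(k, nt)
    dc, idx = tree.query(pts, k=k)
    dc = np.atleast_2d(dc.T).T
    idx = np.atleast_2d(idx.T).T
    # exact distances to the k candidates
    n, kk = idx.shape
    flat_idx = idx.ravel()
    rep_pts = np.repeat(pts, kk, axis=0)
    d, cp = _point_triangle_distance(
        rep_pts, tris[flat_idx, 0], tris[flat_idx, 1], tris[flat_idx, 2]
    )
    d = d.reshape(n, kk)
    kbest = d.argmin(axis=1)
    rows = np.arange(n)
    best = d[rows, kbest]
    best_tri = idx[rows, kbest]
    best_cp = cp.reshape(n, kk, 3)[rows, kbest]
    # a triangle outside the candidate set has centroid distance > dc[:, -1];
    # its surface can still be closer by at most rmax. For points whose
    # current best cannot rule that out, evaluate exactly every triangle
    # whose lower bound (centroid distance minus its own circumradius)
    # undercuts the point's best — an exact pruned fallback, so the result
    # is correct regardless of mesh shape.
    unsafe = np.nonzero(best > dc[:, -1] - rmax)[0]
    if len(unsafe):
        radii = np.linalg.norm(tris - centroids[:, None, :], axis=2).max(axis=1)
        block = max(1, int(2e7 // max(nt, 1)))
        for s in range(0, len(unsafe), block):
            rows_u = unsafe[s : s + block]
            p = pts[rows_u]
            d2 = (
                (p**2).sum(axis=1)[:, None]
                + (centroids**2).sum(axis=1)[None, :]
                - 2.0 * p @ centroids.T
            )
            np.maximum(d2, 0.0, out=d2)
            lb = np.sqrt(d2) - radii[None, :]
            ii, jj = np.nonzero(lb < best[rows_u][:, None] - 1e-12)
            if not len(ii):
                continue
            di, cpi = _point_triangle_distance(
                p[ii], tris[jj, 0], tris[jj, 1], tris[jj, 2]
            )
            order = np.lexsort((di, ii))
            ii, jj, di, cpi = ii[order], jj[order], di[order], cpi[order]
            first = np.unique(ii, return_index=True)[1]
            rows_f = rows_u[ii[first]]
            upd = di[first] < best[rows_f]
            rs = rows_f[upd]
            best[rs] = di[first][upd]
            best_tri[rs] = jj[first][upd]
            best_cp[rs] = cpi[first][upd]
    if return_closest:
        return best, best_tri, best_cp
    return best


def mesh_min_distance(mesh_a, mesh_b) -> float:
    """Minimum distance between two triangle meshes.

    Computed symmetrically as the minimum over (vertices of A -> triangles
    of B) and (vertices of B -> triangles of A); for disjoint, well-shaped
    surface meshes this attains the exact surface-to-surface minimum (the
    closest pair involves a vertex of one of the meshes up to mesh
    resolution).
    """
    da = points_to_triangles_distance(mesh_a.vertices, mesh_b.triangles)
    db = points_to_triangles_distance(mesh_b.vertices, mesh_a.triangles)
    return float(min(da.min(), db.min()))
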