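"""Independent oracles used by the test suite.

These deliberately avoid the package's spatial-index distance path and its
divergence-theorem volume: distances are evaluated by exact brute force
over point/triangle pairs (with a provably exact lower-bound prune for
speed), and volumes by column integration on a regular grid.
"""

from __future__ import annotations

import numpy as np

from t3d.geometry import _point_triangle_distance


def brute_min_distance(points: np.ndarray, triangles: np.ndarray, chunk: int = 20000) -> float:
    """Exact minimum distance from a point set to a triangle soup.

    Every pair whose exact lower bound (centroid distance minus the
    triangle's circumradius) undercuts the running minimum is evaluated
    with the exact point-triangle distance, so the result equals the full
    brute-force minimum.
    """
    pts = np.asarray(points, dtype=float)
    tris = np.asarray(triangles, dtype=float)
    cent = tris.mean(axis=1)
    rad = np.linalg.norm(tris - cent[:, None, :], axis=2).max(axis=1)
    best = np.inf
    for s in range(0, len(pts), chunk):
        p = pts[s : s + chunk]
        d2 = (p**2).sum(1)[:, None] + (cent**2).sum(1)[None, :] - 2.0 * p @ cent.T
        np.maximum(d2, 0.0, out=d2)
        lb = np.sqrt(d2) - rad[None, :]
        lbmin = lb.min(axis=1)
        rows = np.nonzero(lbmin < best)[0]
        if len(rows):
            j0 = lb[rows].argmin(axis=1)
            d, _ = _point_triangle_distance(
                p[rows], tris[j0, 0], tris[j0, 1], tris[j0, 2]
            )
            best = min(best, float(d.min()))
        ii, jj = np.nonzero(lb < best)
        if len(ii):
            d, _ = _point_triangle_distance(p[ii], tris[jj, 0], tris[jj, 1], tris[jj, 2])
            best = min(best, float(d.min()))
    return best


def column_volume(mesh, pitch: float = 0.1) -> float:
    """Volume of a watertight mesh by z-column integration on an (x, y) grid.

    For every grid column, all triangle crossings are collected, sorted,
    and paired; the enclosed length per column times the cell area sums to
    the volume. Independent of the signed-tetrahedron formula.
    """
    V = np.asarray(mesh.vertices, dtype=float)
    F = np.asarray(mesh.faces)
    tri = V[F]
    lo = V.min(axis=0)[:2] - pitch
    hi = V.max(axis=0)[:2] + pitch
    nx = int(np.ceil((hi[0] - lo[0]) / pitch))
    ny = int(np.ceil((hi[1] - lo[1]) / pitch))
    xs = lo[0] + (np.arange(nx) + 0.5) * pitch
    ys = lo[1] + (np.arange(ny) + 0.5) * pitch
    columns: dict[tuple[int, int], list[float]] = {}
    for a, b, c in tri:
        xmin, ymin = np.minimum(np.minimum(a, b), c)[:2]
        xmax, ymax = np.maximum(np.maximum(a, b), c)[:2]
        i0 = max(0, int(np.ceil((xmin - lo[0]) / pitch - 0.5)))
        i1 = min(nx - 1, int(np.floor((xmax - lo[0]) / pitch - 0.5)))
        j0 = max(0, int(np.ceil((ymin - lo[1]) / pitch - 0.5)))
        j1 = min(ny - 1, int(np.floor((ymax - lo[1]) / pitch - 0.5)))
        if i1 < i0 or j1 < j0:
            continue
        gx, gy = np.meshgrid(xs[i0 : i1 + 1], ys[j0 : j1 + 1], indexing="ij")
        p = np.column_stack([gx.ravel(), gy.ravel()])
        v0 = b[:2] - a[:2]
        v1 = c[:2] - a[:2]
        den = v0[0] * v1[1] - v0[1] * v1[0]
        if abs(den) < 1e-14:
            continue
        d = p - a[:2]
        s = (d[:, 0] * v1[1] - d[:, 1] * v1[0]) / den
        t = (v0[0] * d[:, 1] - v0[1] * d[:, 0]) / den
        inside = (s >= 0) & (t >= 0) & (s + t <= 1)
        if not inside.any():
            continue
        z = a[2] + s[inside] * (b[2] - a[2]) + t[inside] * (c[2] - a[2])
        ii = (i0 + np.nonzero(inside)[0] // (j1 - j0 + 1)).astype(int)
        jj = (j0 + np.nonzero(inside)[0] % (j1 - j0 + 1)).astype(int)
        for i, j, zz in zip(ii, jj, z):
            columns.setdefault((int(i), int(j)), []).append(float(zz))
    vol = 0.0
    for zs in columns.values():
        if len(zs) < 2:
            continue
        zs = sorted(zs)
        for k in range(0, len(zs) - 1, 2):
            vol += zs[k + 1] - zs[k]
    return vol * pitch * pitch
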