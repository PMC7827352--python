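"""Quadric error-metric edge-collapse decimation.

Garland–Heckbert style simplification: every vertex accumulates the sum of
squared-distance quadrics of its incident face planes; edges are collapsed
in order of increasing quadric error until the face budget is reached. The
collapse target position is chosen among the two endpoints and the midpoint
(the minimizer of the pair quadric among those candidates), which avoids
ill-conditioned 4x4 solves while staying within a small factor of the
optimal-placement error.

Determinism: the priority queue orders by (cost, vertex pair, stamp), so
ties are broken by the lowest edge index. Collapses that would break the
manifold (link condition), invert a face normal, or create a degenerate
face are skipped.

Intended for closed, manifold meshes (the pipeline repairs scans to
watertight before simplifying); watertightness is preserved because each
collapse removes exactly the two faces incident to the edge.
"""

from __future__ import annotations

import heapq

import numpy as np

__all__ = ["quadric_decimate"]


def _face_quadrics(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Fundamental quadric K = p p^T of each face plane p=(a,b,c,d), |n|=1."""
    tri = vertices[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    n = n / norm
    d = -np.einsum("ij,ij->i", n, tri[:, 0])
    p = np.column_stack([n, d])  # (m, 4)
    return np.einsum("mi,mj->mij", p, p)


def _pair_cost(Q: np.ndarray, va: np.ndarray, vb: np.ndarray):
    """Best of {a, b, midpoint} under the pair quadric; returns (cost, pos)."""
    cand = np.empty((3, 4))
    cand[0, :3] = va
    cand[1, :3] = vb
    cand[2, :3] = 0.5 * (va + vb)
    cand[:, 3] = 1.0
    costs = np.einsum("ci,ij,cj->c", cand, Q, cand)
    k = int(np.argmin(costs))
    return max(float(costs[k]), 0.0), cand[k, :3].copy()


def quadric_decimate(
    vertices: np.ndarray, faces: np.ndarray, target_faces: int
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse edges of a closed manifold mesh until ``target_faces`` remain.

    Returns (vertices, faces) of the simplified mesh with unused vertices
    dropped. If no further collapse is topologically valid the current mesh
    is returned (face count may then exceed the target).
    """
    V = np.array(vertices, dtype=float)
    F = np.array(faces, dtype=np.int64)
    nf = len(F)
    if nf <= target_faces:
        return V, F

    Q = _face_quadrics(V, F).copy()
    VQ = np.zeros((len(V), 4, 4))
    for c in range(3):
        np.add.at(VQ, F[:, c], Q)

    face_alive = np.ones(nf, dtype=bool)
    vert_alive = np.ones(len(V), dtype=bool)
    vfaces: list[set[int]] = [set() for _ in range(len(V))]
    for fi, (a, b, c) in enumerate(F):
        vfaces[a].add(fi)
        vfaces[b].add(fi)
        vfaces[c].add(fi)

    # unique undirected edges
    e = np.sort(
        np.vstack([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]]), axis=1
    )
    edges = np.unique(e, axis=0)

    stamp: dict[tuple[int, int], int] = {}
    heap: list[tuple[float, int, int, int]] = []
    for a, b in edges:
        a, b = int(a), int(b)
        cost, _ = _pair_cost(VQ[a] + VQ[b], V[a], V[b])
        stamp[(a, b)] = 0
        heap.append((cost, a, b, 0))
    heapq.heapify(heap)

    def push_edge(a: int, b: int):
        if a > b:
            a, b = b, a
        s = stamp.get((a, b), -1) + 1
        stamp[(a, b)] = s
        cost, _ = _pair_cost(VQ[a] + VQ[b], V[a], V[b])
        heapq.heappush(heap, (cost, a, b, s))

    def neighbors(u: int) -> set[int]:
        out: set[int] = set()
        for fi in vfaces[u]:
            out.update(int(x) for x in F[fi])
        out.discard(u)
        return out

    live = nf
    while live > target_faces and heap:
        cost, u, v, s = heapq.heappop(heap)
        if stamp.get((u, v)) != s or not (vert_alive[u] and vert_alive[v]):
            continue
        shared = vfaces[u] & vfaces[v]
        if len(shared) != 2:
            continue  # edge no longer manifold-interior
        # link condition: common one-ring neighbours must be exactly the
        # opposite vertices of the two shared faces
        nu, nv = neighbors(u), neighbors(v)
        opposite = set()
        for fi in shared:
            for x in F[fi]:
                x = int(x)
                if x != u and x != v:
                    opposite.add(x)
        if nu & nv != opposite or len(opposite) != 2:
            continue
        _, pos = _pair_cost(VQ[u] + VQ[v], V[u], V[v])
        # normal flip / degeneracy check on surviving faces
        affected = (vfaces[u] | vfaces[v]) - shared
        ok = True
        for fi in affected:
            a, b, c = (int(x) for x in F[fi])
            pa, pb, pc = V[a], V[b], V[c]
            old_n = np.cross(pb - pa, pc - pa)
            qa = pos if a in (u, v) else pa
            qb = pos if b in (u, v) else pb
            qc = pos if c in (u, v) else pc
            new_n = np.cross(qb - qa, qc - qa)
            nn = np.linalg.norm(new_n)
            if nn < 1e-14 or np.dot(old_n, new_n) <= 1e-10 * np.linalg.norm(old_n) * nn:
                ok = False
                break
        if not ok:
            continue
        # commit
        V[u] = pos
        VQ[u] = VQ[u] + VQ[v]
        vert_alive[v] = False
        for fi in shared:
            face_alive[fi] = False
            for x in F[fi]:
                vfaces[int(x)].discard(fi)
        live -= len(shared)
        moved = vfaces[v] - shared
        for fi in moved:
            f = F[fi]
            F[fi] = np.where(f == v, u, f)
        vfaces[u] |= moved
        vfaces[v] = set()
        for w in sorted(neighbors(u)):
            push_edge(u, w)

    keep = face_alive
    newF = F[keep]
    used = np.unique(newF)
    remap = np.full(len(V), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return V[used], remap[newF]
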