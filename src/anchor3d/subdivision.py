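"""Catmull-Clark subdivision for closed all-quad meshes.

The block model is angular; its displayed surface is the Catmull-Clark
subdivision of the control mesh.  For a closed quad mesh one level produces
V' = V + E + F vertices, F' = 4F faces and E' = 2E + 4F edges with the
classic weights: face point = face centroid; edge point = mean of the
edge's two endpoints and its two adjacent face points; updated vertex =
(Q + 2R + (n-3)S)/n with Q the mean of adjacent face points, R the mean of
adjacent edge midpoints, S the old position, n the valence.

Because every rule is a fixed convex combination of control positions, a
subdivision level is a sparse linear operator on the vertex array.  The
operator depends only on topology, so repeated smoothing of a deforming
mesh (constant connectivity, moving vertices) reuses a cached matrix.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .errors import BuildError
from .meshbuild import QuadMesh, validate_mesh

__all__ = ["catmull_clark", "limit_check", "SubdivisionOperator"]


def _one_level(faces: np.ndarray, n_vertices: int):
    """Sparse matrix and new face array for one Catmull-Clark level."""
    F = len(faces)
    edge_index: dict = {}
    face_edges = np.empty((F, 4), dtype=np.int64)
    for fi, face in enumerate(faces):
        for k in range(4):
            a, b = int(face[k]), int(face[(k + 1) % 4])
            key = (a, b) if a < b else (b, a)
            if key not in edge_index:
                edge_index[key] = len(edge_index)
            face_edges[fi, k] = edge_index[key]
    E = len(edge_index)
    edge_verts = np.empty((E, 2), dtype=np.int64)
    for (a, b), ei in edge_index.items():
        edge_verts[ei] = (a, b)

    # adjacency: faces per edge, faces/edges per vertex
    edge_faces = [[] for _ in range(E)]
    vert_faces = [[] for _ in range(n_vertices)]
    vert_edges = [set() for _ in range(n_vertices)]
    for fi, face in enumerate(faces):
        for k in range(4):
            edge_faces[face_edges[fi, k]].append(fi)
        for v in face:
            vert_faces[int(v)].append(fi)
    for ei, (a, b) in enumerate(edge_verts):
        vert_edges[a].add(ei)
        vert_edges[b].add(ei)

    if any(len(fs) != 2 for fs in edge_faces):
        raise BuildError("Catmull-Clark requires a closed mesh (every edge in 2 faces)")

    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    # new vertex ordering: updated old vertices, then face points, then edge points
    fp_base = n_vertices
    ep_base = n_vertices + F

    # face points: centroid
    for fi, face in enumerate(faces):
        for v in face:
            add(fp_base + fi, int(v), 0.25)

    # edge points: mean of endpoints and the two adjacent face centroids
    for ei, (a, b) in enumerate(edge_verts):
        add(ep_base + ei, a, 0.25)
        add(ep_base + ei, b, 0.25)
        for fi in edge_faces[ei]:
            for v in faces[fi]:
                add(ep_base + ei, int(v), 0.25 * 0.25)

    # updated old vertices: (Q + 2R + (n-3)S)/n
    for v in range(n_vertices):
        n = len(vert_edges[v])
        if n == 0:
            add(v, v, 1.0)
            continue
        if len(vert_faces[v]) != n:
            raise BuildError("non-manifold vertex encountered in subdivision")
        for fi in vert_faces[v]:
            for w in faces[fi]:
                add(v, int(w), 0.25 / n / n)  # Q/n
        for ei in vert_edges[v]:
            a, b = edge_verts[ei]
            add(v, int(a), 1.0 / n / n)  # 2R/n, midpoint = (a+b)/2
            add(v, int(b), 1.0 / n / n)
        add(v, v, (n - 3.0) / n)  # (n-3)S/n

    S = sparse.coo_matrix((vals, (rows, cols)),
                          shape=(n_vertices + F + E, n_vertices)).tocsr()

    new_faces = np.empty((4 * F, 4), dtype=np.int64)
    for fi, face in enumerate(faces):
        for k in range(4):
            v = int(face[k])
            e_next = face_edges[fi, k]
            e_prev = face_edges[fi, (k - 1) % 4]
            new_faces[4 * fi + k] = (v, ep_base + e_next, fp_base + fi, ep_base + e_prev)
    return S, new_faces


class SubdivisionOperator:
    """Cached multi-level Catmull-Clark operator for a fixed topology."""

    def __init__(self, faces, n_vertices: int, levels: int):
        if levels < 0:
            raise BuildError("levels must be >= 0")
        self.levels = levels
        faces = np.asarray(faces, dtype=np.int64)
        matrix = sparse.identity(n_vertices, format="csr")
        for _ in range(levels):
            S, faces = _one_level(faces, matrix.shape[0])
            matrix = S @ matrix
        self.matrix = matrix
        self.faces = faces

    def apply(self, vertices: np.ndarray) -> QuadMesh:
        return QuadMesh(self.matrix @ np.asarray(vertices, float), self.faces)


def catmull_clark(mesh: QuadMesh, levels: int) -> QuadMesh:
    """Smooth a closed oriented quad mesh by ``levels`` Catmull-Clark steps."""
    if levels < 0:
        raise BuildError("levels must be >= 0")
    if levels == 0:
        return mesh
    rep = validate_mesh(mesh)
    if not (rep.is_closed and rep.is_oriented):
        raise BuildError("catmull_clark requires a closed, consistently oriented mesh")
    op = SubdivisionOperator(mesh.faces, mesh.n_vertices, levels)
    return op.apply(mesh.vertices)


def limit_check(mesh: QuadMesh, subdivided: QuadMesh, tol: float = 1e-7) -> bool:
    """True iff every subdivided vertex lies in the control mesh's convex hull.

    All Catmull-Clark weights are nonnegative and sum to one, so subdivided
    vertices are convex combinations of control vertices; a vertex outside
    the hull indicates corruption of the smoothed geometry.
    """
    from scipy.spatial import ConvexHull

    hull = ConvexHull(mesh.vertices)
    eq = hull.equations  # (n_facets, 4): normal | offset
    pts = subdivided.vertices
    vals = pts @ eq[:, :3].T + eq[:, 3][None, :]
    return bool(np.all(vals <= tol))
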