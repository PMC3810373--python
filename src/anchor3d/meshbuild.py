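"""Hexahedral block assembly: extrude the 2D strip layout into rectangular
building blocks and weld them into a closed all-quad boundary mesh.

Each in-plane point primitive is duplicated at z = +t/2 (front layer) and
z = -t/2 (back layer); each in-plane quad between adjacent stations becomes
one hexahedral block (8 point primitives).  Welding removes interior faces
shared by two blocks, leaving the closed, consistently oriented, genus-0
boundary surface whose vertices are the model's control points.

Where the across-resolution changes from 2 to 4 points per station (entering
or leaving a densified site), a conforming quad transition template is used:
four quads and two interior points tile the gap so that no T-junctions or
degenerate quads arise and the welded surface stays manifold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BuildError, DegeneracyError, LookupError_, TopologyError
from .template import NORMAL, SITE_LABELS, StripLayout

__all__ = [
    "PointPrimitive3D",
    "Hexahedron",
    "QuadMesh",
    "MeshReport",
    "extrude_strip",
    "assemble_mesh",
    "wireframe_edges",
    "validate_mesh",
    "count_site_primitives",
]

_AREA_TOL = 1e-9  # grid units^2; quads below this are rejected as slivers


@dataclass(frozen=True)
class PointPrimitive3D:
    """A control vertex of the block model, tagged with its template origin."""

    id: int
    x: float
    y: float
    z: float
    station_index: int
    across_index: int
    layer: str  # 'front' | 'back'
    site: str

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class Hexahedron:
    """8 vertex ids: front quad CCW viewed from +z, then back quad matching."""

    vertex_ids: tuple

    def __post_init__(self) -> None:
        if len(self.vertex_ids) != 8 or len(set(self.vertex_ids)) != 8:
            raise BuildError("hexahedron needs 8 distinct vertex ids")

    def faces(self) -> list[tuple]:
        """The 6 outward-oriented quad faces."""
        f = self.vertex_ids[:4]
        b = self.vertex_ids[4:]
        out = [tuple(f), (b[3], b[2], b[1], b[0])]
        for i in range(4):
            j = (i + 1) % 4
            out.append((f[j], f[i], b[i], b[j]))
        return out


class QuadMesh:
    """Closed, oriented, all-quad boundary mesh.

    ``vertices`` is a float array (V, 3); ``faces`` an int array (F, 4) of
    vertex ids, wound counter-clockwise as seen from outside.
    """

    def __init__(self, vertices, faces):
        self.vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(faces, dtype=np.int64).reshape(-1, 4)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> set:
        """Undirected edge set as sorted id pairs."""
        es = set()
        for face in self.faces:
            for i in range(4):
                a, b = int(face[i]), int(face[(i + 1) % 4])
                es.add((a, b) if a < b else (b, a))
        return es

    def copy(self) -> "QuadMesh":
        return QuadMesh(self.vertices.copy(), self.faces.copy())

    def transformed(self, matrix: np.ndarray, offset=None) -> "QuadMesh":
        """Apply an affine map x -> matrix @ x + offset."""
        off = np.zeros(3) if offset is None else np.asarray(offset, float)
        return QuadMesh(self.vertices @ np.asarray(matrix, float).T + off, self.faces)

    def face_areas(self) -> np.ndarray:
        v = self.vertices[self.faces]
        # quad area as sum of two triangles
        a1 = 0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)
        a2 = 0.5 * np.linalg.norm(np.cross(v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]), axis=1)
        return a1 + a2


@dataclass(frozen=True)
class MeshReport:
    is_closed: bool
    is_oriented: bool
    V: int
    E: int
    F: int
    euler: int
    degenerate_faces: int


def _quad_signed_area_xy(pts) -> float:
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _transition_quads(coarse, fine, coarse_first: bool):
    """Conforming 1->3 quad transition between a 2-point and a 4-point station.

    Returns (interior_points, quads) where quads reference corner tokens
    ('c', i) for coarse points, ('f', i) for fine points, ('n', k) for the
    two new interior points.
    """
    A0, A1 = np.asarray(coarse[0]), np.asarray(coarse[1])
    B = [np.asarray(p) for p in fine]
    Af = lambda f: A0 + (A1 - A0) * f
    Bf = lambda f: B[0] + (B[3] - B[0]) * f
    P = 0.5 * (Af(1.0 / 3.0) + Bf(1.0 / 3.0))
    Q = 0.5 * (Af(2.0 / 3.0) + Bf(2.0 / 3.0))
    quads = [
        (("c", 0), ("f", 0), ("f", 1), ("n", 0)),
        (("n", 0), ("f", 1), ("f", 2), ("n", 1)),
        (("n", 1), ("f", 2), ("f", 3), ("c", 1)),
        (("c", 0), ("n", 0), ("n", 1), ("c", 1)),
    ]
    return [P, Q], quads


def extrude_strip(layout: StripLayout, thickness: float = 1.0):
    """Extrude the in-plane layout into hexahedral building blocks.

    Every in-plane point primitive yields two 3D primitives at z = +/-t/2;
    every in-plane quad between adjacent stations yields one block of 8
    point primitives.  Returns (vertices, blocks).
    """
    stations = layout.stations
    if len(stations) < 2:
        raise BuildError("strip layout needs at least 2 stations")
    if thickness <= 0:
        raise BuildError("thickness must be > 0")

    # collect in-plane points: (xy, station_index, across_index, site)
    plane_pts = []
    station_base = []
    for j, st in enumerate(stations):
        station_base.append(len(plane_pts))
        for i, p in enumerate(st.points):
            plane_pts.append((np.asarray(p, float), j, i, st.site))

    quads = []  # each: 4 in-plane point indices, CCW in xy
    for j in range(len(stations) - 1):
        a, b = stations[j], stations[j + 1]
        ia, ib = station_base[j], station_base[j + 1]
        na, nb = a.n_across, b.n_across
        if na == nb:
            for i in range(na - 1):
                quads.append([ia + i, ib + i, ib + i + 1, ia + i + 1])
        elif {na, nb} == {2, 4}:
            if na == 2:
                coarse_idx = [ia, ia + 1]
                fine_idx = [ib + k for k in range(4)]
                coarse_pts = a.points
                fine_pts = b.points
            else:
                coarse_idx = [ib, ib + 1]
                fine_idx = [ia + k for k in range(4)]
                coarse_pts = b.points
                fine_pts = a.points
            new_pts, tq = _transition_quads(coarse_pts, fine_pts, na == 2)
            new_idx = []
            mid_s = 0.5 * (a.s + b.s)
            for k, p in enumerate(new_pts):
                new_idx.append(len(plane_pts))
                # interior transition points carry the coarse side's tag
                coarse_site = a.site if na == 2 else b.site
                plane_pts.append((p, j, -(k + 1), coarse_site))
            token_map = {("c", 0): coarse_idx[0], ("c", 1): coarse_idx[1],
                         ("n", 0): new_idx[0], ("n", 1): new_idx[1]}
            for k in range(4):
                token_map[("f", k)] = fine_idx[k]
            for q in tq:
                quads.append([token_map[t] for t in q])
        else:
            raise BuildError(
                f"unsupported across-resolution change {na} -> {nb} "
                f"between stations at s={a.s:.4f} and s={b.s:.4f}")

    # orient all in-plane quads CCW, reject slivers
    for q in quads:
        area = _quad_signed_area_xy([plane_pts[i][0] for i in q])
        if abs(area) < _AREA_TOL:
            raise DegeneracyError("degenerate (zero-area) quad in strip extrusion")
        if area < 0:
            q.reverse()

    n = len(plane_pts)
    half = thickness / 2.0
    vertices = []
    for k, (p, j, i, site) in enumerate(plane_pts):
        vertices.append(PointPrimitive3D(id=k, x=float(p[0]), y=float(p[1]), z=half,
                                         station_index=j, across_index=i,
                                         layer="front", site=site))
    for k, (p, j, i, site) in enumerate(plane_pts):
        vertices.append(PointPrimitive3D(id=n + k, x=float(p[0]), y=float(p[1]), z=-half,
                                         station_index=j, across_index=i,
                                         layer="back", site=site))

    blocks = [Hexahedron(tuple(q) + tuple(i + n for i in q)) for q in quads]
    return vertices, blocks


def assemble_mesh(vertices, blocks) -> QuadMesh:
    """Weld hexahedral blocks into their closed boundary QuadMesh.

    Interior faces (shared by exactly two blocks) are removed; a face
    shared by three or more blocks is a non-manifold weld and raises
    :class:`TopologyError`.
    """
    if not blocks:
        raise BuildError("no blocks to assemble")
    positions = np.array([[v.x, v.y, v.z] for v in sorted(vertices, key=lambda v: v.id)])
    ids = [v.id for v in sorted(vertices, key=lambda v: v.id)]
    if ids != list(range(len(ids))):
        raise BuildError("vertex ids must be contiguous from 0")

    face_count: dict = {}
    face_repr: dict = {}
    for hx in blocks:
        for f in hx.faces():
            key = frozenset(f)
            face_count[key] = face_count.get(key, 0) + 1
            face_repr.setdefault(key, f)
    if any(c > 2 for c in face_count.values()):
        raise TopologyError("non-manifold weld: a face is shared by more than two blocks")

    boundary = [face_repr[k] for k, c in face_count.items() if c == 1]
    mesh = QuadMesh(positions, boundary)
    areas = mesh.face_areas()
    if np.any(areas < _AREA_TOL):
        raise DegeneracyError("degenerate face in assembled mesh")
    return mesh


def wireframe_edges(mesh: QuadMesh) -> list[tuple]:
    """Every edge of the block surface exactly once (unordered id pairs).

    This is the wireframe view used to inspect the underlying block
    structure of the model.
    """
    return sorted(mesh.edges())


def validate_mesh(mesh: QuadMesh) -> MeshReport:
    """Compute closure/orientation/Euler diagnostics; never raises."""
    undirected: dict = {}
    directed: set = set()
    dup_directed = False
    for face in mesh.faces:
        for i in range(4):
            a, b = int(face[i]), int(face[(i + 1) % 4])
            key = (a, b) if a < b else (b, a)
            undirected[key] = undirected.get(key, 0) + 1
            if (a, b) in directed:
                dup_directed = True
            directed.add((a, b))
    V = mesh.n_vertices
    E = len(undirected)
    F = mesh.n_faces
    is_closed = bool(undirected) and all(c == 2 for c in undirected.values())
    is_oriented = (not dup_directed) and all(
        ((b, a) in directed) == (undirected[(min(a, b), max(a, b))] == 2)
        for (a, b) in directed)
    degenerate = int(np.sum(mesh.face_areas() < _AREA_TOL)) if F else 0
    return MeshReport(is_closed=is_closed, is_oriented=is_oriented,
                      V=V, E=E, F=F, euler=V - E + F, degenerate_faces=degenerate)


def count_site_primitives(model_vertices, site: str) -> int:
    """Distinct front-layer in-plane primitive positions tagged with ``site``."""
    if site not in SITE_LABELS and site != NORMAL:
        raise LookupError_(f"unknown site label {site!r}")
    seen = set()
    for v in model_vertices:
        if v.layer == "front" and v.site == site:
            seen.add((round(v.x, 9), round(v.y, 9)))
    return len(seen)
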