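"""Deformation of the generic anchor model into new target shapes.

Two routes mirror the modelling workflow:

* **direct manipulation** (:func:`fit_to_template`): every control vertex is
  a pilot point; boundary pilots are put in correspondence with the target
  outline and displaced iteratively until the silhouette of the smoothed
  model matches the target illustration;
* **coordinate replacement** (:func:`deform_by_coordinates`): control vertex
  positions are replaced wholesale from a coordinate table, e.g. one
  exported from a previous fit.  Both routes produce identical meshes when
  fed equivalent coordinates.

The fit criterion is quantified: mean symmetric boundary distance (absolute
and relative to the target's bounding-box diagonal), Hausdorff distance and
silhouette/target area IoU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely import hausdorff_distance
from shapely.geometry import LinearRing, Point, Polygon
from shapely.geometry.polygon import orient
from shapely.ops import unary_union
from shapely.validation import make_valid

from .errors import GeometryError, LookupError_, TableError
from .meshbuild import QuadMesh
from .subdivision import SubdivisionOperator
from .template import Template2D

__all__ = [
    "GenericModel",
    "Correspondence",
    "FitReport",
    "FitTolerances",
    "DeformationResult",
    "silhouette",
    "fit_report",
    "correspond_pilots",
    "move_pilots",
    "fit_to_template",
    "deform_by_coordinates",
    "rotate_views",
]


@dataclass(frozen=True)
class GenericModel:
    """Deformable block model: control mesh + primitive tags + template.

    Every control vertex is a pilot point.  ``primitives`` is the build-time
    tag list (one :class:`~anchor3d.meshbuild.PointPrimitive3D` per vertex,
    same order); only the tags are read from it after construction — the
    live positions are ``control_mesh.vertices``.
    """

    control_mesh: QuadMesh
    primitives: tuple
    template_ref: Template2D
    display_levels: int = 2

    @property
    def pilots(self) -> frozenset:
        return frozenset(range(self.control_mesh.n_vertices))

    @property
    def site_map(self) -> dict:
        return {p.id: p.site for p in self.primitives}

    def front_ids(self) -> np.ndarray:
        return np.array([p.id for p in self.primitives if p.layer == "front"])

    def boundary_loop(self) -> list[int]:
        """Front-layer boundary pilots as an ordered CCW cycle.

        Topological: rim edges are those used by exactly one all-front face.
        """
        front = {p.id for p in self.primitives if p.layer == "front"}
        faces = self.control_mesh.faces
        edge_use: dict = {}
        for face in faces:
            if all(int(v) in front for v in face):
                for i in range(4):
                    a, b = int(face[i]), int(face[(i + 1) % 4])
                    key = (a, b) if a < b else (b, a)
                    edge_use[key] = edge_use.get(key, 0) + 1
        rim = [e for e, c in edge_use.items() if c == 1]
        if not rim:
            raise GeometryError("model has no front-face rim")
        nbr: dict = {}
        for a, b in rim:
            nbr.setdefault(a, []).append(b)
            nbr.setdefault(b, []).append(a)
        start = rim[0][0]
        loop = [start]
        prev = None
        while True:
            cands = [v for v in nbr[loop[-1]] if v != prev]
            nxt = cands[0]
            if nxt == start:
                break
            prev = loop[-1]
            loop.append(nxt)
        xy = self.control_mesh.vertices[loop][:, :2]
        area = 0.5 * np.sum(xy[:, 0] * np.roll(xy[:, 1], -1) - np.roll(xy[:, 0], -1) * xy[:, 1])
        if area < 0:
            loop = [loop[0]] + loop[:0:-1]
        return loop

    def with_vertices(self, vertices: np.ndarray) -> "GenericModel":
        return replace(self, control_mesh=QuadMesh(vertices, self.control_mesh.faces))


@dataclass(frozen=True)
class Correspondence:
    """Boundary pilot -> target outline point mapping by cyclic arc length."""

    pairs: dict
    cyclic_offset: float
    orientation: int


@dataclass(frozen=True)
class FitReport:
    mean_sym_dist: float
    mean_sym_dist_rel: float
    hausdorff: float
    iou: float


@dataclass(frozen=True)
class FitTolerances:
    """Convergence tolerances and step control for direct-manipulation fits."""

    rel: float = 0.015
    iou: float = 0.95
    lam: float = 0.8
    max_iters: int = 200


@dataclass(frozen=True)
class DeformationResult:
    model: GenericModel
    fit: FitReport
    iterations: int
    trace: tuple
    converged: bool


# ---------------------------------------------------------------------------
# Silhouette and fit metrics
# ---------------------------------------------------------------------------

def _silhouette_polygon(sub: QuadMesh) -> Polygon:
    v = sub.vertices
    fv = v[sub.faces]
    n = np.cross(fv[:, 1] - fv[:, 0], fv[:, 2] - fv[:, 0]) \
        + np.cross(fv[:, 2] - fv[:, 0], fv[:, 3] - fv[:, 0])
    # for a closed mesh the union of upward-facing projections equals the
    # union of all non-edge-on projections; the latter is robust when the
    # mesh is viewed edge-on (rotated 90 degrees)
    front = fv[np.abs(n[:, 2]) > 1e-12][:, :, :2]
    if len(front) == 0:
        raise GeometryError("mesh projects to zero area")
    polys = []
    for quad in front:
        p = Polygon(quad)
        if not p.is_valid:
            p = make_valid(p)
        if p.area > 0:
            polys.append(p)
    try:
        u = unary_union(polys)
    except Exception:
        # GEOS can fail on near-degenerate overlaps; retry with snap rounding
        import shapely

        u = shapely.union_all(polys, grid_size=1e-9)
    if u.geom_type == "GeometryCollection":
        parts = [g for g in u.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        u = unary_union(parts)
    if u.geom_type == "MultiPolygon":
        areas = [g.area for g in u.geoms]
        amax = max(areas)
        big = [g for g in u.geoms if g.area > 1e-6 * amax]
        if len(big) > 1:
            raise GeometryError("silhouette projection has multiple disjoint components")
        u = big[0]
    if u.is_empty or u.geom_type != "Polygon":
        raise GeometryError("silhouette projection is degenerate")
    return orient(Polygon(u.exterior), sign=1.0)


def silhouette(mesh: QuadMesh, levels: int = 0) -> np.ndarray:
    """Outline of the smoothed mesh's x-y projection (closed CCW polygon).

    The mesh is Catmull-Clark subdivided ``levels`` times, its upward-facing
    faces are projected to the template plane, and the boundary of their
    union is returned as an (N, 2) array (last point not repeated).
    """
    from .subdivision import catmull_clark

    sub = catmull_clark(mesh, levels) if levels > 0 else mesh
    poly = _silhouette_polygon(sub)
    return np.asarray(poly.exterior.coords[:-1], dtype=float)


def _as_polygon(obj) -> Polygon:
    if isinstance(obj, Polygon):
        return obj
    if isinstance(obj, Template2D):
        return Polygon(obj.outline)
    return Polygon(np.asarray(obj, dtype=float))


def _ring_samples(ring: LinearRing, n: int) -> np.ndarray:
    d = np.linspace(0.0, ring.length, n, endpoint=False)
    import shapely

    pts = shapely.line_interpolate_point(ring, d)
    return np.array([[p.x, p.y] for p in pts])


def fit_report(model_silhouette, target, n_samples: int = 256) -> FitReport:
    """Quantify agreement between a silhouette polygon and a target outline."""
    ps = _as_polygon(model_silhouette)
    pt = _as_polygon(target)
    if ps.area < 1e-9 or pt.area < 1e-9:
        raise GeometryError("degenerate polygon in fit_report")
    rs, rt = LinearRing(ps.exterior), LinearRing(pt.exterior)
    import shapely

    a = _ring_samples(rs, n_samples)
    b = _ring_samples(rt, n_samples)
    da = shapely.distance(shapely.points(a), rt)
    db = shapely.distance(shapely.points(b), rs)
    mean_sym = 0.5 * (float(np.mean(da)) + float(np.mean(db)))
    haus = max(float(np.max(da)), float(np.max(db)))
    minx, miny, maxx, maxy = pt.bounds
    diag = float(np.hypot(maxx - minx, maxy - miny))
    inter = ps.intersection(pt).area
    union = ps.union(pt).area
    return FitReport(mean_sym_dist=mean_sym,
                     mean_sym_dist_rel=mean_sym / diag,
                     hausdorff=haus,
                     iou=inter / union if union > 0 else 0.0)


# ---------------------------------------------------------------------------
# Correspondence and pilot movement
# ---------------------------------------------------------------------------

def _loop_arclengths(xy: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(np.vstack([xy, xy[:1]]), axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg[:-1])])
    return cum / seg.sum()


def correspond_pilots(model: GenericModel, target: Template2D,
                      n_offsets: int = 64) -> Correspondence:
    """Map front boundary pilots to target outline points by arc length.

    The cyclic offset and traversal orientation are chosen by brute force
    (``n_offsets`` offsets x 2 orientations) to minimize the mean distance
    from pilots to their mapped target points.
    """
    loop = model.boundary_loop()
    xy = model.control_mesh.vertices[loop][:, :2]
    s = _loop_arclengths(xy)
    ring = LinearRing(_as_polygon(target).exterior)
    M = 1024
    grid = _ring_samples(ring, M)

    def evaluate(off, orientation):
        idx = np.mod(np.round((orientation * s + off) * M).astype(int), M)
        cand = grid[idx]
        cost = float(np.mean(np.linalg.norm(xy - cand, axis=1)))
        return cost, off, orientation, cand

    best = min(evaluate(k / n_offsets, o)
               for o in (1, -1) for k in range(n_offsets))
    # refine the cyclic offset around the best coarse candidate
    coarse = best[1]
    best = min(evaluate((coarse + d / n_offsets) % 1.0, best[2])
               for d in np.linspace(-1.0, 1.0, 65))
    _, off, orientation, cand = best
    pairs = {int(v): cand[i].copy() for i, v in enumerate(loop)}
    return Correspondence(pairs=pairs, cyclic_offset=off, orientation=orientation)


def move_pilots(model: GenericModel, selection, displacements) -> GenericModel:
    """Displace selected pilot points exactly; topology untouched.

    ``displacements`` maps pilot id -> 3-vector.  Unselected vertices are
    not moved (no proportional falloff).
    """
    verts = model.control_mesh.vertices.copy()
    V = len(verts)
    for vid in selection:
        if not (0 <= int(vid) < V):
            raise LookupError_(f"unknown pilot id {vid}")
        verts[int(vid)] += np.asarray(displacements[vid], dtype=float)
    return model.with_vertices(verts)


# ---------------------------------------------------------------------------
# Direct-manipulation fitting
# ---------------------------------------------------------------------------

def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares non-decreasing fit to y."""
    n = len(y)
    vals = y.astype(float).copy()
    wts = np.ones(n)
    blocks = []  # (value, weight, count)
    for i in range(n):
        v, w, c = vals[i], wts[i], 1
        while blocks and blocks[-1][0] > v:
            pv, pw, pc = blocks.pop()
            v = (v * w + pv * pw) / (w + pw)
            w += pw
            c += pc
        blocks.append((v, w, c))
    out = np.empty(n)
    k = 0
    for v, _, c in blocks:
        out[k:k + c] = v
        k += c
    return out


def _ordered_icp_residual(sil_pts: np.ndarray, target_ring: LinearRing) -> np.ndarray:
    """Order-preserving nearest-point residual toward the target outline.

    Each silhouette point is projected to its nearest arc position on the
    target ring; positions are then cyclically unwrapped and made monotone
    (pool-adjacent-violators) so neighbouring pilots cannot swap targets —
    this keeps the correspondence untangled around narrow protrusions.
    """
    L = target_ring.length
    raw = np.array([target_ring.project(Point(q)) / L for q in sil_pts])
    # nearest unwrap relative to the previous point
    t = raw.copy()
    for i in range(1, len(t)):
        t[i] = raw[i] + np.round(t[i - 1] - raw[i])
    inc = _pava(t)
    dec = -_pava(-t)
    # pick the traversal direction that disturbs the projections least
    t_fit = inc if np.sum((inc - t) ** 2) <= np.sum((dec - t) ** 2) else dec
    pts = np.array([target_ring.interpolate((ti % 1.0) * L).coords[0] for ti in t_fit])
    return pts - sil_pts


def _idw_displacements(verts: np.ndarray, boundary_ids: np.ndarray,
                       boundary_disp: np.ndarray, k: int = 6) -> np.ndarray:
    """Propagate boundary displacements to all vertices by inverse-distance
    weighting (power 2) in the template plane.

    Each vertex follows only its ``k`` nearest boundary pilots, so a large
    move at one pilot deforms its own neighbourhood without dragging distant
    parts of the model.  A vertex coincident in x-y with a boundary pilot
    (its back-layer twin) copies that displacement exactly."""
    bxy = verts[boundary_ids][:, :2]
    d2 = ((verts[:, None, :2] - bxy[None, :, :]) ** 2).sum(axis=2)
    exact = d2 < 1e-18
    w = 1.0 / np.maximum(d2, 1e-18)
    if w.shape[1] > k:
        # zero out all but the k nearest boundary pilots per vertex
        idx = np.argpartition(d2, k, axis=1)[:, k:]
        np.put_along_axis(w, idx, 0.0, axis=1)
    has_exact = exact.any(axis=1)
    w[has_exact] = exact[has_exact].astype(float)
    return (w @ boundary_disp) / w.sum(axis=1, keepdims=True)


def fit_to_template(model: GenericModel, target: Template2D,
                    max_iters: int | None = None,
                    tol: FitTolerances = FitTolerances(),
                    align: bool = True) -> DeformationResult:
    """Deform the model onto a target outline by direct manipulation.

    Each iteration: (1) boundary pilots are put in correspondence with the
    target outline, (2) each pilot is stepped by ``tol.lam`` times the
    residual between its corresponding target point and its nearest point
    on the current smoothed silhouette (so the *displayed* surface, not the
    control cage, converges to the outline), (3) interior and back-layer
    vertices follow by inverse-distance-weighted interpolation, (4) the
    silhouette and fit metrics are recomputed.  Steps that would worsen the
    mean symmetric distance are retried with a halved step; the accepted
    trace is therefore monotone non-increasing.  z coordinates are never
    modified.
    """
    if max_iters is None:
        max_iters = tol.max_iters
    control = model.control_mesh
    op = SubdivisionOperator(control.faces, control.n_vertices, model.display_levels)
    verts = control.vertices.copy()
    target_poly = _as_polygon(target)

    if align:
        sil = _silhouette_polygon(op.apply(verts))
        sb, tb = sil.bounds, target_poly.bounds
        s_diag = np.hypot(sb[2] - sb[0], sb[3] - sb[1])
        t_diag = np.hypot(tb[2] - tb[0], tb[3] - tb[1])
        scale = t_diag / s_diag
        sc = np.array([(sb[0] + sb[2]) / 2, (sb[1] + sb[3]) / 2])
        tc = np.array([(tb[0] + tb[2]) / 2, (tb[1] + tb[3]) / 2])
        verts[:, :2] = (verts[:, :2] - sc) * scale + tc

    cur_sil = _silhouette_polygon(op.apply(verts))
    cur_fit = fit_report(cur_sil, target_poly)
    trace = [cur_fit]
    iterations = 0
    converged = cur_fit.mean_sym_dist_rel <= tol.rel and cur_fit.iou >= tol.iou
    lam = tol.lam
    target_ring = LinearRing(target_poly.exterior)

    def _try_step(residual, bids, step):
        bdisp = step * residual
        disp = _idw_displacements(verts, bids, bdisp)
        cand = verts.copy()
        cand[:, :2] += disp
        try:
            cand_sil = _silhouette_polygon(op.apply(cand))
            cand_fit = fit_report(cand_sil, target_poly)
        except Exception:
            # a step that degenerates the silhouette is simply not accepted
            return None
        if cand_fit.mean_sym_dist <= cur_fit.mean_sym_dist + 1e-12:
            return cand, cand_sil, cand_fit
        return None

    while not converged and iterations < max_iters and lam >= 0.005:
        work = model.with_vertices(verts)
        corr = correspond_pilots(work, target)
        loop = list(corr.pairs.keys())
        bids = np.array(loop)
        pilots_xy = verts[bids][:, :2]
        # where the smoothed silhouette currently sits for each pilot
        sil_ring = LinearRing(cur_sil.exterior)
        sil_pts = np.array([
            sil_ring.interpolate(sil_ring.project(Point(q))).coords[0]
            for q in pilots_xy])
        # global residual: cyclic arc-length correspondence with the outline
        targets_xy = np.array([corr.pairs[v] for v in loop])
        res_arc = targets_xy - sil_pts
        # local residual: nearest target point to the silhouette (ICP-style),
        # robust where a protrusion distorts the arc-length parameterization
        res_icp = _ordered_icp_residual(sil_pts, target_ring)
        # focused residual: act only on the worst-matched half of the boundary
        mag = np.linalg.norm(res_arc, axis=1)
        res_focus = np.where((mag >= np.median(mag))[:, None], res_arc, 0.0)

        candidates = []
        for residual in (res_icp, res_arc, 0.5 * (res_arc + res_icp), res_focus):
            step = lam
            for _ in range(5):
                hit = _try_step(residual, bids, step)
                if hit is not None:
                    candidates.append(hit)
                    break
                step *= 0.5
        accepted = min(candidates, key=lambda t: t[2].mean_sym_dist) if candidates else None
        if accepted is None:
            # all step sizes down to lam/16 were just rejected; resume the
            # search below them rather than re-trying overlapping steps
            lam /= 32.0
            continue
        verts, cur_sil, cur_fit = accepted
        lam = min(tol.lam, lam * 1.5)  # recover step size after progress
        trace.append(cur_fit)
        iterations += 1
        converged = cur_fit.mean_sym_dist_rel <= tol.rel and cur_fit.iou >= tol.iou

    return DeformationResult(model=model.with_vertices(verts), fit=cur_fit,
                             iterations=iterations, trace=tuple(trace),
                             converged=converged)


# ---------------------------------------------------------------------------
# Coordinate-table deformation and rotation views
# ---------------------------------------------------------------------------

def deform_by_coordinates(model: GenericModel, table) -> GenericModel:
    """Replace control vertex positions from a coordinate table.

    The table must carry exactly one row per control vertex with matching
    ids (see :mod:`anchor3d.io`); topology is unchanged.
    """
    V = model.control_mesh.n_vertices
    ids = np.asarray(table.ids)
    if len(ids) != V:
        raise TableError(f"table has {len(ids)} rows, model has {V} control vertices")
    if not np.array_equal(ids, np.arange(V)):
        raise TableError("table ids must match the model's vertex ids 0..V-1")
    return model.with_vertices(np.asarray(table.xyz, dtype=float).copy())


def _rotation_matrix(axis: str, degrees: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    if axis not in ("x", "y", "z"):
        raise GeometryError(f"unknown rotation axis {axis!r}")
    return Rotation.from_euler(axis, degrees, degrees=True).as_matrix()


def rotate_views(mesh: QuadMesh, axis: str, angles, levels: int = 0):
    """Silhouettes of the mesh rigidly rotated (anti-clockwise) about an axis.

    Rotation is about the vertex centroid so views stay registered.
    Returns a list of (angle, silhouette polygon) pairs.
    """
    centroid = mesh.vertices.mean(axis=0)
    out = []
    for ang in angles:
        R = _rotation_matrix(axis, float(ang))
        rot = QuadMesh((mesh.vertices - centroid) @ R.T + centroid, mesh.faces)
        out.append((float(ang), silhouette(rot, levels)))
    return out
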