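"""Coordinate tables and mesh/vector export.

The coordinate table is the package's interchange format for model
geometry: one CSV row per control vertex (``id,x,y,z,site``), written at
full precision so a write -> read -> write cycle is byte identical.
Applying a table to a freshly built generic model reproduces a deformed
mesh exactly — the file-based equivalent of re-entering Cartesian
coordinates into the build script.

Mesh export covers OBJ and ascii PLY (quads preserved) and ascii STL
(quads split along the shorter diagonal).  All writers are deterministic:
no timestamps, fixed float formatting (``repr`` round-trip).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ParseError
from .meshbuild import QuadMesh
from .template import Template2D

logger = logging.getLogger("anchor3d")

__all__ = [
    "CoordinateTable",
    "write_coordinate_table",
    "read_coordinate_table",
    "write_obj",
    "write_ply",
    "write_stl",
    "write_svg_overlay",
]


@dataclass(frozen=True)
class CoordinateTable:
    """Ordered records of control-vertex coordinates with site tags."""

    ids: np.ndarray
    xyz: np.ndarray
    sites: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", np.asarray(self.ids, dtype=np.int64))
        object.__setattr__(self, "xyz", np.asarray(self.xyz, dtype=float).reshape(-1, 3))
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ParseError("duplicate ids in coordinate table")
        if len(self.ids) != len(self.xyz) or len(self.ids) != len(self.sites):
            raise ParseError("coordinate table columns have unequal lengths")


def _fmt(x: float) -> str:
    return repr(float(x))


def coordinate_table_from_model(model) -> CoordinateTable:
    verts = model.control_mesh.vertices
    site_map = model.site_map
    ids = np.arange(len(verts))
    return CoordinateTable(ids=ids, xyz=verts,
                           sites=tuple(site_map[i] for i in ids))


def write_coordinate_table(model, path) -> None:
    """Write one CSV row per control vertex: ``id,x,y,z,site``.

    Floats are written with ``repr`` so the file round-trips losslessly.
    A comment header records the template's grid spacing (coordinates are
    unit-agnostic grid squares).
    """
    table = coordinate_table_from_model(model)
    lines = [f"# grid_spacing={_fmt(model.template_ref.grid_spacing)}",
             "id,x,y,z,site"]
    for i, (x, y, z), site in zip(table.ids, table.xyz, table.sites):
        lines.append(f"{i},{_fmt(x)},{_fmt(y)},{_fmt(z)},{site}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_coordinate_table(path) -> CoordinateTable:
    """Parse a coordinate table; errors name the offending line.

    Unknown extra columns are ignored with a logged warning.
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    rows = [(n + 1, line) for n, line in enumerate(raw)
            if line.strip() and not line.startswith("#")]
    if not rows:
        raise ParseError(f"{path}: empty coordinate table")
    header_no, header = rows[0]
    cols = [c.strip() for c in header.split(",")]
    required = ["id", "x", "y", "z", "site"]
    for c in required:
        if c not in cols:
            raise ParseError(f"{path}:{header_no}: missing column {c!r}")
    extra = [c for c in cols if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, extra)
    idx = {c: cols.index(c) for c in required}

    ids, xyz, sites = [], [], []
    seen = set()
    for line_no, line in rows[1:]:
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < len(cols):
            raise ParseError(f"{path}:{line_no}: expected {len(cols)} fields")
        try:
            vid = int(parts[idx["id"]])
            pos = [float(parts[idx[c]]) for c in ("x", "y", "z")]
        except ValueError as exc:
            raise ParseError(f"{path}:{line_no}: non-numeric value ({exc})") from None
        if vid in seen:
            raise ParseError(f"{path}:{line_no}: duplicate id {vid}")
        seen.add(vid)
        ids.append(vid)
        xyz.append(pos)
        sites.append(parts[idx["site"]])
    return CoordinateTable(ids=np.array(ids), xyz=np.array(xyz), sites=tuple(sites))


# ---------------------------------------------------------------------------
# Mesh export
# ---------------------------------------------------------------------------

def write_obj(mesh: QuadMesh, path) -> None:
    """Wavefront OBJ with quad faces (1-based indices per the format)."""
    lines = []
    for v in mesh.vertices:
        lines.append(f"v {_fmt(v[0])} {_fmt(v[1])} {_fmt(v[2])}")
    for f in mesh.faces:
        lines.append(f"f {f[0]+1} {f[1]+1} {f[2]+1} {f[3]+1}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def write_ply(mesh: QuadMesh, path) -> None:
    """ascii PLY with quad faces."""
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property float x", "property float y", "property float z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v in mesh.vertices:
        lines.append(f"{_fmt(v[0])} {_fmt(v[1])} {_fmt(v[2])}")
    for f in mesh.faces:
        lines.append(f"4 {f[0]} {f[1]} {f[2]} {f[3]}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def write_stl(mesh: QuadMesh, path, name: str = "anchor3d") -> None:
    """ascii STL; each quad split into two triangles along its shorter diagonal."""
    v = mesh.vertices
    lines = [f"solid {name}"]
    for f in mesh.faces:
        a, b, c, d = (v[i] for i in f)
        if np.linalg.norm(c - a) <= np.linalg.norm(d - b):
            tris = [(a, b, c), (a, c, d)]
        else:
            tris = [(a, b, d), (b, c, d)]
        for p0, p1, p2 in tris:
            n = np.cross(p1 - p0, p2 - p0)
            nn = np.linalg.norm(n)
            n = n / nn if nn > 0 else n
            lines.append(f"  facet normal {_fmt(n[0])} {_fmt(n[1])} {_fmt(n[2])}")
            lines.append("    outer loop")
            for p in (p0, p1, p2):
                lines.append(f"      vertex {_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}")
            lines.append("    endloop")
            lines.append("  endfacet")
    lines.append(f"endsolid {name}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SVG overlay (target outline in red, model silhouettes in grey)
# ---------------------------------------------------------------------------

def _svg_path(points: np.ndarray) -> str:
    cmds = [f"{'M' if i == 0 else 'L'} {_fmt(x)} {_fmt(-y)}"
            for i, (x, y) in enumerate(points)]
    return " ".join(cmds) + " Z"


def write_svg_overlay(target: Template2D, silhouettes, path) -> None:
    """SVG comparing a target outline (red stroke) with model silhouettes
    (grey fill at 50% opacity); y axis flipped to screen convention; viewBox
    is the target bounding box padded by 10%."""
    outline = np.asarray(target.outline, dtype=float)
    if len(outline) < 3:
        raise GeometryError("target outline is degenerate")
    minx, miny = outline.min(axis=0)
    maxx, maxy = outline.max(axis=0)
    w, h = maxx - minx, maxy - miny
    pad = 0.10
    vb = (minx - pad * w, -(maxy + pad * h), w * (1 + 2 * pad), h * (1 + 2 * pad))
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'viewBox="{_fmt(vb[0])} {_fmt(vb[1])} {_fmt(vb[2])} {_fmt(vb[3])}">',
    ]
    for sil in silhouettes:
        parts.append(f'<path d="{_svg_path(np.asarray(sil, float))}" '
                     'fill="grey" fill-opacity="0.5" stroke="none"/>')
    parts.append(f'<path d="{_svg_path(outline)}" fill="none" '
                 'stroke="red" stroke-width="0.2"/>')
    parts.append("</svg>")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(parts) + "\n")
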