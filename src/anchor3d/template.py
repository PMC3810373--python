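"""2D anchor templates: synthetic outline generation, site annotation, strip layout.

A dactylogyridean anchor is a hook-shaped sclerite with an inner root, an
outer root, a shaft and a recurved point.  The modelling workflow starts
from a closed 2D outline of the anchor (the *template*) together with a
medial path running from the inner-root end to the point tip.  Point
primitives — the future control vertices of the 3D model — are laid out in
*stations* along the medial path: each station is a short chord across the
local width of the anchor carrying 2 or more equally spaced points.

Seven regions of the anchor (sites I–VII) concentrate most of the shape
variation seen across species (root bulges, the outer root, the 'ear'
extrusion, the recurve of the point); these sites receive densified
primitive layouts controlled by a :class:`SiteConfig`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LinearRing, LineString, Point, Polygon

from .errors import AnnotationError, DegeneracyError, GeometryError, ParameterError

__all__ = [
    "SITE_LABELS",
    "NORMAL",
    "SiteAnnotation",
    "SiteConfig",
    "AnchorParams",
    "Template2D",
    "Station",
    "StripLayout",
    "DEFAULT_SITES",
    "DEFAULT_SITE_COUNTS",
    "generate_synthetic_anchor",
    "reference_template",
    "anchor_variants",
    "snap_to_grid",
    "annotate_sites",
    "layout_strip",
    "save_template",
    "load_template",
]

SITE_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII")
NORMAL = "normal"


@dataclass(frozen=True)
class SiteAnnotation:
    """A labelled interval of the medial path (normalized arc length)."""

    label: str
    s_start: float
    s_end: float

    def __post_init__(self) -> None:
        if self.label not in SITE_LABELS and self.label != NORMAL:
            raise AnnotationError(f"unknown site label {self.label!r}")
        if not (0.0 <= self.s_start < self.s_end <= 1.0):
            raise AnnotationError(
                f"site {self.label}: interval [{self.s_start}, {self.s_end}] "
                "must satisfy 0 <= start < end <= 1"
            )


#: Packaged annotation of the seven high-variation sites, ordered from the
#: inner-root end (s=0) to the point tip (s=1).
DEFAULT_SITES = (
    SiteAnnotation("I", 0.02, 0.10),
    SiteAnnotation("II", 0.12, 0.20),
    SiteAnnotation("III", 0.22, 0.28),
    SiteAnnotation("IV", 0.30, 0.44),
    SiteAnnotation("V", 0.48, 0.56),
    SiteAnnotation("VI", 0.60, 0.72),
    SiteAnnotation("VII", 0.76, 0.88),
)

#: Packaged per-site in-plane primitive counts for the final generic model.
DEFAULT_SITE_COUNTS = {
    NORMAL: 4,
    "I": 8,
    "II": 8,
    "III": 8,
    "IV": 8,
    "V": 6,
    "VI": 16,
    "VII": 16,
}


@dataclass(frozen=True)
class SiteConfig:
    """Per-site in-plane point-primitive counts.

    A count ``c`` is realised as ``n_along`` stations of ``n_across`` points
    each.  The packaged factorizations are 4 -> 2x2, 6 -> 3x2, 8 -> 4x2,
    16 -> 4x4; other even counts use 4 across when divisible by 4 and >= 16,
    else 2 across.
    """

    counts: dict = field(default_factory=lambda: dict(DEFAULT_SITE_COUNTS))
    metadata: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        for label, c in self.counts.items():
            if label not in SITE_LABELS and label != NORMAL:
                raise ParameterError(f"unknown site label {label!r} in config")
            if c < 4 or c % 2:
                raise ParameterError(f"site {label}: count {c} must be even and >= 4")

    def count(self, label: str) -> int:
        return self.counts.get(label, self.counts.get(NORMAL, 4))

    def factorize(self, label: str) -> tuple[int, int]:
        """Return (n_along, n_across) for a site's count."""
        c = self.count(label)
        fixed = {4: (2, 2), 6: (3, 2), 8: (4, 2), 16: (4, 4)}
        if c in fixed:
            return fixed[c]
        if c >= 16 and c % 4 == 0:
            return (c // 4, 4)
        return (c // 2, 2)


@dataclass(frozen=True)
class AnchorParams:
    """Parameters of the synthetic anchor generator (grid units / radians).

    The generator emulates the morphology of a simple dactylogyridean
    anchor: a gently curved shaft descending from the inner root, a
    sharply recurved point, an outer-root protrusion on one side of the
    base, and optionally an 'ear' lobe plus small ornament bumps.
    """

    shaft_length: float = 10.0
    shaft_curvature: float = 0.8
    point_length: float = 5.0
    point_curl: float = 1.9
    inner_root_length: float = 5.0
    inner_root_width: float = 2.2
    outer_root_length: float = 2.2
    outer_root_width: float = 1.6
    outer_root_lobes: int = 1
    outer_root_centers: tuple = ()  # medial positions of the lobes; () = spread in site IV
    ear: bool = False
    ear_size: float = 1.2
    ornament_bumps: int = 0
    ornament_amplitude: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        for name in ("shaft_length", "point_length", "inner_root_length",
                     "outer_root_length", "inner_root_width", "outer_root_width"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.inner_root_width >= self.inner_root_length:
            raise ParameterError("inner_root_width must be < inner_root_length")
        if self.outer_root_width >= 2.0 * self.outer_root_length:
            raise ParameterError("outer_root_width must be < 2 * outer_root_length")
        if self.ear and self.ear_size <= 0:
            raise ParameterError("ear_size must be > 0 when ear is set")
        if self.ornament_bumps < 0:
            raise ParameterError("ornament_bumps must be >= 0")
        if self.outer_root_lobes < 1:
            raise ParameterError("outer_root_lobes must be >= 1")


@dataclass(frozen=True)
class Template2D:
    """Closed 2D anchor outline with medial path and site annotations.

    ``outline`` is a simple, counter-clockwise closed polyline (last point
    is not a repeat of the first); ``medial_path`` runs from the inner-root
    end to the point tip, strictly inside the outline.  All coordinates are
    in grid units; ``grid_spacing`` records the physical length of one grid
    square for provenance only.
    """

    name: str
    outline: np.ndarray
    medial_path: np.ndarray
    grid_spacing: float = 1.0
    sites: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "outline", np.asarray(self.outline, dtype=float))
        object.__setattr__(self, "medial_path", np.asarray(self.medial_path, dtype=float))

    # -- derived geometry -------------------------------------------------

    def polygon(self) -> Polygon:
        return Polygon(self.outline)

    def medial_arclength(self) -> np.ndarray:
        """Cumulative normalized arc length (0..1) at each medial vertex."""
        seg = np.linalg.norm(np.diff(self.medial_path, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        return cum / cum[-1]

    def medial_point(self, s: float) -> np.ndarray:
        """Point on the medial path at normalized arc length ``s``."""
        t = self.medial_arclength()
        x = np.interp(s, t, self.medial_path[:, 0])
        y = np.interp(s, t, self.medial_path[:, 1])
        return np.array([x, y])

    def medial_tangent(self, s: float) -> np.ndarray:
        t = self.medial_arclength()
        h = 5e-3
        a = max(0.0, s - h)
        b = min(1.0, s + h)
        pa = np.array([np.interp(a, t, self.medial_path[:, 0]),
                       np.interp(a, t, self.medial_path[:, 1])])
        pb = np.array([np.interp(b, t, self.medial_path[:, 0]),
                       np.interp(b, t, self.medial_path[:, 1])])
        d = pb - pa
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise GeometryError(f"degenerate medial tangent at s={s}")
        return d / n

    def site_at(self, s: float) -> str:
        for ann in self.sites:
            if ann.s_start <= s <= ann.s_end:
                return ann.label
        return NORMAL

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if len(self.outline) < 8:
            raise GeometryError("outline must have >= 8 points")
        ring = LinearRing(self.outline)
        if not ring.is_simple:
            raise DegeneracyError("outline is self-intersecting")
        if not ring.is_ccw:
            raise GeometryError("outline must be counter-clockwise")
        poly = Polygon(self.outline)
        if not poly.is_valid:
            raise DegeneracyError("outline polygon is invalid")
        if len(self.medial_path) < 2:
            raise GeometryError("medial path must have >= 2 points")
        interior = [Point(p) for p in self.medial_path]
        if not all(poly.contains(p) for p in interior):
            raise GeometryError("medial path must lie strictly inside outline")
        for end in (self.medial_path[0], self.medial_path[-1]):
            if ring.distance(Point(end)) > 1.0:
                raise GeometryError("medial path endpoints must be within 1 grid unit of outline")
        _check_site_overlap(self.sites)


def _check_site_overlap(sites) -> None:
    seen = set()
    for ann in sites:
        if ann.label != NORMAL:
            if ann.label in seen:
                raise AnnotationError(f"site {ann.label} annotated more than once")
            seen.add(ann.label)
    ordered = sorted(sites, key=lambda a: a.s_start)
    for a, b in zip(ordered, ordered[1:]):
        if b.s_start < a.s_end:
            raise AnnotationError(
                f"site intervals overlap: {a.label} [{a.s_start},{a.s_end}] "
                f"and {b.label} [{b.s_start},{b.s_end}]"
            )


# ---------------------------------------------------------------------------
# Synthetic anchor generation
# ---------------------------------------------------------------------------

_N_MEDIAL = 240  # samples along the medial curve


def _smoothstep(u: np.ndarray, a: float, b: float) -> np.ndarray:
    t = np.clip((u - a) / (b - a), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _gauss(u: np.ndarray, c: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((u - c) / sigma) ** 2)


def generate_synthetic_anchor(params: AnchorParams) -> Template2D:
    """Generate a hook-shaped anchor template from morphological parameters.

    The medial curve is integrated from piecewise-constant curvature
    segments (inner root, shaft, recurved point); the outline is the
    medial curve offset by a smoothly varying half-width on each side.
    The outer root appears as a one-sided bump centred in site IV's
    interval; the optional 'ear' is a one-sided lobe centred in site VI's
    interval.  Deterministic for a fixed seed (the seed drives ornament
    bump placement only).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    L_root = params.inner_root_length
    L_shaft = params.shaft_length
    L_point = params.point_length
    L = L_root + L_shaft + L_point

    u = np.linspace(0.0, 1.0, _N_MEDIAL)
    ds = L / (_N_MEDIAL - 1)
    arc = u * L

    # curvature (turn per unit length), negative = clockwise curl
    kappa = np.zeros(_N_MEDIAL)
    in_shaft = (arc >= L_root) & (arc < L_root + L_shaft)
    in_point = arc >= L_root + L_shaft
    kappa[in_shaft] = -params.shaft_curvature / L_shaft
    kappa[in_point] = -params.point_curl / L_point

    theta0 = -0.45 * math.pi  # inner root points down-and-right
    theta = theta0 + np.concatenate([[0.0], np.cumsum(kappa[:-1]) * ds])
    medial = np.zeros((_N_MEDIAL, 2))
    steps = np.stack([np.cos(theta[:-1]), np.sin(theta[:-1])], axis=1) * ds
    medial[1:] = np.cumsum(steps, axis=0)

    # half-width profile: broad at the root, tapering toward the tip
    W = params.inner_root_width / 2.0
    w = W * (1.0 - 0.55 * _smoothstep(u, 0.30, 0.85))
    w *= 1.0 - 0.55 * _smoothstep(u, 0.90, 1.0)  # sharpen at the point tip
    w_left = w.copy()
    w_right = w.copy()

    # outer root: protrusion on the outer (right) side within site IV;
    # more than one lobe gives a bifid (notched) outer root
    k = params.outer_root_lobes
    sigma_or = max(params.outer_root_width / L / k, 0.010)
    if params.outer_root_centers:
        centers = list(params.outer_root_centers)
    else:
        centers = np.linspace(0.345, 0.385, k) if k > 1 else [0.36]
    for c_or in centers:
        w_right += params.outer_root_length * _gauss(u, c_or, sigma_or)

    # optional 'ear' lobe on the left side within site VI
    if params.ear:
        w_left += params.ear_size * _gauss(u, 0.62, 0.030)

    # seeded ornament bumps (small, both sides)
    for _ in range(params.ornament_bumps):
        c = rng.uniform(0.10, 0.88)
        side = w_left if rng.random() < 0.5 else w_right
        side += params.ornament_amplitude * _gauss(u, c, 0.02)

    tang = np.gradient(medial, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)

    left = medial + normal * w_left[:, None]
    right = medial - normal * w_right[:, None]
    outline = np.vstack([left, right[::-1]])

    # enforce CCW
    if _signed_area(outline) < 0:
        outline = outline[::-1]

    # medial path trimmed slightly so endpoints are strictly interior
    t_lo, t_hi = 2, _N_MEDIAL - 3
    medial_path = medial[t_lo:t_hi + 1]

    name = f"synthetic-anchor-seed{params.seed}"
    tpl = Template2D(name=name, outline=outline, medial_path=medial_path,
                     grid_spacing=1.0, sites=tuple(DEFAULT_SITES))
    tpl.validate()
    return tpl


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def reference_template(seed: int = 0) -> Template2D:
    """The packaged generic-model template: a morphologically simple anchor
    (in the style of *Bivaginogyrus obscurus*, the simplest dactylogyridean
    anchor shape) with the seven-site annotation attached."""
    return generate_synthetic_anchor(AnchorParams(seed=seed))


def anchor_variants(n: int = 8, base_seed: int = 0) -> list[Template2D]:
    """Seeded family of anchor shape variants emulating across-species
    diversity: varying shaft curvature, point curl, root sizes, with the
    'ear' lobe present in some variants."""
    rng = np.random.default_rng(base_seed)
    out = []
    for i in range(n):
        p = AnchorParams(
            shaft_length=float(rng.uniform(8.5, 11.5)),
            shaft_curvature=float(rng.uniform(0.55, 1.05)),
            point_length=float(rng.uniform(4.2, 5.8)),
            point_curl=float(rng.uniform(1.55, 2.2)),
            inner_root_length=float(rng.uniform(4.2, 5.8)),
            inner_root_width=float(rng.uniform(1.9, 2.5)),
            outer_root_length=float(rng.uniform(1.6, 2.7)),
            outer_root_width=float(rng.uniform(1.3, 1.9)),
            ear=bool(i % 2),
            ear_size=float(rng.uniform(0.8, 1.4)),
            ornament_bumps=int(rng.integers(0, 3)),
            seed=base_seed * 1000 + i,
        )
        out.append(generate_synthetic_anchor(p))
    return out


# ---------------------------------------------------------------------------
# Template operations
# ---------------------------------------------------------------------------

def snap_to_grid(template: Template2D, spacing: float) -> Template2D:
    """Round every outline/medial coordinate to the nearest grid multiple.

    Raises :class:`DegeneracyError` if snapping makes the outline
    self-intersecting or collapses consecutive points.  Idempotent.
    """
    if spacing <= 0:
        raise ParameterError("spacing must be > 0")
    snap = lambda a: np.round(np.asarray(a) / spacing) * spacing
    outline = snap(template.outline)
    # drop consecutive duplicates created by coarse snapping
    keep = np.any(np.abs(np.diff(np.vstack([outline, outline[:1]]), axis=0)) > 1e-12, axis=1)
    outline = outline[keep]
    if len(outline) < 4:
        raise DegeneracyError("snapping collapsed the outline")
    ring = LinearRing(outline)
    if not ring.is_simple or not Polygon(outline).is_valid:
        raise DegeneracyError(
            f"snapping to spacing {spacing} makes the outline self-intersect")
    medial = snap(template.medial_path)
    keep_m = np.concatenate([[True], np.any(np.abs(np.diff(medial, axis=0)) > 1e-12, axis=1)])
    medial = medial[keep_m]
    if len(medial) < 2:
        raise DegeneracyError("snapping collapsed the medial path")
    if not ring.is_ccw:
        outline = outline[::-1]
    return replace(template, outline=outline, medial_path=medial)


def annotate_sites(template: Template2D, annotations) -> Template2D:
    """Attach site annotations; spans not covered are implicitly 'normal'."""
    anns = tuple(annotations)
    _check_site_overlap(anns)
    return replace(template, sites=anns)


@dataclass(frozen=True)
class Station:
    """One chord of point primitives across the anchor's local width."""

    s: float
    site: str
    points: np.ndarray  # (n_across, 2), ordered consistently across stations

    @property
    def n_across(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class StripLayout:
    """Ordered stations of in-plane point primitives along the medial path."""

    template: Template2D
    stations: tuple

    def total_points(self) -> int:
        return sum(st.n_across for st in self.stations)

    def site_points(self, label: str) -> int:
        return sum(st.n_across for st in self.stations if st.site == label)


def _station_chord(template: Template2D, s: float, ring: LinearRing,
                   diameter: float) -> tuple[np.ndarray, np.ndarray]:
    """Nearest outline crossing of the medial normal line on each side."""
    m = template.medial_point(s)
    t = template.medial_tangent(s)
    nrm = np.array([-t[1], t[0]])
    probe = LineString([m - nrm * diameter, m + nrm * diameter])
    inter = probe.intersection(ring)
    pts = []
    if inter.is_empty:
        pass
    elif inter.geom_type == "Point":
        pts = [inter]
    elif inter.geom_type == "MultiPoint":
        pts = list(inter.geoms)
    else:  # GeometryCollection / LineString overlaps
        for g in getattr(inter, "geoms", [inter]):
            if g.geom_type == "Point":
                pts.append(g)
            else:
                pts.extend(Point(c) for c in g.coords)
    offs = [float(np.dot(np.array([p.x, p.y]) - m, nrm)) for p in pts]
    pos = [(o, p) for o, p in zip(offs, pts) if o > 1e-9]
    neg = [(o, p) for o, p in zip(offs, pts) if o < -1e-9]
    if not pos or not neg:
        raise GeometryError(
            f"station normal line at s={s:.4f} does not cross the outline on both sides")
    _, p_pos = min(pos, key=lambda t: t[0])
    _, p_neg = max(neg, key=lambda t: t[0])
    return np.array([p_neg.x, p_neg.y]), np.array([p_pos.x, p_pos.y])


def _normal_span_positions(a: float, b: float, k: int) -> np.ndarray:
    """Station positions inside a normal span, including the template ends."""
    if a <= 1e-12 and b >= 1.0 - 1e-12:
        return np.linspace(a, b, k)
    if a <= 1e-12:
        return a + (b - a) * np.arange(k) / k
    if b >= 1.0 - 1e-12:
        return a + (b - a) * (np.arange(1, k + 1)) / k
    return a + (b - a) * (np.arange(k) + 0.5) / k


def layout_strip(template: Template2D, config: SiteConfig,
                 n_normal_stations: int = 12) -> StripLayout:
    """Lay out point-primitive stations along the medial path.

    A site with count ``c = n_along x n_across`` receives ``n_along``
    stations of ``n_across`` points spanning its interval; normal spans
    receive 2-point stations distributed proportionally to span length.
    Points at each station sit at equal fractions of the chord between
    the two outline crossings of the local medial normal.
    """
    if n_normal_stations < 2:
        raise ParameterError("n_normal_stations must be >= 2")
    template.validate()
    ring = LinearRing(template.outline)
    bb = template.outline
    diameter = float(np.hypot(*(bb.max(axis=0) - bb.min(axis=0)))) * 2.0

    sites = sorted((a for a in template.sites if a.label != NORMAL),
                   key=lambda a: a.s_start)
    # build ordered regions: (s0, s1, label or NORMAL)
    regions = []
    cursor = 0.0
    for ann in sites:
        if ann.s_start > cursor + 1e-12:
            regions.append((cursor, ann.s_start, NORMAL))
        regions.append((ann.s_start, ann.s_end, ann.label))
        cursor = ann.s_end
    if cursor < 1.0 - 1e-12:
        regions.append((cursor, 1.0, NORMAL))

    normal_spans = [(a, b) for a, b, lab in regions if lab == NORMAL]
    total_norm = sum(b - a for a, b in normal_spans)
    alloc = {}
    if normal_spans:
        raw = [(b - a) / total_norm * n_normal_stations for a, b in normal_spans]
        alloc = {i: max(1, int(round(r))) for i, r in enumerate(raw)}

    stations: list[Station] = []
    norm_i = 0
    for a, b, lab in regions:
        if lab == NORMAL:
            k = alloc[norm_i]
            norm_i += 1
            ss = _normal_span_positions(a, b, k)
            n_across = 2
        else:
            n_along, n_across = config.factorize(lab)
            ss = np.linspace(a, b, n_along)
        for s in ss:
            p_neg, p_pos = _station_chord(template, float(s), ring, diameter)
            fr = np.linspace(0.0, 1.0, n_across)[:, None]
            pts = p_neg[None, :] * (1 - fr) + p_pos[None, :] * fr
            stations.append(Station(s=float(s), site=lab, points=pts))

    stations.sort(key=lambda st: st.s)
    return StripLayout(template=template, stations=tuple(stations))


# ---------------------------------------------------------------------------
# Template file I/O (JSON)
# ---------------------------------------------------------------------------

def save_template(template: Template2D, path) -> None:
    doc = {
        "name": template.name,
        "grid_spacing": template.grid_spacing,
        "outline": [[float(x), float(y)] for x, y in template.outline],
        "medial_path": [[float(x), float(y)] for x, y in template.medial_path],
        "sites": [{"label": a.label, "s_start": a.s_start, "s_end": a.s_end}
                  for a in template.sites],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_template(path) -> Template2D:
    with open(path) as fh:
        doc = json.load(fh)
    tpl = Template2D(
        name=doc["name"],
        outline=np.asarray(doc["outline"], dtype=float),
        medial_path=np.asarray(doc["medial_path"], dtype=float),
        grid_spacing=float(doc.get("grid_spacing", 1.0)),
        sites=tuple(SiteAnnotation(d["label"], d["s_start"], d["s_end"])
                    for d in doc.get("sites", [])),
    )
    tpl.validate()
    return tpl
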