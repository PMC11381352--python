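"""Cell geometry primitives.

Bacterial cells are represented as closed polygons with two pole landmarks.
The synthetic generator produces ideal spherocylinders (a rectangle capped by
two semicircles, the standard rod-shape idealization for *B. subtilis*);
outlines segmented from real brightfield images can be loaded from JSON and
used interchangeably as long as the two pole positions are supplied.

Units are micrometres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon


@dataclass
class CellOutline:
    """A single cell's outline polygon plus pole landmarks.

    Attributes
    ----------
    cell_id : int
        Identifier, unique within a dataset.
    vertices : (N, 2) ndarray
        Closed simple polygon, μm.  The first vertex is not repeated.
    pole_a, pole_b : (2,) ndarray
        Positions of the two cell poles, μm.  `length` is their separation.
    length : float
        Pole-to-pole distance, μm.
    width : float
        Maximal width perpendicular to the pole axis, μm.
    """

    cell_id: int
    vertices: np.ndarray
    pole_a: np.ndarray
    pole_b: np.ndarray
    length: float
    width: float
    _polygon: Polygon | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.pole_a = np.asarray(self.pole_a, dtype=float)
        self.pole_b = np.asarray(self.pole_b, dtype=float)
        if self.width <= 0:
            raise ValueError("cell width must be positive")
        d = float(np.hypot(*(self.pole_b - self.pole_a)))
        if d == 0:
            raise ValueError("pole_a and pole_b must be distinct")
        if abs(d - self.length) > 1e-9:
            raise ValueError(
                f"length {self.length} inconsistent with pole separation {d}"
            )
        poly = self.polygon
        if not poly.is_valid or not poly.is_simple:
            raise ValueError("cell outline polygon must be simple")

    @property
    def polygon(self) -> Polygon:
        if self._polygon is None:
            self._polygon = Polygon(self.vertices)
        return self._polygon

    @property
    def axis_unit(self) -> np.ndarray:
        """Unit vector from pole_a to pole_b."""
        v = self.pole_b - self.pole_a
        return v / np.hypot(*v)

    def contains_xy(self, x, y) -> np.ndarray:
        """Vectorized point-in-cell test (boundary counts as inside)."""
        covered = shapely.intersects(self.polygon, shapely.points(x, y))
        return np.asarray(covered)

    def uv_to_xy(self, u, v) -> tuple[np.ndarray, np.ndarray]:
        """Map normalized (u along long axis in [0,1], v across in [0,1]) to μm."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        ax = self.axis_unit
        perp = np.array([-ax[1], ax[0]])
        x = self.pole_a[0] + u * self.length * ax[0] + (v - 0.5) * self.width * perp[0]
        y = self.pole_a[1] + u * self.length * ax[1] + (v - 0.5) * self.width * perp[1]
        return x, y


def spherocylinder(
    cell_id: int,
    length: float,
    width: float,
    center: tuple[float, float] = (0.0, 0.0),
    angle: float = 0.0,
    n_arc: int = 24,
) -> CellOutline:
    """Construct an ideal spherocylindrical cell outline.

    The shape is a rectangle of length ``length - width`` capped by two
    semicircles of radius ``width / 2``; the poles are the two cap apices so
    the pole separation equals ``length``.

    Parameters
    ----------
    length, width : float
        Overall pole-to-pole length and diameter, μm.  Requires
        ``length >= width``.
    center : (float, float)
        Midpoint between the poles, μm.
    angle : float
        Orientation of the long axis, radians (0 = aligned with x).
    n_arc : int
        Vertices per polar cap (>= 16 so the polygon has >= 32 vertices).
    """
    if length <= 0 or width <= 0:
        raise ValueError("cell dimensions must be positive")
    if length < width:
        raise ValueError("length must be at least the width (rod shape)")
    if n_arc < 16:
        raise ValueError("n_arc must be >= 16")
    r = width / 2.0
    h = length / 2.0 - r  # half-length of the cylindrical part
    # right cap: -90 deg -> +90 deg; left cap: +90 -> 270; an odd point count
    # per cap guarantees the apex vertex, so the poles lie on the polygon
    n_pts = n_arc + 1 if n_arc % 2 == 0 else n_arc
    th_r = np.linspace(-np.pi / 2, np.pi / 2, n_pts)
    th_l = np.linspace(np.pi / 2, 3 * np.pi / 2, n_pts)
    xs = np.concatenate([h + r * np.cos(th_r), -h + r * np.cos(th_l)])
    ys = np.concatenate([r * np.sin(th_r), r * np.sin(th_l)])
    verts = np.column_stack([xs, ys])
    poles = np.array([[-length / 2.0, 0.0], [length / 2.0, 0.0]])
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    verts = verts @ rot.T + np.asarray(center)
    poles = poles @ rot.T + np.asarray(center)
    return CellOutline(
        cell_id=cell_id,
        vertices=verts,
        pole_a=poles[0],
        pole_b=poles[1],
        length=float(length),
        width=float(width),
    )


def uniform_points_in_cell(
    cell: CellOutline, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample ``n`` points uniform over the cell polygon. (n, 2) μm."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = cell.polygon.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(2 * (n - got), 32)
        pts = rng.uniform([minx, miny], [maxx, maxy], size=(m, 2))
        ok = cell.contains_xy(pts[:, 0], pts[:, 1])
        pts = pts[ok]
        take = min(len(pts), n - got)
        out[got : got + take] = pts[:take]
        got += take
    return out


def reflect_step(
    cell: CellOutline, p: np.ndarray, q: np.ndarray, max_bounce: int = 8
) -> np.ndarray:
    """Propagate a Brownian step from inside point ``p`` toward ``q`` with
    specular reflection at the polygon boundary.

    Specular reflection preserves the uniform stationary distribution inside
    the cell, which the colocalization null (g(r) = 1 for uniform molecules)
    relies on.  If the bounce cascade does not resolve within ``max_bounce``
    reflections (pathological near-corner geometry), the particle is left at
    the last interior point.
    """
    poly = cell.polygon
    verts = np.asarray(poly.exterior.coords)  # closed ring
    a = verts[:-1]
    b = verts[1:]
    p = np.array(p, dtype=float)
    q = np.array(q, dtype=float)
    for _ in range(max_bounce):
        if poly.covers(Point(q)):
            return q
        d = q - p
        # first intersection of segment p->q with any boundary edge
        e = b - a
        denom = d[0] * e[:, 1] - d[1] * e[:, 0]
        w = a - p
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]) / denom
            s = (w[:, 0] * d[1] - w[:, 1] * d[0]) / denom
        hit = (denom != 0) & (t > 1e-12) & (t <= 1.0) & (s >= -1e-12) & (s <= 1 + 1e-12)
        if not np.any(hit):
            return p  # numerically grazing: stay put
        i = np.flatnonzero(hit)[np.argmin(t[hit])]
        ti = t[i]
        hit_pt = p + ti * d
        # reflect the remaining displacement across the edge direction
        edge = e[i] / np.hypot(*e[i])
        rem = (1.0 - ti) * d
        rem_ref = 2.0 * (rem @ edge) * edge - rem
        p = hit_pt + 1e-9 * (rem_ref / (np.hypot(*rem_ref) + 1e-300))
        q = hit_pt + rem_ref
    return p if poly.covers(Point(p)) else np.asarray(poly.representative_point().coords[0])
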