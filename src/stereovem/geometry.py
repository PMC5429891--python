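"""Analytic planar geometry for virtual sections.

All section profiles produced by plane/primitive intersection are convex and are
represented as intersections of linear (half-plane) and quadratic (ellipse)
constraints.  Working with implicit constraints keeps point-in-profile tests,
line chords and boundary-crossing counts exact (root finding on polynomials)
instead of relying on polygonal approximation.  Lengths are in micrometres
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

EPS = 1e-12


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < EPS:
        raise ValueError("zero-length vector cannot be normalised")
    return v / n


def plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic right-handed in-plane basis (e1, e2) for a unit normal."""
    n = unit(normal)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(n)))] = 1.0
    e1 = unit(np.cross(n, helper))
    e2 = np.cross(n, e1)
    return e1, e2


def rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = unit(axis)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


@dataclass(frozen=True)
class Plane:
    """Oriented plane {x . normal = offset} with a fixed in-plane frame."""

    normal: np.ndarray
    offset: float
    e1: np.ndarray = None
    e2: np.ndarray = None

    def __post_init__(self):
        object.__setattr__(self, "normal", unit(self.normal))
        if self.e1 is None or self.e2 is None:
            e1, e2 = plane_basis(self.normal)
            object.__setattr__(self, "e1", e1)
            object.__setattr__(self, "e2", e2)

    @property
    def origin(self) -> np.ndarray:
        return self.offset * self.normal

    def to_plane(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float)) - self.origin
        return np.stack([pts @ self.e1, pts @ self.e2], axis=-1)

    def to_world(self, pts2: np.ndarray) -> np.ndarray:
        pts2 = np.atleast_2d(np.asarray(pts2, dtype=float))
        return self.origin + np.outer(pts2[:, 0], self.e1) + np.outer(pts2[:, 1], self.e2)


# ---------------------------------------------------------------------------
# implicit constraints
# ---------------------------------------------------------------------------


class LinearConstraint:
    """Half plane  a . x - b <= 0  with |a| = 1."""

    def __init__(self, a, b):
        self.a = unit(np.asarray(a, dtype=float))
        self.b = float(b)

    def g(self, pts):
        pts = np.atleast_2d(pts)
        return pts @ self.a - self.b

    def line_roots(self, p, d):
        den = float(np.dot(self.a, d))
        if abs(den) < EPS:
            return []
        return [(self.b - float(np.dot(self.a, p))) / den]

    def line_interval(self, p, d):
        den = float(np.dot(self.a, d))
        num = self.b - float(np.dot(self.a, p))
        if abs(den) < EPS:
            return (-np.inf, np.inf) if num >= 0 else None
        t = num / den
        return (t, np.inf) if den < 0 else (-np.inf, t)


class QuadraticConstraint:
    """Ellipse interior  (x-c)^T Q (x-c) - 1 <= 0  (Q symmetric pos. def.)."""

    def __init__(self, center, Q):
        self.c = np.asarray(center, dtype=float)
        self.Q = np.asarray(Q, dtype=float)

    def g(self, pts):
        y = np.atleast_2d(pts) - self.c
        return np.einsum("ni,ij,nj->n", y, self.Q, y) - 1.0

    def _coefs(self, p, d):
        y = np.asarray(p, dtype=float) - self.c
        d = np.asarray(d, dtype=float)
        A = float(d @ self.Q @ d)
        B = 2.0 * float(y @ self.Q @ d)
        C = float(y @ self.Q @ y) - 1.0
        return A, B, C

    # tangencies (root separation below ~1e-9 um) count as misses: the tie
    # rule demands a strict sign change, and float fuzz at grazing contacts
    # must not fabricate crossings
    _TANGENT_TOL = 1e-6

    def line_roots(self, p, d):
        A, B, C = self._coefs(p, d)
        if A < EPS:
            return []
        disc = B * B - 4 * A * C
        if disc <= 0:
            return []
        s = np.sqrt(disc)
        if s / A < self._TANGENT_TOL:
            return []
        return [(-B - s) / (2 * A), (-B + s) / (2 * A)]

    def line_interval(self, p, d):
        A, B, C = self._coefs(p, d)
        if A < EPS:
            return (-np.inf, np.inf) if C <= 0 else None
        disc = B * B - 4 * A * C
        if disc <= 0:
            return None
        s = np.sqrt(disc)
        if s / A < self._TANGENT_TOL:
            return None
        return ((-B - s) / (2 * A), (-B + s) / (2 * A))


def _intersect_intervals(iv1, iv2):
    if iv1 is None or iv2 is None:
        return None
    lo, hi = max(iv1[0], iv2[0]), min(iv1[1], iv2[1])
    return (lo, hi) if lo < hi else None


# ---------------------------------------------------------------------------
# convex profiles
# ---------------------------------------------------------------------------


@dataclass
class ConvexProfile:
    """A convex section profile: intersection of implicit constraints.

    ``membrane`` marks the constraints whose boundary represents membrane
    surface for intersection counting (e.g. the two faces of a cisternal plate
    when the rim is excluded from the surface model).
    """

    label: str
    parent_id: int
    constraints: list
    membrane: list
    area: float
    apparent_width: Optional[float] = None
    trace_length: Optional[float] = None
    centroid: Optional[np.ndarray] = None
    _boundary: Optional[np.ndarray] = field(default=None, repr=False)

    # -- point queries -----------------------------------------------------
    def contains(self, pts) -> np.ndarray:
        """Strict-interior membership (boundary points do not count)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        ok = np.ones(len(pts), dtype=bool)
        for c in self.constraints:
            ok &= c.g(pts) < 0.0
        return ok

    # -- line queries ------------------------------------------------------
    def line_interval(self, p, d):
        """Parameter interval of {p + t d} inside the profile, or None."""
        iv = (-np.inf, np.inf)
        for c in self.constraints:
            iv = _intersect_intervals(iv, c.line_interval(p, d))
            if iv is None:
                return None
        return iv

    def line_crossings(self, p, d, tmin=-np.inf, tmax=np.inf, membrane_only=True):
        """Parameters where the line transversally crosses the boundary.

        A crossing requires a strict sign change of one constraint while all
        other constraints are satisfied (tangencies count zero).
        """
        out = []
        for i, c in enumerate(self.constraints):
            if membrane_only and not self.membrane[i]:
                continue
            for t in c.line_roots(p, d):
                if not (tmin < t < tmax):
                    continue
                x = np.asarray(p) + t * np.asarray(d)
                ok = True
                for j, other in enumerate(self.constraints):
                    if j == i:
                        continue
                    if float(other.g(x[None, :])[0]) > -1e-9:
                        ok = False
                        break
                if ok:
                    out.append(t)
        return sorted(out)

    def curve_crossings(self, pts, membrane_only=True) -> int:
        """Count transversal crossings of a polyline (e.g. a cycloid arc)."""
        pts = np.asarray(pts, dtype=float)
        total = 0
        gs = [c.g(pts) for c in self.constraints]
        for i, c in enumerate(self.constraints):
            if membrane_only and not self.membrane[i]:
                continue
            gi = gs[i]
            flips = np.nonzero(np.sign(gi[:-1]) * np.sign(gi[1:]) < 0)[0]
            for k in flips:
                # linear interpolation of the crossing point within the segment
                w = gi[k] / (gi[k] - gi[k + 1])
                x = pts[k] + w * (pts[k + 1] - pts[k])
                if all(
                    float(self.constraints[j].g(x[None, :])[0]) < 1e-9
                    for j in range(len(self.constraints))
                    if j != i
                ):
                    total += 1
        return total

    # -- derived geometry --------------------------------------------------
    def boundary_polyline(self, n=256) -> np.ndarray:
        """Dense closed polyline on the boundary (radial casting, convex)."""
        if self._boundary is not None and len(self._boundary) >= n:
            return self._boundary
        c = self.centroid if self.centroid is not None else self._interior_point()
        ang = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        pts = np.empty((n, 2))
        for k, a in enumerate(ang):
            d = np.array([np.cos(a), np.sin(a)])
            iv = self.line_interval(c, d)
            t = iv[1] if iv is not None and np.isfinite(iv[1]) else 0.0
            pts[k] = c + t * d
        self._boundary = pts
        return pts

    def _interior_point(self) -> np.ndarray:
        for c in self.constraints:
            if isinstance(c, QuadraticConstraint):
                return c.c.copy()
        # average of half-plane foot points as a fallback
        return np.mean([c.a * c.b for c in self.constraints], axis=0)

    @property
    def boundary_length(self) -> float:
        pts = self.boundary_polyline()
        closed = np.vstack([pts, pts[:1]])
        return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        pts = self.boundary_polyline(128)
        return (
            float(pts[:, 0].min()),
            float(pts[:, 0].max()),
            float(pts[:, 1].min()),
            float(pts[:, 1].max()),
        )

    @property
    def min_dimension(self) -> float:
        if self.apparent_width is not None:
            return float(self.apparent_width)
        x0, x1, y0, y1 = self.bbox
        return float(min(x1 - x0, y1 - y0))


# ---------------------------------------------------------------------------
# profile factories
# ---------------------------------------------------------------------------


def circle_profile(label, parent_id, center, r) -> ConvexProfile:
    r = float(r)
    q = QuadraticConstraint(center, np.eye(2) / max(r, EPS) ** 2)
    prof = ConvexProfile(
        label=label,
        parent_id=parent_id,
        constraints=[q],
        membrane=[True],
        area=np.pi * r * r,
        centroid=np.asarray(center, dtype=float),
    )
    prof.radius = r
    return prof


def ellipse_profile(label, parent_id, center, B) -> ConvexProfile:
    """Ellipse = image of the unit disc under the 2x2 map ``B``."""
    B = np.asarray(B, dtype=float)
    Q = np.linalg.inv(B @ B.T)
    prof = ConvexProfile(
        label=label,
        parent_id=parent_id,
        constraints=[QuadraticConstraint(center, Q)],
        membrane=[True],
        area=float(np.pi * abs(np.linalg.det(B))),
        centroid=np.asarray(center, dtype=float),
    )
    prof.semiaxes = tuple(sorted(np.linalg.svd(B, compute_uv=False), reverse=True))
    return prof


def polygon_profile(label, parent_id, vertices) -> ConvexProfile:
    """Convex polygon given by counter-clockwise vertices (exact shoelace area)."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    area2 = float(np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1]))
    if area2 < 0:  # enforce CCW
        v = v[::-1]
        area2 = -area2
    cons = []
    for i in range(len(v)):
        p, qv = v[i], v[(i + 1) % len(v)]
        edge = qv - p
        n_out = np.array([edge[1], -edge[0]])  # outward for CCW
        cons.append(LinearConstraint(n_out, float(np.dot(unit(n_out), p))))
    return ConvexProfile(
        label=label,
        parent_id=parent_id,
        constraints=cons,
        membrane=[True] * len(cons),
        area=0.5 * area2,
        centroid=v.mean(axis=0),
    )


def circle_strip_area(R: float, w1: float, w2: float) -> float:
    """Area of {x^2 + y^2 <= R^2, w1 <= y <= w2} (closed form)."""
    w1 = float(np.clip(w1, -R, R))
    w2 = float(np.clip(w2, -R, R))
    if w2 <= w1:
        return 0.0

    def F(w):
        return w * np.sqrt(max(R * R - w * w, 0.0)) + R * R * np.arcsin(np.clip(w / R, -1, 1))

    return F(w2) - F(w1)


def band_ellipse_profile(
    label,
    parent_id,
    center,
    w_dir,
    cgamma,
    sgamma,
    R,
    H,
    D,
    membrane_faces_only,
) -> ConvexProfile:
    """Section of a finite cylinder (radius R, half-length H) by a tilted plane.

    ``center`` is the in-plane position of the projected cylinder centre,
    ``w_dir`` the in-plane direction of the projected axis, ``cgamma``/``sgamma``
    the cosine/sine of the angle between the plane normal and the cylinder
    axis, and ``D`` the signed distance of the cylinder centre from the plane.
    In coordinates (w, q) along/across the projected axis the region is
    {q^2 + (cgamma*w + sgamma*D)^2 <= R^2, |sgamma*w - D*cgamma| <= H}.
    """
    w_dir = unit(np.asarray(w_dir, dtype=float))
    q_dir = np.array([-w_dir[1], w_dir[0]])
    center = np.asarray(center, dtype=float)

    cons: list = []
    membrane: list = []

    # band (the two plate faces); w is measured from ``center`` along w_dir
    if sgamma > EPS:
        for sgn in (+1.0, -1.0):
            # sgn*(sgamma*w - D*cgamma) <= H  ->  (sgn) * w <= (H + sgn*D*cgamma)/sgamma
            a = sgn * w_dir
            b = (H + sgn * D * cgamma) / sgamma + float(np.dot(a, center))
            cons.append(LinearConstraint(a, b))
            membrane.append(True)
    width = 2 * H / sgamma if sgamma > EPS else np.inf

    # radial constraint
    if cgamma > EPS:
        # circle of radius R in (q, W) with W = cgamma*w + sgamma*D
        w0 = -sgamma * D / cgamma
        c2 = center + w0 * w_dir
        M = np.outer(q_dir, q_dir) + cgamma ** 2 * np.outer(w_dir, w_dir)
        cons.append(QuadraticConstraint(c2, M / R ** 2))
        membrane.append(not membrane_faces_only)
        # area: circle strip in W over the band, divided by cgamma
        if sgamma > EPS:
            W1 = (D - cgamma * H) / sgamma
            W2 = (D + cgamma * H) / sgamma
            area = circle_strip_area(R, min(W1, W2), max(W1, W2)) / cgamma
        else:
            area = np.pi * R * R / cgamma  # full ellipse (plane crosses inside slab)
    else:
        # plane parallel to the axis: rectangle of half-width sqrt(R^2 - D^2)
        half_q = np.sqrt(max(R * R - D * D, 0.0))
        for sgn in (+1.0, -1.0):
            cons.append(LinearConstraint(sgn * q_dir, half_q + sgn * float(np.dot(q_dir, center))))
            membrane.append(not membrane_faces_only)
        area = width * 2 * half_q if np.isfinite(width) else 0.0

    # exact chord of the cylinder mid-plane trace (profile "length")
    trace = None
    if sgamma > EPS:
        d_line = abs(D) / sgamma
        if d_line < R:
            trace = 2.0 * np.sqrt(R * R - d_line * d_line)
        else:
            trace = 0.0

    # interior point: midpoint of the feasible w-interval at q = q(center)
    if sgamma > EPS:
        wb = ((D * cgamma - H) / sgamma, (D * cgamma + H) / sgamma)
        if cgamma > EPS:
            we = ((-R - sgamma * D) / cgamma, (R - sgamma * D) / cgamma)
            lo, hi = max(wb[0], we[0]), min(wb[1], we[1])
        else:
            lo, hi = wb
        centroid = center + 0.5 * (lo + hi) * w_dir
    else:
        centroid = center.copy()

    prof = ConvexProfile(
        label=label,
        parent_id=parent_id,
        constraints=cons,
        membrane=membrane,
        area=float(max(area, 0.0)),
        apparent_width=float(width) if np.isfinite(width) else None,
        trace_length=trace,
        centroid=centroid,
    )
    prof.axis_dir = w_dir  # in-plane direction of the projected cylinder axis
    prof.ortho_dir = q_dir
    return prof
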