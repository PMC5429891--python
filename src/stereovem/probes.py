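"""Geometric test systems and counting rules.

Probes follow systematic uniform random (SUR) placement: a regular layout with
one uniform random phase (and, where isotropy is needed, a random rotation).
Counting obeys deterministic tie rules: a test point exactly on a profile
boundary does not count, and an intersection requires a strict sign change of
the profile's implicit function along the test line or arc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .phantom import as_rng
from .sectioning import SectionImage

__all__ = [
    "TestSystem",
    "CountRecord",
    "CountingFrame",
    "GuardAreaError",
    "make_test_system",
    "count_points",
    "count_intersections",
    "apply_counting_frame",
    "count_disector",
    "count_orthogonal_cisternae",
    "measure_point_sampled_intercepts",
    "sur_pairs",
]


@dataclass
class CountRecord:
    """Per-image, per-label probe tallies."""

    image_id: int
    label: str
    P: int = 0  # point hits
    I: int = 0  # line/arc - boundary intersections
    Qminus: int = 0  # disappearing profiles (disector)
    ortho_counts: list = field(default_factory=list)
    intercepts: list = field(default_factory=list)  # point-sampled l0 (um)

    def __post_init__(self):
        if self.P < 0 or self.I < 0 or self.Qminus < 0:
            raise ValueError("tallies must be non-negative")


@dataclass
class CountingFrame:
    """Unbiased counting frame with a forbidden line and guard margin.

    The forbidden line is the left edge plus its infinite upward extension,
    the bottom edge, and the infinite downward extension below the
    bottom-right corner; profiles touching it are rejected, all others
    intersecting the frame are accepted (tiling-exact selection).
    """

    x0: float
    y0: float
    width: float
    height: float
    guard: float = 0.0

    @property
    def x1(self):
        return self.x0 + self.width

    @property
    def y1(self):
        return self.y0 + self.height

    @property
    def area(self):
        return self.width * self.height

    def contains_points(self, pts) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return (
            (pts[:, 0] >= self.x0) & (pts[:, 0] < self.x1)
            & (pts[:, 1] >= self.y0) & (pts[:, 1] < self.y1)
        )


class GuardAreaError(RuntimeError):
    """A profile at the image edge cannot be identified reliably."""


@dataclass
class TestSystem:
    __test__ = False  # "test" as in stereological test system, not pytest

    kind: str  # point_grid | line_grid | cycloid_array | counting_frame
    d: float = 0.1  # grid spacing (um)
    r: float = 0.05  # cycloid scale (um)
    theta: float = 0.0  # rotation of the layout
    phase: np.ndarray = None  # uniform random phase within one period
    frame: Optional[CountingFrame] = None
    arc_points: int = 96

    def __post_init__(self):
        if self.phase is None:
            self.phase = np.zeros(2)
        self.phase = np.asarray(self.phase, dtype=float)

    # -- constants ---------------------------------------------------------
    @property
    def a(self) -> float:
        """Area per test point (um^2)."""
        if self.kind == "cycloid_array":
            return np.pi * self.r * 4 * self.r  # one arc (and point) per cell
        return self.d ** 2

    @property
    def l_p(self) -> float:
        """Test-line length per associated point (um)."""
        if self.kind == "cycloid_array":
            return 4.0 * self.r  # exact half-arch length
        return self.d

    # -- layout generation ---------------------------------------------------
    def _rot(self):
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    def points(self, fov) -> np.ndarray:
        """Lattice of test points covering the field of view."""
        if self.kind == "cycloid_array":
            return np.array([o for o, _ in self._arcs_raw(fov)])
        x0, x1, y0, y1 = fov
        R = self._rot()
        corners = np.array([[x0, y0], [x1, y0], [x0, y1], [x1, y1]]) @ R  # R^-1 = R^T applied as right-mult
        u0, u1 = corners[:, 0].min(), corners[:, 0].max()
        v0, v1 = corners[:, 1].min(), corners[:, 1].max()
        iu = np.arange(np.floor((u0 - self.phase[0]) / self.d) - 1,
                       np.ceil((u1 - self.phase[0]) / self.d) + 2)
        iv = np.arange(np.floor((v0 - self.phase[1]) / self.d) - 1,
                       np.ceil((v1 - self.phase[1]) / self.d) + 2)
        U, V = np.meshgrid(self.phase[0] + iu * self.d, self.phase[1] + iv * self.d)
        pts = np.column_stack([U.ravel(), V.ravel()]) @ R.T
        keep = (pts[:, 0] >= x0) & (pts[:, 0] <= x1) & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
        return pts[keep]

    def lines(self, fov) -> list[tuple[np.ndarray, np.ndarray, float, float]]:
        """Parallel test lines as (point, direction, t0, t1) clipped to the fov."""
        if self.kind not in ("line_grid", "point_grid"):
            raise ValueError("lines() requires a line or point grid")
        x0, x1, y0, y1 = fov
        m = np.array([np.cos(self.theta), np.sin(self.theta)])
        p_hat = np.array([-m[1], m[0]])
        corners = np.array([[x0, y0], [x1, y0], [x0, y1], [x1, y1]])
        s = corners @ p_hat
        t = corners @ m
        js = np.arange(np.floor((s.min() - self.phase[0]) / self.d) - 1,
                       np.ceil((s.max() - self.phase[0]) / self.d) + 2)
        out = []
        for j in js:
            origin = (self.phase[0] + j * self.d) * p_hat
            out.append((origin, m, float(t.min()), float(t.max())))
        return out

    def _arcs_raw(self, fov, vertical=None):
        """Cycloid half-arches tiling the fov: list of (origin, mirror)."""
        v2 = np.array([0.0, 1.0]) if vertical is None else np.asarray(vertical, float)
        v2 = v2 / np.linalg.norm(v2)
        h2 = np.array([v2[1], -v2[0]])
        cw, ch = np.pi * self.r, 4.0 * self.r
        x0, x1, y0, y1 = fov
        corners = np.array([[x0, y0], [x1, y0], [x0, y1], [x1, y1]])
        hs, vs = corners @ h2, corners @ v2
        iu = np.arange(np.floor((hs.min() - self.phase[0]) / cw) - 1,
                       np.ceil((hs.max() - self.phase[0]) / cw) + 2)
        iv = np.arange(np.floor((vs.min() - self.phase[1]) / ch) - 1,
                       np.ceil((vs.max() - self.phase[1]) / ch) + 2)
        out = []
        for i in iu:
            mirror = int(i) % 2 == 1  # alternate columns mirrored
            for j in iv:
                origin = (self.phase[0] + i * cw) * h2 + (self.phase[1] + j * ch) * v2
                out.append((origin, mirror))
        return out

    def arcs(self, fov, vertical=None) -> list[np.ndarray]:
        """Cycloid arc polylines (minor axis along the vertical direction)."""
        if self.kind != "cycloid_array":
            raise ValueError("arcs() requires a cycloid array")
        v2 = np.array([0.0, 1.0]) if vertical is None else np.asarray(vertical, float)
        v2 = v2 / np.linalg.norm(v2)
        h2 = np.array([v2[1], -v2[0]])
        th = np.linspace(0.0, np.pi, self.arc_points)
        xa = self.r * (th - np.sin(th))  # horizontal extent pi*r
        ya = self.r * (1.0 - np.cos(th))  # vertical (minor) extent 2r
        x0, x1, y0, y1 = fov
        out = []
        for origin, mirror in self._arcs_raw(fov, vertical):
            # mirrored arcs flip within their own cell to keep coverage uniform
            xs = (np.pi * self.r - xa) if mirror else xa
            pts = origin + np.outer(xs, h2) + np.outer(ya, v2)
            if pts[:, 0].max() < x0 or pts[:, 0].min() > x1 or \
               pts[:, 1].max() < y0 or pts[:, 1].min() > y1:
                continue
            out.append(pts)
        return out


def make_test_system(kind: str, params: Optional[dict] = None, seed=None) -> TestSystem:
    """SUR-placed test system with a uniform random phase.

    For line grids on IUR sections pass ``params={"iur_rotation": True}`` to
    randomise the in-plane rotation as well (required for isotropy of the
    line field in 3D).
    """
    params = dict(params or {})
    rng = as_rng(seed)
    d = float(params.get("d", 0.1))
    r = float(params.get("r", 0.05))
    if kind not in ("point_grid", "line_grid", "cycloid_array", "counting_frame"):
        raise ValueError(f"unknown test system kind {kind!r}")
    if d <= 0 or r <= 0:
        raise ValueError("grid spacing and cycloid scale must be positive")
    theta = float(params.get("theta", 0.0))
    if params.get("iur_rotation"):
        theta = rng.uniform(0.0, np.pi)
    period = (np.pi * r, 4 * r) if kind == "cycloid_array" else (d, d)
    phase = np.array([rng.uniform(0, period[0]), rng.uniform(0, period[1])])
    frame = params.get("frame")
    return TestSystem(kind=kind, d=d, r=r, theta=theta, phase=phase, frame=frame,
                      arc_points=int(params.get("arc_points", 96)))


# ---------------------------------------------------------------------------
# counting operations
# ---------------------------------------------------------------------------


def _labels(image: SectionImage, labels) -> list[str]:
    if labels is not None:
        return list(labels)
    seen = []
    for p in image.profiles:
        if p.label not in seen:
            seen.append(p.label)
    return seen


def count_points(image: SectionImage, system: TestSystem, labels=None,
                 frame: Optional[CountingFrame] = None) -> list[CountRecord]:
    """Point hits per label: grid points strictly inside any profile of the label."""
    pts = system.points(image.fov)
    if frame is not None:
        pts = pts[frame.contains_points(pts)]
    records = []
    for lab in _labels(image, labels):
        if len(pts) == 0:
            records.append(CountRecord(image.image_id, lab, P=0))
            continue
        inside = np.zeros(len(pts), dtype=bool)
        for prof in image.by_label(lab):
            inside |= prof.contains(pts)
        records.append(CountRecord(image.image_id, lab, P=int(inside.sum())))
    return records


def count_intersections(image: SectionImage, system: TestSystem, labels=None) -> list[CountRecord]:
    """Transversal crossings between test lines/arcs and membrane boundaries.

    Tangencies count zero.  For plate profiles whose surface model excludes
    the rim, only crossings of the two face edges are counted, consistent
    with the ground-truth surface.
    """
    records = []
    use_arcs = system.kind == "cycloid_array"
    if use_arcs and image.vertical is None:
        raise ValueError("cycloid arrays require a vertical-section image "
                         "(no vertical axis is defined here)")
    arcs = system.arcs(image.fov, image.vertical) if use_arcs else None
    lines = None if use_arcs else system.lines(image.fov)
    for lab in _labels(image, labels):
        total = 0
        for prof in image.by_label(lab):
            if use_arcs:
                for arc in arcs:
                    total += prof.curve_crossings(arc)
            else:
                for p, m, t0, t1 in lines:
                    total += len(prof.line_crossings(p, m, t0, t1))
        records.append(CountRecord(image.image_id, lab, I=total))
    return records


def _touches_forbidden(prof, frame: CountingFrame) -> bool:
    big = 1e9
    pieces = [
        (np.array([frame.x0, frame.y0]), np.array([0.0, 1.0]), 0.0, big),  # left + up ext
        (np.array([frame.x0, frame.y0]), np.array([1.0, 0.0]), 0.0, frame.width),  # bottom
        (np.array([frame.x1, frame.y0]), np.array([0.0, -1.0]), 0.0, big),  # down ext
    ]
    for p, d, t0, t1 in pieces:
        iv = prof.line_interval(p, d)
        if iv is None:
            continue
        lo, hi = max(iv[0], t0), min(iv[1], t1)
        if hi - lo > 1e-12:
            return True
    return False


def _intersects_rect(prof, frame: CountingFrame) -> bool:
    bx0, bx1, by0, by1 = prof.bbox
    if bx1 < frame.x0 or bx0 > frame.x1 or by1 < frame.y0 or by0 > frame.y1:
        return False
    if prof.centroid is not None and frame.contains_points(prof.centroid[None, :])[0]:
        return True
    corners = np.array([[frame.x0, frame.y0], [frame.x1, frame.y0],
                        [frame.x1, frame.y1], [frame.x0, frame.y1]])
    if prof.contains(corners).any():
        return True
    edges = [
        (corners[0], np.array([1.0, 0.0]), frame.width),
        (corners[1], np.array([0.0, 1.0]), frame.height),
        (corners[3], np.array([1.0, 0.0]), frame.width),
        (corners[0], np.array([0.0, 1.0]), frame.height),
    ]
    for p, d, tmax in edges:
        iv = prof.line_interval(p, d)
        if iv is not None and min(iv[1], tmax) - max(iv[0], 0.0) > 1e-12:
            return True
    return False


def apply_counting_frame(profiles, frame: CountingFrame, fov=None) -> list:
    """Unbiased frame selection (Gundersen rule).

    Keeps profiles intersecting the frame that do not touch the forbidden
    line.  If a field of view is given, a selected profile extending beyond
    it (into unknown territory past the guard area) raises
    :class:`GuardAreaError`, since its identity cannot be established.
    """
    if fov is not None:
        x0, x1, y0, y1 = fov
        if (frame.x0 - frame.guard < x0 or frame.x1 + frame.guard > x1
                or frame.y0 - frame.guard < y0 or frame.y1 + frame.guard > y1):
            raise GuardAreaError("counting frame plus guard margin exceeds the image")
    selected = []
    for prof in profiles:
        if not _intersects_rect(prof, frame):
            continue
        if _touches_forbidden(prof, frame):
            continue
        if fov is not None:
            bx0, bx1, by0, by1 = prof.bbox
            if bx0 < fov[0] or bx1 > fov[1] or by0 < fov[2] or by1 > fov[3]:
                raise GuardAreaError(
                    f"profile of {prof.label!r} extends beyond the image edge"
                )
        selected.append(prof)
    return selected


def count_disector(sampling_image: SectionImage, lookup_image: SectionImage,
                   frame: Optional[CountingFrame] = None, labels=None) -> list[CountRecord]:
    """Q- counts: frame-selected profiles whose parent vanishes in the lookup.

    For whole-organelle stacks the frame may be None (no guard area needed);
    all sampling profiles are then eligible.
    """
    if not np.allclose(sampling_image.spec.normal, lookup_image.spec.normal):
        raise ValueError("disector sections must share one normal")
    h = abs(lookup_image.spec.offset - sampling_image.spec.offset)
    if h <= 0:
        raise ValueError("disector separation h must be positive")
    records = []
    for lab in _labels(sampling_image, labels):
        profs = sampling_image.by_label(lab)
        if frame is not None:
            profs = apply_counting_frame(profs, frame)
        lookup_parents = {p.parent_id for p in lookup_image.by_label(lab)}
        q = sum(1 for p in profs if p.parent_id not in lookup_parents)
        records.append(CountRecord(sampling_image.image_id, lab, Qminus=q))
    return records


def count_orthogonal_cisternae(image: SectionImage, system: TestSystem,
                               label: str = "cisterna") -> CountRecord:
    """Stack-composition probe: cisternae crossed orthogonally at face hits.

    Test-line hits on the stack's envelope face (the largest cisterna profile,
    whose faces proxy the ribbon face) are located; at each hit the number of
    cisterna profiles crossed along the in-plane stack axis is recorded.
    """
    profs = image.by_label(label)
    if not profs:
        return CountRecord(image.image_id, label)
    envelope = max(profs, key=lambda p: (p.trace_length or 0.0, p.area))
    if not hasattr(envelope, "axis_dir"):
        raise ValueError("orthogonal direction undefined for this profile")
    ortho = envelope.axis_dir  # in-plane projection of the stack axis
    counts = []
    for p, m, t0, t1 in system.lines(image.fov):
        for t in envelope.line_crossings(p, m, t0, t1, membrane_only=True):
            x = p + t * m
            c = 0
            for prof in profs:
                iv = prof.line_interval(x, ortho)
                if iv is not None and iv[1] - iv[0] > 1e-12:
                    c += 1
            counts.append(c)
    return CountRecord(image.image_id, label, ortho_counts=counts)


def measure_point_sampled_intercepts(
    image: SectionImage,
    system: TestSystem,
    label: str = "cisterna",
    mode: str = "analytic",
    seed=None,
    reprobe_spacing: Optional[float] = None,
) -> CountRecord:
    """Point-sampled intercept lengths l0 for star-area estimation.

    Each transversal pass of a test line across the profile trace records one
    intercept (the length of the full sectioned profile), so profiles are
    sampled with probability proportional to their trace length.  In analytic
    mode the exact mid-plane chord is used; otherwise the profile is re-probed
    with an independently randomised grid and l0 = (pi/2) * I * d (Buffon
    length estimator).
    """
    rng = as_rng(seed)
    intercepts = []
    lines = system.lines(image.fov)
    for prof in image.by_label(label):
        hits = 0
        for p, m, t0, t1 in lines:
            # one hit per transversal pass = half the boundary crossings
            hits += len(prof.line_crossings(p, m, t0, t1, membrane_only=True)) // 2
        if hits == 0:
            continue
        if mode == "analytic":
            l0 = prof.trace_length if prof.trace_length is not None else prof.boundary_length
        else:
            dre = reprobe_spacing or system.d
            re_sys = make_test_system("line_grid", {"d": dre, "iur_rotation": True}, rng)
            closed = prof.trace_length is None
            crossings = 0
            bx0, bx1, by0, by1 = prof.bbox
            pad = 2 * dre
            sub_fov = (bx0 - pad, bx1 + pad, by0 - pad, by1 + pad)
            for p, m, t0, t1 in re_sys.lines(sub_fov):
                nc = len(prof.line_crossings(p, m, t0, t1, membrane_only=False))
                # closed profiles: the trace is the boundary itself; open
                # (band) profiles: one mid-line crossing per boundary pair
                crossings += nc if closed else nc // 2
            l0 = (np.pi / 2.0) * crossings * dre
        intercepts.extend([float(l0)] * hits)
    return CountRecord(image.image_id, label, intercepts=intercepts)


def sur_pairs(n_sections: int, spacing: int, seed=None, gap: int = 1) -> list[tuple[int, int]]:
    """SUR-placed disector pairs (i, i+gap) every ``spacing`` sections."""
    if spacing < 1:
        raise ValueError("pair spacing must be >= 1")
    rng = as_rng(seed)
    start = int(rng.integers(0, spacing))
    return [(i, i + gap) for i in range(start, n_sections - gap, spacing)]
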