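"""Virtual sectioning of phantom scenes.

Sections are ideal planes (``h_phys = 0``) or slabs with a physical thickness
and an imaging depth.  The slab convention is half-open: the section at offset
``o`` covers [o, o + h_phys) along the stack normal, and imaging sees the
surface layer [o, o + h_img) at full opacity (blind below it).  Coordinates
are continuous micrometres, right handed; stack sections are indexed 0-based
from the random start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import ConvexProfile, Plane, circle_profile, plane_basis, rotation_about, unit
from .phantom import Scene, Sphere, as_rng

__all__ = [
    "SectionSpec",
    "SectionStack",
    "SectionImage",
    "sample_iur_orientation",
    "make_sur_stack",
    "make_vertical_section",
    "intersect",
    "project_slab",
    "ministack_projection",
    "rasterize",
]


@dataclass
class SectionSpec:
    """One virtual section: plane + thickness/imaging-depth provenance."""

    normal: np.ndarray
    offset: float
    h_phys: float = 0.0
    h_img: float = 0.0
    pixel_size: Optional[float] = None
    vertical: Optional[np.ndarray] = None  # in-plane 2D unit vector, VS mode

    def __post_init__(self):
        self.normal = unit(self.normal)
        if not (0.0 <= self.h_img <= self.h_phys or self.h_phys == 0.0):
            raise ValueError("require 0 <= h_img <= h_phys")
        if self.h_phys < 0:
            raise ValueError("h_phys must be non-negative")

    def plane(self, e2_hint: Optional[np.ndarray] = None) -> Plane:
        if e2_hint is not None:
            e2 = unit(e2_hint - np.dot(e2_hint, self.normal) * self.normal)
            e1 = np.cross(e2, self.normal)
            return Plane(self.normal, self.offset, e1, e2)
        return Plane(self.normal, self.offset)


@dataclass
class SectionStack:
    """Ordered, equally spaced parallel sections sharing one normal."""

    normal: np.ndarray
    start_offset: float
    spacing: float
    n_sections: int
    h_phys: float = 0.0
    h_img: float = 0.0
    mode: str = "arbitrary"  # arbitrary | iur | vertical  (provenance flag)
    vertical_axis: Optional[np.ndarray] = None
    flagged_sparse: bool = False

    def __post_init__(self):
        self.normal = unit(self.normal)
        if self.spacing <= 0:
            raise ValueError("spacing k must be positive")

    @property
    def offsets(self) -> np.ndarray:
        return self.start_offset + self.spacing * np.arange(self.n_sections)

    def spec(self, i: int) -> SectionSpec:
        if not 0 <= i < self.n_sections:
            raise IndexError("section index out of range")
        return SectionSpec(self.normal, float(self.offsets[i]), self.h_phys, self.h_img)

    def __len__(self) -> int:
        return self.n_sections


@dataclass
class SectionImage:
    """One sectioned image: analytic profiles plus field-of-view and frame."""

    profiles: list
    fov: tuple  # (x0, x1, y0, y1)
    spec: SectionSpec
    plane: Plane
    image_id: int = 0
    vertical: Optional[np.ndarray] = None  # in-plane vertical direction (2D)

    def by_label(self, label: str) -> list:
        return [p for p in self.profiles if p.label == label]


def sample_iur_orientation(seed=None) -> np.ndarray:
    """Direction uniform on the unit sphere (isector-style randomisation)."""
    rng = as_rng(seed)
    v = rng.standard_normal(3)
    while np.linalg.norm(v) < 1e-12:
        v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def make_sur_stack(
    scene: Scene,
    normal,
    k: float,
    seed=None,
    h_phys: float = 0.0,
    h_img: float = 0.0,
    span: str = "primitives",
    mode: str = "arbitrary",
) -> SectionStack:
    """Systematic uniform random stack spanning the scene's caliper extent.

    The first section falls at ``lo - U[0, k)`` so the whole systematic grid
    has a single uniform random phase, the defining property of SUR sampling.
    """
    if k <= 0:
        raise ValueError("spacing k must be positive")
    rng = as_rng(seed)
    n = unit(normal)
    lo, hi = scene.caliper(n, include_region=(span == "reference"))
    start = lo - rng.uniform(0.0, k)
    # one extra section past the caliper so every particle edge lies between
    # two sections of the stack (required for disector sweeps)
    n_sections = int(np.floor((hi - start) / k)) + 2
    flagged = k > (hi - lo)
    if flagged:
        warnings.warn("spacing k exceeds the scene extent; sections may miss everything")
    return SectionStack(n, start, k, max(n_sections, 1), h_phys, h_img,
                        mode=mode, flagged_sparse=flagged)


def make_vertical_section(scene: Scene, horizontal_normal, seed=None) -> SectionSpec:
    """Vertical section: contains the vertical axis, random rotation about it.

    ``horizontal_normal`` is the normal of the arbitrary horizontal plane
    (e.g. the culture-dish bottom), i.e. the vertical direction itself.  The
    rotation about the vertical is uniform on [0, pi) and the offset uniform
    over the scene's caliper along the resulting normal.
    """
    rng = as_rng(seed)
    vert = unit(horizontal_normal)
    e1, e2 = plane_basis(vert)
    phi = rng.uniform(0.0, np.pi)
    normal = np.cos(phi) * e1 + np.sin(phi) * e2  # perpendicular to vertical
    lo, hi = scene.caliper(normal)
    offset = rng.uniform(lo, hi)
    spec = SectionSpec(normal, offset)
    spec.vertical_axis_3d = vert
    spec.vertical = np.array([0.0, 1.0])  # e2 of the plane frame is the vertical
    return spec


def _fov_from_scene(scene: Scene, plane: Plane, pad: float = 0.05) -> tuple:
    # project the reference region onto the in-plane axes
    def extent(axis):
        lo, hi = scene.reference_region.support(axis)
        org = float(np.dot(plane.origin, axis))
        return lo - org, hi - org

    x0, x1 = extent(plane.e1)
    y0, y1 = extent(plane.e2)
    return (x0 - pad, x1 + pad, y0 - pad, y1 + pad)


def intersect(
    scene: Scene,
    spec: SectionSpec,
    include_reference: bool = True,
    image_id: int = 0,
    grazing_tol: float = 1e-12,
) -> SectionImage:
    """Exact plane/scene intersection (requires an ideal section, h_phys = 0)."""
    if spec.h_phys != 0.0:
        raise ValueError("intersect() requires an ideal plane; use project_slab()")
    if spec.vertical is not None and hasattr(spec, "vertical_axis_3d"):
        plane = spec.plane(e2_hint=spec.vertical_axis_3d)
    else:
        plane = spec.plane()
    profiles = []
    # vectorised pre-filter for (possibly large) sphere populations
    cache = getattr(scene, "_sphere_cache", None)
    if cache is None or cache[3] is not scene.primitives:
        idx = [i for i, p in enumerate(scene.primitives) if isinstance(p, Sphere)]
        centers = np.array([scene.primitives[i].center for i in idx]).reshape(-1, 3)
        radii = np.array([scene.primitives[i].radius for i in idx])
        cache = (np.array(idx, dtype=int), centers, radii, scene.primitives)
        scene._sphere_cache = cache
    sph_idx, centers, radii = cache[0], cache[1], cache[2]
    sphere_set = set(sph_idx.tolist())
    if len(sph_idx):
        dist = centers @ plane.normal - plane.offset
        hits = np.abs(dist) <= radii + grazing_tol
        rho = np.sqrt(np.maximum(radii ** 2 - dist ** 2, 0.0))
        c2 = plane.to_plane(centers[hits]) if hits.any() else None
        for j, pid in enumerate(sph_idx[hits]):
            profiles.append(
                circle_profile(scene.primitives[pid].label, int(pid), c2[j],
                               float(rho[hits][j]))
            )
    for pid, prim in enumerate(scene.primitives):
        if pid in sphere_set:
            continue
        prof = prim.section(plane, pid, tol=grazing_tol)
        if prof is not None:
            profiles.append(prof)
    if include_reference:
        ref = scene.reference_region.section(plane, -1)
        if ref is not None:
            profiles.append(ref)
    return SectionImage(
        profiles=profiles,
        fov=_fov_from_scene(scene, plane),
        spec=spec,
        plane=plane,
        image_id=image_id,
        vertical=spec.vertical,
    )


class ProjectedProfile(ConvexProfile):
    """Full-opacity projection of one primitive over an imaged slab depth.

    Membership is exact (segment/solid intersection); area and crossing
    queries fall back to numerical evaluation on the in-plane bounding box.
    """

    def __init__(self, label, parent_id, prim, plane, h_img, resolution=200):
        self._prim = prim
        self._plane = plane
        self._h = h_img
        lo, hi = prim.support(plane.e1)
        # bbox: project the primitive's bounding ball over the slab
        c2 = plane.to_plane(prim.center)[0]
        r = prim.bounding_radius()
        ConvexProfile.__init__(
            self,
            label=label,
            parent_id=parent_id,
            constraints=[],
            membrane=[],
            area=0.0,
            centroid=c2,
        )
        self._bbox = (c2[0] - r, c2[0] + r, c2[1] - r, c2[1] + r)
        self._resolution = resolution
        self.area = self._numeric_area()

    def contains(self, pts):
        pts3 = self._plane.to_world(np.atleast_2d(pts))
        return self._prim.segment_hits(pts3, self._plane.normal, self._h)

    def _numeric_area(self) -> float:
        x0, x1, y0, y1 = self._bbox
        n = self._resolution
        xs = np.linspace(x0, x1, n)
        ys = np.linspace(y0, y1, n)
        X, Y = np.meshgrid(xs, ys)
        inside = self.contains(np.column_stack([X.ravel(), Y.ravel()]))
        cell = (x1 - x0) / (n - 1) * (y1 - y0) / (n - 1)
        return float(inside.sum() * cell)

    def line_interval(self, p, d):
        # sampled fallback: scan the line across the bbox
        x0, x1, y0, y1 = self._bbox
        tspan = 2.0 * max(x1 - x0, y1 - y0)
        ts = np.linspace(-tspan, tspan, 4 * self._resolution)
        pts = np.asarray(p) + np.outer(ts, np.asarray(d))
        inside = self.contains(pts)
        if not inside.any():
            return None
        idx = np.nonzero(inside)[0]
        return float(ts[idx[0]]), float(ts[idx[-1]])

    def line_crossings(self, p, d, tmin=-np.inf, tmax=np.inf, membrane_only=True):
        iv = self.line_interval(p, d)
        if iv is None:
            return []
        return [t for t in iv if tmin < t < tmax]

    def curve_crossings(self, pts, membrane_only=True) -> int:
        inside = self.contains(pts).astype(int)
        return int(np.abs(np.diff(inside)).sum())

    @property
    def bbox(self):
        return self._bbox

    def boundary_polyline(self, n=256):
        # radial casting against the sampled membership
        c = self.centroid
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r_max = max(self._bbox[1] - self._bbox[0], self._bbox[3] - self._bbox[2])
        out = np.empty((n, 2))
        rs = np.linspace(0, r_max, 200)
        for k, a in enumerate(ang):
            d = np.array([np.cos(a), np.sin(a)])
            pts = c + np.outer(rs, d)
            inside = self.contains(pts)
            hit = np.nonzero(inside)[0]
            out[k] = c + (rs[hit[-1]] if len(hit) else 0.0) * d
        return out


def project_slab(
    scene: Scene,
    spec: SectionSpec,
    image_id: int = 0,
    lost_caps_eps: float = 0.0,
    include_reference: bool = True,
) -> SectionImage:
    """Imaged slab: union of intersections over [offset, offset + h_img).

    Models surface-layer imaging in volume-SEM: structures anywhere in the
    imaged depth project at full opacity (Holmes overprojection), and profiles
    whose smallest dimension falls below ``lost_caps_eps`` are dropped
    (lost caps).
    """
    if spec.h_img <= 0:
        ideal = SectionSpec(spec.normal, spec.offset, 0.0, 0.0, spec.pixel_size, spec.vertical)
        return intersect(scene, ideal, include_reference, image_id)
    if spec.h_img > spec.h_phys:
        raise ValueError("imaging depth cannot exceed physical thickness")
    plane = spec.plane()
    profiles = []
    for pid, prim in enumerate(scene.primitives):
        lo, hi = prim.support(plane.normal)
        if hi < spec.offset or lo > spec.offset + spec.h_img:
            continue
        if isinstance(prim, Sphere):
            # analytic union: the widest equatorial disc visible in the slab
            zc = float(np.dot(prim.center, plane.normal))
            z1, z2 = spec.offset - zc, spec.offset + spec.h_img - zc
            if z1 <= 0.0 <= z2:
                rho = prim.radius
            else:
                z = min(abs(z1), abs(z2))
                rho = np.sqrt(max(prim.radius ** 2 - z * z, 0.0))
            prof = circle_profile(prim.label, pid, plane.to_plane(prim.center)[0], rho)
        else:
            prof = ProjectedProfile(prim.label, pid, prim, plane, spec.h_img)
            if prof.area <= 0:
                continue
        if lost_caps_eps > 0 and prof.min_dimension < lost_caps_eps:
            continue
        profiles.append(prof)
    if include_reference:
        ref = scene.reference_region.section(plane, -1)
        if ref is not None:
            profiles.append(ref)
    return SectionImage(profiles, _fov_from_scene(scene, plane), spec, plane,
                        image_id, spec.vertical)


def ministack_projection(scene: Scene, stack: SectionStack, m: int,
                         lost_caps_eps: float = 0.0) -> list[SectionImage]:
    """Disjoint ministacks of ``m`` consecutive sections, each projected.

    Tiling the stack into consecutive groups of ``m`` gives projection images
    whose effective thickness m*k can be matched to the particle size
    (restoring one-section-disector behaviour for very thin sections).
    """
    if m < 1:
        raise ValueError("ministack size must be >= 1")
    if m > stack.n_sections:
        raise ValueError("ministack exceeds the stack length")
    images = []
    n_groups = stack.n_sections // m
    for g in range(n_groups):
        o = float(stack.offsets[g * m])
        depth = stack.spacing * m
        spec = SectionSpec(stack.normal, o, h_phys=max(depth, stack.h_phys), h_img=depth)
        images.append(project_slab(scene, spec, image_id=g, lost_caps_eps=lost_caps_eps))
    return images


def rasterize(image: SectionImage, pixel_size: float,
              label_map: Optional[dict] = None) -> tuple[np.ndarray, dict]:
    """Sample profiles at pixel centres into an integer label image.

    Collisions resolve smallest-structure-wins (smaller profile area painted
    last), which is deterministic and independent of the profile order.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    x0, x1, y0, y1 = image.fov
    nx = max(int(np.ceil((x1 - x0) / pixel_size)), 1)
    ny = max(int(np.ceil((y1 - y0) / pixel_size)), 1)
    xs = x0 + (np.arange(nx) + 0.5) * pixel_size
    ys = y0 + (np.arange(ny) + 0.5) * pixel_size
    if label_map is None:
        labels = sorted({p.label for p in image.profiles})
        label_map = {lab: i + 1 for i, lab in enumerate(labels)}
    out = np.zeros((ny, nx), dtype=np.int32)
    smallest = min((p.min_dimension for p in image.profiles), default=np.inf)
    if image.profiles and pixel_size > smallest:
        warnings.warn("pixel size exceeds the smallest profile; counts will be unreliable")
    # paint largest first so smaller structures win label collisions
    order = sorted(
        range(len(image.profiles)),
        key=lambda i: (-image.profiles[i].area, image.profiles[i].label, image.profiles[i].parent_id),
    )
    for i in order:
        prof = image.profiles[i]
        bx0, bx1, by0, by1 = prof.bbox
        ix = np.nonzero((xs >= bx0 - pixel_size) & (xs <= bx1 + pixel_size))[0]
        iy = np.nonzero((ys >= by0 - pixel_size) & (ys <= by1 + pixel_size))[0]
        if len(ix) == 0 or len(iy) == 0:
            continue
        X, Y = np.meshgrid(xs[ix], ys[iy])
        inside = prof.contains(np.column_stack([X.ravel(), Y.ravel()])).reshape(len(iy), len(ix))
        sub = out[np.ix_(iy, ix)]
        sub[inside] = label_map[prof.label]
        out[np.ix_(iy, ix)] = sub
    return out, label_map
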