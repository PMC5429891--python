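"""Golgi-like 3D phantoms with exact analytic ground truth.

A :class:`Scene` is a collection of labelled convex primitives (spheres for
vesicles, thin disc plates for cisternae, cylinders for tubules, an ellipsoid
where a smooth test body is wanted) inside a reference region (the "cell").
Because every primitive has closed-form volume, surface and plane-section
geometry, the scene serves as the oracle against which every stereological
estimator is validated.  All lengths are micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .geometry import (
    EPS,
    ConvexProfile,
    Plane,
    band_ellipse_profile,
    circle_profile,
    ellipse_profile,
    plane_basis,
    polygon_profile,
    unit,
)

__all__ = [
    "Sphere",
    "DiscPlate",
    "Tubule",
    "Ellipsoid",
    "Box",
    "SphereRegion",
    "GroundTruth",
    "Scene",
    "make_vesicle_population",
    "make_golgi_stack",
    "make_cell_scene",
]


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


@dataclass
class Sphere:
    center: np.ndarray
    radius: float
    label: str = "vesicle"
    kind: str = field(default="sphere", init=False)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius ** 3

    def surface(self, include_rim=False) -> float:
        return 4.0 * np.pi * self.radius ** 2

    def support(self, n) -> tuple[float, float]:
        c = float(np.dot(self.center, n))
        return c - self.radius, c + self.radius

    def bounding_radius(self) -> float:
        return self.radius

    def section(self, plane: Plane, pid: int, tol=1e-12) -> Optional[ConvexProfile]:
        dist = float(np.dot(self.center, plane.normal)) - plane.offset
        if abs(dist) > self.radius + tol:
            return None
        rho = np.sqrt(max(self.radius ** 2 - dist ** 2, 0.0))
        c2 = plane.to_plane(self.center)[0]
        return circle_profile(self.label, pid, c2, rho)

    def segment_hits(self, p0: np.ndarray, d: np.ndarray, h: float) -> np.ndarray:
        """Which of the segments {p0[i] + t d, t in [0, h]} hit the sphere."""
        y = np.atleast_2d(p0) - self.center
        b = y @ d
        c = np.einsum("ij,ij->i", y, y) - self.radius ** 2
        disc = b * b - c
        ok = disc >= 0
        s = np.sqrt(np.where(ok, disc, 0.0))
        t1, t2 = -b - s, -b + s
        return ok & (t2 >= 0) & (t1 <= h)

    def transformed(self, R: np.ndarray, about: np.ndarray) -> "Sphere":
        return Sphere(about + R @ (self.center - about), self.radius, self.label)


class _FiniteCylinder:
    """Shared plane-section math for disc plates and tubules."""

    center: np.ndarray
    axis: np.ndarray
    R: float  # radial extent
    H: float  # half-length along the axis
    label: str

    @property
    def volume(self) -> float:
        return np.pi * self.R ** 2 * 2 * self.H

    def support(self, n) -> tuple[float, float]:
        c = float(np.dot(self.center, n))
        cg = abs(float(np.dot(self.axis, n)))
        sg = np.sqrt(max(1.0 - cg * cg, 0.0))
        half = self.H * cg + self.R * sg
        return c - half, c + half

    def bounding_radius(self) -> float:
        return float(np.hypot(self.R, self.H))

    def _membrane_faces_only(self) -> bool:
        return False

    def section(self, plane: Plane, pid: int, tol=1e-12) -> Optional[ConvexProfile]:
        n = plane.normal
        cg_signed = float(np.dot(n, self.axis))
        cg = abs(cg_signed)
        sg = np.sqrt(max(1.0 - cg * cg, 0.0))
        lo, hi = self.support(n)
        if plane.offset < lo - tol or plane.offset > hi + tol:
            return None
        D = float(np.dot(self.center, n)) - plane.offset
        c_proj = self.center - D * n
        c2 = plane.to_plane(c_proj)[0]
        if sg <= 1e-9:
            # plane perpendicular to the axis: full disc
            return band_ellipse_profile(
                self.label, pid, c2, np.array([1.0, 0.0]), cg, 0.0, self.R, self.H,
                D * np.sign(cg_signed) if cg_signed != 0 else D,
                self._membrane_faces_only(),
            )
        # in-plane direction of the projected axis; orient so the algebra uses
        # a consistent sign of cos(gamma)
        a_eff = self.axis if cg_signed >= 0 else -self.axis
        g2 = np.array([float(np.dot(a_eff, plane.e1)), float(np.dot(a_eff, plane.e2))])
        w_dir = g2 / sg
        prof = band_ellipse_profile(
            self.label, pid, c2, w_dir, cg, sg, self.R, self.H, D,
            self._membrane_faces_only(),
        )
        if prof.area <= 0.0 and abs(plane.offset - lo) > tol and abs(plane.offset - hi) > tol:
            # numerically empty corner graze
            return None
        return prof

    def segment_hits(self, p0: np.ndarray, d: np.ndarray, h: float) -> np.ndarray:
        p0 = np.atleast_2d(p0)
        y0 = p0 - self.center
        za, da = y0 @ self.axis, float(np.dot(d, self.axis))
        # |za + t*da| <= H  -> linear interval
        t_lo = np.zeros(len(p0))
        t_hi = np.full(len(p0), h)
        if abs(da) < EPS:
            ok = np.abs(za) <= self.H
        else:
            a1 = (-self.H - za) / da
            a2 = (self.H - za) / da
            t_lo = np.maximum(t_lo, np.minimum(a1, a2))
            t_hi = np.minimum(t_hi, np.maximum(a1, a2))
            ok = t_lo <= t_hi
        # radial: |y0 + t d - (za + t da) axis|^2 <= R^2
        perp0 = y0 - np.outer(za, self.axis)
        dperp = d - da * self.axis
        A = float(np.dot(dperp, dperp))
        B = 2.0 * perp0 @ dperp
        C = np.einsum("ij,ij->i", perp0, perp0) - self.R ** 2
        if A < EPS:
            ok &= C <= 0
            return ok
        disc = B * B - 4 * A * C
        ok &= disc >= 0
        s = np.sqrt(np.where(disc >= 0, disc, 0.0))
        r1 = (-B - s) / (2 * A)
        r2 = (-B + s) / (2 * A)
        return ok & (np.maximum(t_lo, r1) <= np.minimum(t_hi, r2))


@dataclass
class DiscPlate(_FiniteCylinder):
    """Flat circular plate: the cisterna model (thickness t << radius R)."""

    center: np.ndarray
    axis: np.ndarray
    radius: float
    thickness: float
    label: str = "cisterna"
    include_rim: bool = False
    kind: str = field(default="disc_plate", init=False)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.axis = unit(self.axis)
        if self.radius <= 0 or self.thickness <= 0:
            raise ValueError("disc radius and thickness must be positive")
        if self.thickness > self.radius:
            raise ValueError("disc_plate requires thickness <= radius")

    @property
    def R(self):
        return self.radius

    @property
    def H(self):
        return self.thickness / 2.0

    def surface(self, include_rim=None) -> float:
        rim = self.include_rim if include_rim is None else include_rim
        s = 2.0 * np.pi * self.radius ** 2
        if rim:
            s += 2.0 * np.pi * self.radius * self.thickness
        return s

    def _membrane_faces_only(self) -> bool:
        return not self.include_rim

    def transformed(self, Rm, about):
        return DiscPlate(
            about + Rm @ (self.center - about), Rm @ self.axis,
            self.radius, self.thickness, self.label, self.include_rim,
        )


@dataclass
class Tubule(_FiniteCylinder):
    """Cylindrical tubule (length along the axis)."""

    center: np.ndarray
    axis: np.ndarray
    radius: float
    length: float
    label: str = "tubule"
    kind: str = field(default="cylinder", init=False)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.axis = unit(self.axis)
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("tubule radius and length must be positive")

    @property
    def R(self):
        return self.radius

    @property
    def H(self):
        return self.length / 2.0

    def surface(self, include_rim=False) -> float:
        return 2.0 * np.pi * self.radius * self.length + 2.0 * np.pi * self.radius ** 2

    def transformed(self, Rm, about):
        return Tubule(
            about + Rm @ (self.center - about), Rm @ self.axis,
            self.radius, self.length, self.label,
        )


@dataclass
class Ellipsoid:
    """Triaxial ellipsoid; plane sections are exact ellipses."""

    center: np.ndarray
    semiaxes: np.ndarray  # (a, b, c)
    rotation: np.ndarray = None  # columns = principal directions
    label: str = "cell"
    kind: str = field(default="ellipsoid", init=False)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.semiaxes = np.asarray(self.semiaxes, dtype=float)
        if np.any(self.semiaxes <= 0):
            raise ValueError("semiaxes must be positive")
        if self.rotation is None:
            self.rotation = np.eye(3)
        self.rotation = np.asarray(self.rotation, dtype=float)
        self._M = self.rotation @ np.diag(self.semiaxes)

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * float(np.prod(self.semiaxes))

    def surface(self, include_rim=False) -> float:
        # Thomsen approximation, max error ~1.06%
        p = 1.6075
        a, b, c = self.semiaxes
        return 4.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)

    def support(self, n) -> tuple[float, float]:
        c = float(np.dot(self.center, n))
        half = float(np.linalg.norm(self._M.T @ n))
        return c - half, c + half

    def bounding_radius(self) -> float:
        return float(np.max(self.semiaxes))

    def section(self, plane: Plane, pid: int, tol=1e-12) -> Optional[ConvexProfile]:
        m = self._M.T @ plane.normal
        mn = float(np.linalg.norm(m))
        delta = (plane.offset - float(np.dot(self.center, plane.normal))) / mn
        if abs(delta) > 1.0 + tol:
            return None
        rho = np.sqrt(max(1.0 - delta * delta, 0.0))
        u = m / mn
        f1, f2 = plane_basis(u)
        A1 = self._M @ f1 * rho
        A2 = self._M @ f2 * rho
        center3 = self.center + self._M @ (delta * u)
        c2 = plane.to_plane(center3)[0]
        B = np.array(
            [
                [float(np.dot(A1, plane.e1)), float(np.dot(A2, plane.e1))],
                [float(np.dot(A1, plane.e2)), float(np.dot(A2, plane.e2))],
            ]
        )
        if abs(np.linalg.det(B)) < 1e-15:
            return None
        return ellipse_profile(self.label, pid, c2, B)

    def segment_hits(self, p0: np.ndarray, d: np.ndarray, h: float) -> np.ndarray:
        Minv = np.linalg.inv(self._M)
        y = (np.atleast_2d(p0) - self.center) @ Minv.T
        dd = Minv @ d
        A = float(np.dot(dd, dd))
        B = 2.0 * y @ dd
        C = np.einsum("ij,ij->i", y, y) - 1.0
        disc = B * B - 4 * A * C
        ok = disc >= 0
        s = np.sqrt(np.where(ok, disc, 0.0))
        return ok & ((-B + s) / (2 * A) >= 0) & ((-B - s) / (2 * A) <= h)

    def transformed(self, Rm, about):
        return Ellipsoid(
            about + Rm @ (self.center - about), self.semiaxes,
            Rm @ self.rotation, self.label,
        )


# ---------------------------------------------------------------------------
# reference regions
# ---------------------------------------------------------------------------


@dataclass
class Box:
    lo: np.ndarray
    hi: np.ndarray
    label: str = "cell"
    kind: str = field(default="box", init=False)

    def __post_init__(self):
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        if np.any(self.hi <= self.lo):
            raise ValueError("degenerate box region")

    @property
    def volume(self) -> float:
        return float(np.prod(self.hi - self.lo))

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.lo + self.hi)

    def sample(self, rng, n) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=(n, 3))

    def contains_ball(self, center, r) -> bool:
        return bool(np.all(center - r >= self.lo - EPS) and np.all(center + r <= self.hi + EPS))

    def support(self, n) -> tuple[float, float]:
        corners = self.corners()
        proj = corners @ n
        return float(proj.min()), float(proj.max())

    def corners(self) -> np.ndarray:
        xs = [self.lo, self.hi]
        return np.array([[xs[i][0], xs[j][1], xs[k][2]] for i in range(2) for j in range(2) for k in range(2)])

    def section(self, plane: Plane, pid: int = -1) -> Optional[ConvexProfile]:
        pts = []
        c = self.corners()
        edges = [
            (0, 1), (0, 2), (0, 4), (1, 3), (1, 5), (2, 3),
            (2, 6), (3, 7), (4, 5), (4, 6), (5, 7), (6, 7),
        ]
        for i, j in edges:
            gi = float(np.dot(c[i], plane.normal)) - plane.offset
            gj = float(np.dot(c[j], plane.normal)) - plane.offset
            if gi * gj < 0:
                w = gi / (gi - gj)
                pts.append(c[i] + w * (c[j] - c[i]))
        if len(pts) < 3:
            return None
        pts2 = plane.to_plane(np.array(pts))
        ctr = pts2.mean(axis=0)
        order = np.argsort(np.arctan2(pts2[:, 1] - ctr[1], pts2[:, 0] - ctr[0]))
        return polygon_profile(self.label, pid, pts2[order])

    def transformed(self, Rm, about):
        # rotating a box yields a box only for axis permutations; keep regions
        # axis aligned and rotate the scene contents instead.
        raise NotImplementedError("box regions are axis aligned")


@dataclass
class SphereRegion:
    center: np.ndarray
    radius: float
    label: str = "cell"
    kind: str = field(default="sphere_region", init=False)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("region radius must be positive")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius ** 3

    def sample(self, rng, n) -> np.ndarray:
        pts = np.empty((n, 3))
        got = 0
        while got < n:
            cand = rng.uniform(-1, 1, size=(2 * (n - got), 3))
            cand = cand[np.einsum("ij,ij->i", cand, cand) <= 1.0]
            take = min(len(cand), n - got)
            pts[got : got + take] = self.center + self.radius * cand[:take]
            got += take
        return pts

    def contains_ball(self, center, r) -> bool:
        return float(np.linalg.norm(np.asarray(center) - self.center)) + r <= self.radius + EPS

    def support(self, n) -> tuple[float, float]:
        c = float(np.dot(self.center, n))
        return c - self.radius, c + self.radius

    def section(self, plane: Plane, pid: int = -1) -> Optional[ConvexProfile]:
        return Sphere(self.center, self.radius, self.label).section(plane, pid)

    def transformed(self, Rm, about):
        return SphereRegion(about + Rm @ (self.center - about), self.radius, self.label)


# ---------------------------------------------------------------------------
# scene
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    V: float = 0.0
    S: float = 0.0
    N: int = 0


@dataclass
class Scene:
    primitives: list
    reference_region: object
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for p in self.primitives:
            if not self.reference_region.contains_ball(p.center, p.bounding_radius()):
                raise ValueError(
                    f"primitive with label {p.label!r} escapes the reference region"
                )

    @property
    def labels(self) -> list[str]:
        seen = []
        for p in self.primitives:
            if p.label not in seen:
                seen.append(p.label)
        return seen

    def ground_truth(self) -> dict[str, GroundTruth]:
        gt: dict[str, GroundTruth] = {}
        for p in self.primitives:
            g = gt.setdefault(p.label, GroundTruth())
            g.V += p.volume
            g.S += p.surface()
            g.N += 1
        ref = self.reference_region
        gt[ref.label] = GroundTruth(V=ref.volume, S=0.0, N=1)
        return gt

    def caliper(self, normal, include_region=False) -> tuple[float, float]:
        """Extent of the scene contents along ``normal``."""
        n = unit(normal)
        sources = list(self.primitives)
        if include_region or not sources:
            sources.append(self.reference_region)
        los, his = zip(*(p.support(n) for p in sources))
        return min(los), max(his)

    def rotated(self, Rm: np.ndarray, about=None) -> "Scene":
        about = self.reference_region.center if about is None else np.asarray(about)
        prims = [p.transformed(Rm, about) for p in self.primitives]
        region = self.reference_region
        if not isinstance(region, Box):
            region = region.transformed(Rm, about)
        return Scene(prims, region, dict(self.metadata))

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        prims = []
        for p in self.primitives:
            d = {"kind": p.kind, "label": p.label, "center": list(p.center)}
            if p.kind == "sphere":
                d["radius"] = p.radius
            elif p.kind == "disc_plate":
                d.update(axis=list(p.axis), radius=p.radius, thickness=p.thickness,
                         include_rim=p.include_rim)
            elif p.kind == "cylinder":
                d.update(axis=list(p.axis), radius=p.radius, length=p.length)
            elif p.kind == "ellipsoid":
                d.update(semiaxes=list(p.semiaxes), rotation=p.rotation.tolist())
            prims.append(d)
        ref = self.reference_region
        if isinstance(ref, Box):
            region = {"kind": "box", "lo": list(ref.lo), "hi": list(ref.hi), "label": ref.label}
        else:
            region = {"kind": "sphere_region", "center": list(ref.center),
                      "radius": ref.radius, "label": ref.label}
        gt = {k: {"V": g.V, "S": g.S, "N": g.N} for k, g in self.ground_truth().items()}
        return {"primitives": prims, "reference_region": region,
                "ground_truth": gt, "metadata": self.metadata}

    @classmethod
    def from_dict(cls, d: dict) -> "Scene":
        prims = []
        for pd in d["primitives"]:
            kind = pd["kind"]
            if kind == "sphere":
                prims.append(Sphere(pd["center"], pd["radius"], pd["label"]))
            elif kind == "disc_plate":
                prims.append(DiscPlate(pd["center"], pd["axis"], pd["radius"],
                                       pd["thickness"], pd["label"],
                                       pd.get("include_rim", False)))
            elif kind == "cylinder":
                prims.append(Tubule(pd["center"], pd["axis"], pd["radius"],
                                    pd["length"], pd["label"]))
            elif kind == "ellipsoid":
                prims.append(Ellipsoid(pd["center"], pd["semiaxes"],
                                       np.asarray(pd["rotation"]), pd["label"]))
            else:
                raise ValueError(f"unknown primitive kind {kind!r}")
        rd = d["reference_region"]
        if rd["kind"] == "box":
            region = Box(rd["lo"], rd["hi"], rd.get("label", "cell"))
        else:
            region = SphereRegion(rd["center"], rd["radius"], rd.get("label", "cell"))
        return cls(prims, region, d.get("metadata", {}))

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "Scene":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def make_vesicle_population(
    n: int,
    diameter_mean: float = 0.065,
    diameter_sd: float = 0.005,
    region: Optional[Box] = None,
    seed=None,
    label: str = "vesicle",
    hard_core: bool = False,
    negative_mass_tol: float = 0.25,
) -> Scene:
    """Spherical vesicle population with truncated-normal diameters.

    Centres are i.i.d. uniform in the region (overlap permitted by default;
    ``hard_core=True`` enables rejection of overlapping placements, which
    changes the spatial point process but not any estimator's unbiasedness).
    The default diameter 65 +/- 5 nm reflects the 60-70 nm size of Golgi
    COPI-type transport vesicles.
    """
    if n < 1:
        raise ValueError("need at least one vesicle")
    if diameter_mean <= 0 or diameter_sd < 0:
        raise ValueError("diameters must be positive")
    if diameter_sd > 0 and stats.norm.cdf(0.0, diameter_mean, diameter_sd) > negative_mass_tol:
        raise ValueError("diameter distribution places too much mass below zero")
    rng = as_rng(seed)
    region = region if region is not None else Box([0, 0, 0], [5, 5, 5])
    if diameter_sd > 0:
        a = (0.0 - diameter_mean) / diameter_sd
        diam = stats.truncnorm.rvs(a, np.inf, loc=diameter_mean, scale=diameter_sd,
                                   size=n, random_state=rng)
    else:
        diam = np.full(n, diameter_mean)
    radii = diam / 2.0
    # shrink the sampling window so every sphere fits inside the region
    rmax = radii.max()
    if isinstance(region, Box):
        inner = Box(region.lo + rmax, region.hi - rmax)
    else:
        inner = SphereRegion(region.center, region.radius - rmax)
    prims: list[Sphere] = []
    attempts = 0
    while len(prims) < n:
        r = radii[len(prims)]
        c = inner.sample(rng, 1)[0]
        if hard_core and any(
            np.linalg.norm(c - q.center) < r + q.radius for q in prims
        ):
            attempts += 1
            if attempts > 200 * n:
                raise RuntimeError("hard-core packing failed; lower the density")
            continue
        prims.append(Sphere(c, r, label))
    return Scene(prims, region, {"builder": "vesicle_population", "n": n})


def make_golgi_stack(
    n_cisternae: int,
    radii,
    thickness: float = 0.05,
    spacing: float = 0.1,
    orientation=(0.0, 0.0, 1.0),
    center=(0.0, 0.0, 0.0),
    seed=None,
    region: Optional[object] = None,
    label: str = "cisterna",
    include_rim: bool = False,
) -> Scene:
    """Stack of coaxial parallel disc-plate cisternae.

    ``spacing`` is the centre-to-centre distance along the stack axis and must
    exceed ``thickness`` so cisternae do not interpenetrate.  Default geometry
    (40-60 nm thick plates, sub-micrometre radii) follows typical animal-cell
    Golgi dimensions.
    """
    radii = np.asarray(radii, dtype=float)
    if len(radii) != n_cisternae:
        raise ValueError("radii length must equal n_cisternae")
    if spacing <= thickness:
        raise ValueError("spacing must exceed thickness (cisternae overlap)")
    axis = unit(orientation)
    center = np.asarray(center, dtype=float)
    offsets = (np.arange(n_cisternae) - (n_cisternae - 1) / 2.0) * spacing
    prims = [
        DiscPlate(center + off * axis, axis, r, thickness, label, include_rim)
        for off, r in zip(offsets, radii)
    ]
    if region is None:
        half = float(radii.max() + spacing * n_cisternae)
        region = SphereRegion(center, 1.5 * half)
    face_areas = [np.pi * r * r for r in radii]
    return Scene(prims, region, {"builder": "golgi_stack", "face_areas": face_areas,
                                 "spacing": spacing, "thickness": thickness})


def make_cell_scene(config: dict, seed=None) -> Scene:
    """Composite scene from a configuration mapping.

    ``config`` keys (all optional): ``region`` ({"kind": "box"|"sphere", ...}),
    ``stacks`` (list of golgi-stack parameter dicts), ``vesicles`` (vesicle
    population parameters), ``tubules`` ({"n", "radius", "length"}).
    """
    rng = as_rng(seed)
    rd = config.get("region", {"kind": "box", "lo": [0, 0, 0], "hi": [5, 5, 5]})
    if rd.get("kind", "box") == "box":
        region = Box(rd.get("lo", [0, 0, 0]), rd.get("hi", [5, 5, 5]), rd.get("label", "cell"))
    else:
        region = SphereRegion(rd["center"], rd["radius"], rd.get("label", "cell"))
    prims = []
    for sd in config.get("stacks", []):
        sub = make_golgi_stack(
            sd.get("n_cisternae", 5),
            sd.get("radii", [0.8] * sd.get("n_cisternae", 5)),
            sd.get("thickness", 0.05),
            sd.get("spacing", 0.1),
            sd.get("orientation", (0, 0, 1)),
            sd.get("center", region.center if isinstance(region, Box) else region.center),
            seed=rng,
            region=region,
            label=sd.get("label", "cisterna"),
            include_rim=sd.get("include_rim", False),
        )
        prims.extend(sub.primitives)
    vd = config.get("vesicles")
    if vd:
        sub = make_vesicle_population(
            vd["n"], vd.get("diameter_mean", 0.065), vd.get("diameter_sd", 0.005),
            region=region if isinstance(region, Box) else None, seed=rng,
            label=vd.get("label", "vesicle"), hard_core=vd.get("hard_core", False),
        )
        prims.extend(sub.primitives)
    td = config.get("tubules")
    if td:
        for _ in range(td["n"]):
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            L, r = td.get("length", 0.5), td.get("radius", 0.015)
            half = np.hypot(L / 2, r)
            if isinstance(region, Box):
                c = Box(region.lo + half, region.hi - half).sample(rng, 1)[0]
            else:
                c = SphereRegion(region.center, region.radius - half).sample(rng, 1)[0]
            prims.append(Tubule(c, axis, r, L, td.get("label", "tubule")))
    return Scene(prims, region, {"builder": "cell_scene"})
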