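"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's analytic ground-truth paths: volume by
voxel counting, surface by marching cubes on a signed-distance field, chord
statistics by direct simulation.
"""

from __future__ import annotations

import numpy as np
from skimage import measure


def _signed_distance(prim, pts: np.ndarray) -> np.ndarray:
    """Approximate signed distance (negative inside) to one primitive."""
    kind = prim.kind
    if kind == "sphere":
        return np.linalg.norm(pts - prim.center, axis=1) - prim.radius
    if kind in ("disc_plate", "cylinder"):
        y = pts - prim.center
        z = y @ prim.axis
        rho = np.linalg.norm(y - np.outer(z, prim.axis), axis=1)
        dz = np.abs(z) - prim.H
        dr = rho - prim.R
        outside = np.sqrt(np.maximum(dz, 0) ** 2 + np.maximum(dr, 0) ** 2)
        inside = np.minimum(np.maximum(dz, dr), 0.0)
        return outside + inside
    if kind == "ellipsoid":
        Minv = np.linalg.inv(prim.rotation @ np.diag(prim.semiaxes))
        y = (pts - prim.center) @ Minv.T
        r = np.linalg.norm(y, axis=1)
        # first-order distance approximation (adequate at fine voxel pitch)
        grad = np.linalg.norm(y @ Minv, axis=1)
        return (r - 1.0) / np.maximum(grad / np.maximum(r, 1e-12), 1e-12)
    raise ValueError(kind)


def scene_field(scene, voxel: float, pad: float = 0.05):
    """Signed-distance field of the union of primitives on a voxel grid."""
    lo = np.min([p.center - p.bounding_radius() for p in scene.primitives], axis=0) - pad
    hi = np.max([p.center + p.bounding_radius() for p in scene.primitives], axis=0) + pad
    ns = np.maximum(((hi - lo) / voxel).astype(int) + 1, 2)
    axes = [lo[i] + voxel * np.arange(ns[i]) for i in range(3)]
    field = np.full(tuple(ns), np.inf, dtype=np.float32)
    X, Y = np.meshgrid(axes[0], axes[1], indexing="ij")
    base = np.column_stack([X.ravel(), Y.ravel()])
    for iz, z in enumerate(axes[2]):
        pts = np.column_stack([base, np.full(len(base), z)])
        d = np.full(len(pts), np.inf, dtype=np.float32)
        for prim in scene.primitives:
            d = np.minimum(d, _signed_distance(prim, pts))
        field[:, :, iz] = d.reshape(ns[0], ns[1])
    return field, voxel


def voxel_volume(scene, voxel: float = 0.005) -> float:
    field, voxel = scene_field(scene, voxel)
    return float((field < 0).sum()) * voxel ** 3


def voxel_surface(scene, voxel: float = 0.005) -> float:
    field, voxel = scene_field(scene, voxel)
    verts, faces, _, _ = measure.marching_cubes(field, level=0.0,
                                                spacing=(voxel, voxel, voxel))
    return float(measure.mesh_surface_area(verts, faces))


def chord_power_star_area(R: float, n: int = 200_000, seed: int = 0) -> float:
    """Brute-force star area of a disc by length-weighted chord simulation.

    Chords uniform in offset; sampling weight proportional to chord length;
    the star-area constant then satisfies a* = (pi/3) E_w[l^2] = pi R^2.
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(-R, R, n)
    l = 2.0 * np.sqrt(R * R - u * u)
    w = l / l.sum()
    return float(np.pi / 3.0 * np.sum(w * l ** 2))


def holmes_projected_area(r: float, h: float, n: int = 200_000, seed: int = 0) -> float:
    """Mean projected disc area of a sphere imaged through a slab of depth h,
    averaged over slab positions that intersect the sphere (numeric)."""
    rng = np.random.default_rng(seed)
    o = rng.uniform(-r - h, r, n)  # slab [o, o+h] intersects the sphere
    z1, z2 = o, o + h
    rho = np.where((z1 <= 0) & (z2 >= 0), r,
                   np.sqrt(np.maximum(r * r - np.minimum(np.abs(z1), np.abs(z2)) ** 2, 0)))
    return float(np.mean(np.pi * rho ** 2))
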