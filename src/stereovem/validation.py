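"""End-to-end simulation pipelines validating the estimators against phantoms.

Each function generates phantoms with known ground truth, runs the full
sampling -> probing -> estimation pipeline, and reports the recovered quantity
together with its Monte-Carlo uncertainty.  These are the work-horses behind
the ``validate`` CLI subcommand and the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import estimators as est
from . import probes, sectioning
from .phantom import (
    Box,
    DiscPlate,
    Ellipsoid,
    Scene,
    Sphere,
    SphereRegion,
    as_rng,
    make_golgi_stack,
    make_vesicle_population,
)
from .precision import cochran_ratio_se, empirical_ce
from .probes import make_test_system, sur_pairs
from .sectioning import SectionSpec, intersect, make_sur_stack, make_vertical_section

__all__ = [
    "copi_number_simulation",
    "cavalieri_ce_ellipsoid",
    "thickness_factor_simulation",
    "buffon_length_factor",
    "t_times_sv_product",
    "cisterna_hit_ratio",
    "vv_recovery",
    "sv_iur_sphere_recovery",
    "sv_cycloid_plate_recovery",
    "total_number_recovery",
    "mean_reference_volume_recovery",
    "star_area_recovery",
    "composition_two_disc",
    "lvw_vs_lines_stabilization",
    "reference_trap_demo",
]


def _iur_plane_in_region(region: SphereRegion, rng) -> SectionSpec:
    """IUR section of a spherical container: the offset window is the same
    for every orientation, so position and orientation are jointly uniform."""
    n = sectioning.sample_iur_orientation(rng)
    lo, hi = region.support(n)
    return SectionSpec(n, float(rng.uniform(lo, hi)))


# ---------------------------------------------------------------------------
# worked-example scale simulations
# ---------------------------------------------------------------------------


def copi_number_simulation(
    n_seeds: int = 500,
    seed=0,
    n_vesicles: int = 1000,
    diameter: float = 0.060,
    extent: float = 5.0,
    k: float = 0.020,
    pair_spacing: int = 50,
) -> dict:
    """COPI-style vesicle counting with SUR adjacent-pair disectors.

    1000 vesicles through a 5 um organelle, 20 nm sections, pairs every 50
    sections, both directions: the expected total edge count is ~40 and the
    total-number estimate Q- x spacing/2 recovers the true count.
    """
    rng = as_rng(seed)
    totals = np.empty(n_seeds)
    n_estimates = np.empty(n_seeds)
    for s in range(n_seeds):
        region = Box([0, 0, 0], [extent, extent, extent])
        scene = make_vesicle_population(n_vesicles, diameter, 0.0, region, rng)
        stack = make_sur_stack(scene, [0, 0, 1], k, rng)
        pairs = sur_pairs(stack.n_sections, pair_spacing, rng)
        records = []
        for m, (i, j) in enumerate(pairs):
            img_i = intersect(scene, stack.spec(i), include_reference=False, image_id=2 * m)
            img_j = intersect(scene, stack.spec(j), include_reference=False, image_id=2 * m + 1)
            records += probes.count_disector(img_i, img_j, None, ["vesicle"])
            records += probes.count_disector(img_j, img_i, None, ["vesicle"])
        totals[s] = sum(r.Qminus for r in records)
        n_estimates[s] = est.total_number(records, pair_spacing, "vesicle",
                                          both_directions=True).value
    return {
        "mean_total_qminus": float(totals.mean()),
        "se_total_qminus": float(totals.std(ddof=1) / np.sqrt(n_seeds)),
        "mean_number_estimate": float(n_estimates.mean()),
        "se_number_estimate": float(n_estimates.std(ddof=1) / np.sqrt(n_seeds)),
        "true_number": n_vesicles,
        "n_seeds": n_seeds,
    }


def cavalieri_ce_ellipsoid(
    n_replicates: int = 1000,
    seed=0,
    semiaxes=(2.0, 1.5, 1.0),
    n_sections: int = 8,
) -> dict:
    """Empirical CE of the Cavalieri estimate on a smooth ellipsoid.

    Eight systematic sections with a uniform random start; profile areas are
    exact plane-section areas, V = sum(A) x k.
    """
    body = Ellipsoid([0, 0, 0], semiaxes, label="cell")
    region = SphereRegion([0, 0, 0], float(max(semiaxes)) * 1.5)
    scene = Scene([body], region)
    lo, hi = body.support(np.array([0.0, 0.0, 1.0]))
    k = (hi - lo) / n_sections

    def one(rng):
        stack = make_sur_stack(scene, [0, 0, 1], k, rng)
        areas = []
        for i in range(stack.n_sections):
            img = intersect(scene, stack.spec(i), include_reference=False)
            areas.extend(p.area for p in img.by_label("cell"))
        return est.cavalieri_volume_from_areas(areas, k, "cell").value

    ce, values = empirical_ce(one, n_replicates, seed)
    return {
        "ce": float(ce),
        "ce_percent": float(100 * ce),
        "mean_volume": float(values.mean()),
        "true_volume": body.volume,
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# estimator-constant recovery
# ---------------------------------------------------------------------------


def thickness_factor_simulation(n_hits: int = 100_000, seed=0,
                                R: float = 1.0, t: float = 0.04) -> dict:
    """Recover the pi/4 arithmetic and 8/(3 pi) harmonic thickness factors.

    Hit-weighted IUR sections of a thin plate are generated by rejection: an
    orientation's chance of being kept is proportional to the plate's caliper
    along it, which is exactly how random sections sample a structure.
    """
    rng = as_rng(seed)
    plate = DiscPlate([0, 0, 0], [0, 0, 1], R, t)
    bound = float(np.hypot(R, t / 2.0))
    widths = np.empty(n_hits)
    got = 0
    while got < n_hits:
        n = sectioning.sample_iur_orientation(rng)
        offset = rng.uniform(-bound, bound)
        plane = SectionSpec(n, offset).plane()
        prof = plate.section(plane, 0)
        if prof is None or prof.apparent_width is None or prof.area <= 0:
            continue
        widths[got] = prof.apparent_width
        got += 1
    arith = est.thickness(widths, "arithmetic")
    harm = est.thickness(widths, "harmonic")
    return {
        "mean_width": float(widths.mean()),
        # E[w] = 4t/pi on hit-weighted IUR sections, so t/mean(w) recovers pi/4
        "arithmetic_factor": float(t / widths.mean()),
        "thickness_arithmetic": arith.value,
        "thickness_harmonic": harm.value,
        "true_thickness": t,
        "n_hits": n_hits,
    }


def buffon_length_factor(n_placements: int = 8000, seed=0,
                         radius: float = 0.3, d: float = 0.05) -> dict:
    """Recover the pi/2 Buffon length factor on a circle of known perimeter.

    Randomly rotated and phased line grids cross a closed curve of length B
    on average 2B/(pi d) times, so B / (mean(I) * d) converges to pi/2.
    """
    from .geometry import circle_profile

    rng = as_rng(seed)
    circumference = 2 * np.pi * radius
    fov = (-2 * radius, 2 * radius, -2 * radius, 2 * radius)
    prof = circle_profile("cisterna", 0, np.zeros(2), radius)
    Is = np.empty(n_placements)
    for i in range(n_placements):
        system = make_test_system("line_grid", {"d": d, "iur_rotation": True}, rng)
        total = 0
        for p, m, t0, t1 in system.lines(fov):
            total += len(prof.line_crossings(p, m, t0, t1, membrane_only=False))
        Is[i] = total
    factor = circumference / (Is.mean() * d)
    return {
        "factor": float(factor),
        "expected": float(np.pi / 2.0),
        "mean_I": float(Is.mean()),
        "n_placements": n_placements,
    }


def t_times_sv_product(n_sections: int = 2000, seed=0,
                       R: float = 1.0, t: float = 0.04, d: float = 0.05) -> dict:
    """Recover t * Sv = 2 for a thin plate (flat-plate thickness model).

    IUR sections of a plate inside a spherical container; Sv of the plate
    faces within the plate's own volume is 2/t, so the product with the known
    thickness is the dimensionless constant 2.
    """
    rng = as_rng(seed)
    region = SphereRegion([0, 0, 0], 1.3 * R)
    scene = Scene([DiscPlate([0, 0, 0], [0, 0, 1], R, t)], region)
    records = []
    for i in range(n_sections):
        spec = _iur_plane_in_region(region, rng)
        img = intersect(scene, spec, include_reference=False, image_id=i)
        system = make_test_system("line_grid", {"d": d, "iur_rotation": True}, rng)
        records += probes.count_intersections(img, system, ["cisterna"])
        records += probes.count_points(img, system, ["cisterna"])
    system = make_test_system("line_grid", {"d": d})
    sv = est.sv_lines(records, "cisterna", "cisterna", system)
    return {
        "product": float(t * sv.value),
        "product_se": float(t * sv.se),
        "sv": sv.value,
        "true_sv": 2.0 / t,
        "n_sections": n_sections,
    }


def cisterna_hit_ratio(n_sections: int = 16000, seed=0,
                       R_small: float = 1.0, t: float = 0.04) -> dict:
    """Section-hit ratio of two similar cisternae with radii R and 2R.

    Random sections hit the large disc about twice as often (hits scale with
    mean caliper, i.e. linear size), although its face area is four times
    larger: the documented bias of naive profile counting.
    """
    rng = as_rng(seed)
    region = SphereRegion([0, 0, 0], 3.0 * R_small)
    discs = [
        DiscPlate([0, 0, -0.5], [0, 0, 1], R_small, t, label="cisterna_small"),
        DiscPlate([0, 0, 0.5], [0, 0, 1], 2 * R_small, t, label="cisterna_large"),
    ]
    scene = Scene(discs, region)
    hits = {"cisterna_small": 0, "cisterna_large": 0}
    for _ in range(n_sections):
        spec = _iur_plane_in_region(region, rng)
        img = intersect(scene, spec, include_reference=False)
        for lab in hits:
            hits[lab] += len(img.by_label(lab))
    ratio = hits["cisterna_large"] / max(hits["cisterna_small"], 1)
    return {
        "hit_ratio": float(ratio),
        "area_ratio": 4.0,
        "hits": hits,
        "n_sections": n_sections,
    }


# ---------------------------------------------------------------------------
# unbiasedness suite
# ---------------------------------------------------------------------------


@dataclass
class Recovery:
    estimate: float
    se: float
    truth: float
    n_replicates: int

    @property
    def z(self) -> float:
        return (self.estimate - self.truth) / self.se if self.se > 0 else np.inf

    def within(self, n_se: float = 2.0) -> bool:
        return abs(self.estimate - self.truth) <= n_se * self.se


def vv_recovery(n_replicates: int = 500, seed=0, r: float = 0.8,
                box_side: float = 2.0, d: float = 0.1) -> Recovery:
    """Vv of a sphere in a cube by SUR point counting."""
    rng = as_rng(seed)
    half = box_side / 2.0
    region = Box([-half, -half, -half], [half, half, half])
    scene = Scene([Sphere([0, 0, 0], r, "vesicle")], region)
    truth = scene.ground_truth()["vesicle"].V / region.volume
    ys, xs = [], []
    for i in range(n_replicates):
        stack = make_sur_stack(scene, [0, 0, 1], box_side / 5.0, rng, span="reference")
        P_s = P_r = 0
        for j in range(stack.n_sections):
            img = intersect(scene, stack.spec(j), image_id=j)
            system = make_test_system("point_grid", {"d": d}, rng)
            recs = probes.count_points(img, system, ["vesicle", "cell"])
            P_s += next(r_.P for r_ in recs if r_.label == "vesicle")
            P_r += next(r_.P for r_ in recs if r_.label == "cell")
        ys.append(P_s)
        xs.append(P_r)
    y, x = np.array(ys, float), np.array(xs, float)
    return Recovery(y.sum() / x.sum(), cochran_ratio_se(x, y), truth, n_replicates)


def sv_iur_sphere_recovery(n_replicates: int = 500, seed=0, r: float = 0.8,
                           d: float = 0.08) -> Recovery:
    """S/V of a sphere (3/r) by IUR line-intersection counting."""
    rng = as_rng(seed)
    region = SphereRegion([0, 0, 0], 1.5 * r)
    scene = Scene([Sphere([0, 0, 0], r, "vesicle")], region)
    truth = 3.0 / r
    ys, xs = [], []
    for i in range(n_replicates):
        spec = _iur_plane_in_region(region, rng)
        img = intersect(scene, spec, include_reference=False, image_id=i)
        system = make_test_system("line_grid", {"d": d, "iur_rotation": True}, rng)
        I = probes.count_intersections(img, system, ["vesicle"])[0].I
        P = probes.count_points(img, system, ["vesicle"])[0].P
        ys.append(I)
        xs.append(P)
    y, x = np.array(ys, float), np.array(xs, float)
    scale = 2.0 / d
    return Recovery(scale * y.sum() / x.sum(), scale * cochran_ratio_se(x, y),
                    truth, n_replicates)


def sv_cycloid_plate_recovery(n_replicates: int = 400, seed=0, R: float = 0.8,
                              t: float = 0.05, cycloid_r: float = 0.06) -> Recovery:
    """Sv of an anisotropic plate by vertical sections + cycloid arcs (2/t)."""
    rng = as_rng(seed)
    region = SphereRegion([0, 0, 0], 1.4 * R)
    tilt = np.array([np.sin(0.5), 0.0, np.cos(0.5)])  # plate tilted off vertical
    scene = Scene([DiscPlate([0, 0, 0], tilt, R, t)], region)
    truth = 2.0 / t
    ys, xs = [], []
    for i in range(n_replicates):
        spec = make_vertical_section(scene, [0, 0, 1], rng)
        img = intersect(scene, spec, include_reference=False, image_id=i)
        system = make_test_system("cycloid_array", {"r": cycloid_r}, rng)
        I = probes.count_intersections(img, system, ["cisterna"])[0].I
        P = probes.count_points(img, system, ["cisterna"])[0].P
        ys.append(I)
        xs.append(P)
    y, x = np.array(ys, float), np.array(xs, float)
    scale = 2.0 / (4 * cycloid_r)
    return Recovery(scale * y.sum() / x.sum(), scale * cochran_ratio_se(x, y),
                    truth, n_replicates)


def total_number_recovery(n_seeds: int = 500, seed=0, n_true: int = 500) -> Recovery:
    """Total vesicle number by SUR disector pairs + inverse sampling fraction."""
    rng = as_rng(seed)
    values = np.empty(n_seeds)
    for s in range(n_seeds):
        region = Box([0, 0, 0], [5, 5, 5])
        scene = make_vesicle_population(n_true, 0.065, 0.004, region, rng)
        stack = make_sur_stack(scene, [0, 0, 1], 0.02, rng)
        pairs = sur_pairs(stack.n_sections, 50, rng)
        records = []
        for m, (i, j) in enumerate(pairs):
            a = intersect(scene, stack.spec(i), include_reference=False, image_id=2 * m)
            b = intersect(scene, stack.spec(j), include_reference=False, image_id=2 * m + 1)
            records += probes.count_disector(a, b, None, ["vesicle"])
            records += probes.count_disector(b, a, None, ["vesicle"])
        values[s] = est.total_number(records, 50, "vesicle").value
    return Recovery(float(values.mean()), float(values.std(ddof=1) / np.sqrt(n_seeds)),
                    float(n_true), n_seeds)


def mean_reference_volume_recovery(n_replicates: int = 4000, seed=0,
                                   r_cell: float = 1.5) -> Recovery:
    """Number-weighted mean cell volume by a low-magnification disector.

    A dilute population is emulated by sampling one uniformly placed cell per
    low-magnification field: the reference process is then stationary over
    the counting frame's selection region, so P*a*h / Q- is exactly the mean
    cell volume in expectation (no overlap or boundary artefacts).
    """
    rng = as_rng(seed)
    side = 12.0
    region = Box([0, 0, 0], [side] * 3, label="medium")
    truth = 4.0 / 3.0 * np.pi * r_cell ** 3
    ys, xs = [], []
    # x-y support covers the frame's whole selection region (frame 6x6 at the
    # centre plus the cell radius) so no selection mass is clipped
    inner = Box([1.5, 1.5, 2.0], [10.5, 10.5, 10.0])
    h = 1.0  # ~1/3 of the cell diameter
    for i in range(n_replicates):
        scene = Scene([Sphere(inner.sample(rng, 1)[0], r_cell, "cell")], region)
        # offset window covers the cell's full possible z-support so every
        # volume slice and every top edge is sampled uniformly
        o = rng.uniform(2 - r_cell - h, 10 + r_cell)
        img_s = intersect(scene, SectionSpec([0, 0, 1], o), include_reference=False, image_id=0)
        img_l = intersect(scene, SectionSpec([0, 0, 1], o + h), include_reference=False, image_id=1)
        fx0, fx1, fy0, fy1 = img_s.fov
        cx, cy = 0.5 * (fx0 + fx1), 0.5 * (fy0 + fy1)
        frame = probes.CountingFrame(cx - 3.0, cy - 3.0, 6.0, 6.0, guard=2 * r_cell)
        recs = probes.count_disector(img_s, img_l, frame, ["cell"])
        system = make_test_system("point_grid", {"d": 0.25}, rng)
        P = probes.count_points(img_s, system, ["cell"], frame=frame)[0].P
        ys.append(P)
        xs.append(recs[0].Qminus)
    y, x = np.array(ys, float), np.array(xs, float)
    a = 0.25 ** 2
    return Recovery(a * h * y.sum() / x.sum(), a * h * cochran_ratio_se(x, y),
                    truth, n_replicates)


def star_area_recovery(n_replicates: int = 400, seed=0, R: float = 0.8,
                       t: float = 0.04, d: float = 0.1) -> Recovery:
    """Star area of a convex disc cisterna (recovers pi R^2)."""
    rng = as_rng(seed)
    region = SphereRegion([0, 0, 0], 1.4 * R)
    scene = Scene([DiscPlate([0, 0, 0], [0, 0, 1], R, t)], region)
    truth = np.pi * R * R
    records = []
    for i in range(n_replicates):
        spec = _iur_plane_in_region(region, rng)
        img = intersect(scene, spec, include_reference=False, image_id=i)
        system = make_test_system("line_grid", {"d": d, "iur_rotation": True}, rng)
        records.append(probes.measure_point_sampled_intercepts(img, system, "cisterna"))
    ys = np.array([sum(l * l for l in r.intercepts) for r in records])
    xs = np.array([len(r.intercepts) for r in records], dtype=float)
    c = np.pi / 3.0
    return Recovery(c * ys.sum() / xs.sum(), c * cochran_ratio_se(xs, ys),
                    truth, n_replicates)


def composition_two_disc(n_sections: int = 1500, seed=0, R: float = 0.8,
                         t: float = 0.04, spacing: float = 0.15) -> dict:
    """Composition fractions of a two-cisterna stack with radii R and 2R.

    The envelope face is covered by both cisternae over the inner quarter of
    its area (annulus geometry), so the expected fractions are {1: 3/4,
    2: 1/4} despite the naive profile-hit ratio being only ~2.
    """
    rng = as_rng(seed)
    region = SphereRegion([0, 0, 0], 4.0 * R)
    scene = make_golgi_stack(2, [2 * R, R], t, spacing, region=region)
    records = []
    for i in range(n_sections):
        spec = _iur_plane_in_region(region, rng)
        img = intersect(scene, spec, include_reference=False, image_id=i)
        if not img.by_label("cisterna"):
            continue
        system = make_test_system("line_grid", {"d": 0.1, "iur_rotation": True}, rng)
        rec = probes.count_orthogonal_cisternae(img, system, "cisterna")
        if rec.ortho_counts:
            records.append(rec)
    comp = est.composition_fractions(records, "cisterna")
    return {
        "fractions": comp.extra["fractions"],
        "n_hits": comp.extra["n_hits"],
        "expected": {1: 0.75, 2: 0.25},
    }


def lvw_vs_lines_stabilization(n_experiments: int = 15, seed=0,
                               n_lvw: int = 12, n_lines: int = 20) -> dict:
    """Compare how fast LVW and straight-IUR-line Sv estimates stabilise.

    On phantoms with several dispersed cisternal stacks (the drug-fragmented
    regime), the per-image intersection/point ratio of straight lines varies
    with the obliquity of each section, while local vertical windows use only
    near-orthogonally cut profiles.  The LVW estimate therefore reaches a
    given relative SE with fewer images; the comparison mirrors a 12-image
    LVW series against a 20-image line series.
    """
    rng = as_rng(seed)
    lvw_cvs, line_cvs = [], []
    for _ in range(n_experiments):
        region = SphereRegion([0, 0, 0], 2.2)
        prims = []
        for c in ([1.0, 0, 0], [-0.8, 0.6, 0], [0, -0.9, 0.7]):
            axis = sectioning.sample_iur_orientation(rng)
            stack = make_golgi_stack(3, [0.5] * 3, 0.05, 0.12, axis, c, region=region)
            prims.extend(stack.primitives)
        scene = Scene(prims, region)
        images = [
            intersect(scene, _iur_plane_in_region(region, rng),
                      include_reference=False, image_id=i)
            for i in range(n_lines)
        ]
        lvw = est.sv_local_vertical_window(images[:n_lvw], "cisterna", seed=rng)
        ys, xs = [], []
        for img in images:
            system = make_test_system("line_grid", {"d": 0.05, "iur_rotation": True}, rng)
            ys.append(probes.count_intersections(img, system, ["cisterna"])[0].I)
            xs.append(probes.count_points(img, system, ["cisterna"])[0].P)
        system = make_test_system("line_grid", {"d": 0.05})
        lines = est.sv_lines(
            [probes.CountRecord(i, "cisterna", I=y) for i, y in enumerate(ys)]
            + [probes.CountRecord(i, "cisterna", P=x) for i, x in enumerate(xs)],
            "cisterna", "cisterna", system)
        if lvw.value and np.isfinite(lvw.value) and lines.value and np.isfinite(lines.value):
            lvw_cvs.append(lvw.se / lvw.value)
            line_cvs.append(lines.se / lines.value)
    return {
        "lvw_cv": float(np.mean(lvw_cvs)),
        "lines_cv": float(np.mean(line_cvs)),
        "n_experiments": len(lvw_cvs),
        "n_images": {"lvw": n_lvw, "lines": n_lines},
    }


def reference_trap_demo(n_replicates: int = 300, seed=0) -> dict:
    """Halving the reference volume doubles Vv but leaves absolute V unchanged."""
    rng = as_rng(seed)
    r = 0.5
    sphere = Sphere([0, 0, 0], r, "vesicle")

    def run(half: float):
        region = Box([-half] * 3, [half] * 3)
        scene = Scene([sphere], region)
        ys, xs, vols = [], [], []
        for i in range(n_replicates):
            stack = make_sur_stack(scene, [0, 0, 1], 2 * half / 5.0, rng, span="reference")
            P_s = P_r = 0
            areas = []
            for j in range(stack.n_sections):
                img = intersect(scene, stack.spec(j), image_id=j)
                system = make_test_system("point_grid", {"d": 0.08}, rng)
                recs = probes.count_points(img, system, ["vesicle", "cell"])
                P_s += next(rr.P for rr in recs if rr.label == "vesicle")
                P_r += next(rr.P for rr in recs if rr.label == "cell")
                areas.extend(p.area for p in img.by_label("vesicle"))
            ys.append(P_s)
            xs.append(P_r)
            vols.append(est.cavalieri_volume_from_areas(areas, stack.spacing, "vesicle").value)
        y, x = np.array(ys, float), np.array(xs, float)
        return y.sum() / x.sum(), float(np.mean(vols)), float(np.std(vols, ddof=1) / np.sqrt(len(vols)))

    big_half = 1.0  # reference volume 8 um^3
    small_half = big_half / 2 ** (1 / 3)  # half the reference volume
    vv_big, v_big, se_big = run(big_half)
    vv_small, v_small, se_small = run(small_half)
    return {
        "vv_ratio": float(vv_small / vv_big),
        "expected_vv_ratio": 2.0,
        "v_big": v_big, "v_small": v_small,
        "v_se_big": se_big, "v_se_small": se_small,
        "true_volume": sphere.volume,
    }
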