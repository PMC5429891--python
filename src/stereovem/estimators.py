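"""Design-based stereological estimators.

Every ratio estimate pools numerators and denominators over images (ratio of
sums), and standard errors of ratios follow the classical Cochran ratio
estimator.  Quantities and units: Vv (dimensionless), Sv (1/um), Nv (1/um^3),
V (um^3), S (um^2), N (count), star area (um^2), thickness (um).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .phantom import as_rng
from .precision import cochran_ratio_se
from .probes import (
    CountRecord,
    CountingFrame,
    apply_counting_frame,
    count_points,
    make_test_system,
)
from .sectioning import SectionImage, SectionStack, intersect

__all__ = [
    "Estimate",
    "vv_point_count",
    "sv_lines",
    "sv_local_vertical_window",
    "cavalieri_volume",
    "cavalieri_volume_from_areas",
    "nv_disector",
    "total_number",
    "one_section_disector_workup",
    "mean_reference_volume",
    "star_area",
    "composition_fractions",
    "thickness",
    "total_surface",
    "select_cells_by_number",
    "classify_profile",
    "ratio_of_counts",
]


@dataclass
class Estimate:
    quantity: str
    value: float
    units: str
    se: float = 0.0
    n_images: int = 0
    method: str = ""
    label: str = ""
    reference: str = ""
    flags: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("standard error must be non-negative")

    def to_row(self) -> dict:
        return {
            "quantity": self.quantity,
            "label": self.label,
            "reference": self.reference,
            "value": self.value,
            "units": self.units,
            "se": self.se,
            "n_images": self.n_images,
            "method": self.method,
            "flags": ";".join(self.flags),
        }


def _per_image(records: Sequence[CountRecord], label: str, attr: str) -> dict:
    out: dict = {}
    for r in records:
        if r.label == label:
            out[r.image_id] = out.get(r.image_id, 0) + getattr(r, attr)
    return out


def _paired_arrays(records, num_label, den_label, num_attr, den_attr):
    ys = _per_image(records, num_label, num_attr)
    xs = _per_image(records, den_label, den_attr)
    ids = sorted(set(ys) | set(xs))
    y = np.array([ys.get(i, 0) for i in ids], dtype=float)
    x = np.array([xs.get(i, 0) for i in ids], dtype=float)
    return y, x


def _ratio_with_se(y, x):
    if x.sum() <= 0:
        return np.nan, np.nan
    R = y.sum() / x.sum()
    se = cochran_ratio_se(x, y) if len(x) >= 2 else 0.0
    return R, se


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


def vv_point_count(records, structure: str, reference: str) -> Estimate:
    """Volume fraction Vv = sum(P_structure) / sum(P_reference)."""
    y, x = _paired_arrays(records, structure, reference, "P", "P")
    R, se = _ratio_with_se(y, x)
    flags = [] if x.sum() > 0 else ["undefined: zero reference points"]
    return Estimate("Vv", R, "dimensionless", se if np.isfinite(se) else 0.0,
                    len(x), "point_count", structure, reference, flags)


def sv_lines(records, structure: str, reference: str, system) -> Estimate:
    """Surface density Sv = 2 * sum(I) / L with L = sum(P_reference) * l_p.

    Requires isotropic line encounters: IUR sections with rotated line grids,
    or vertical sections probed with cycloid arcs.
    """
    y, x = _paired_arrays(records, structure, reference, "I", "P")
    if x.sum() <= 0:
        return Estimate("Sv", np.nan, "1/um", 0.0, len(x), "lines", structure,
                        reference, ["undefined: zero reference points"])
    R, se = _ratio_with_se(y, x)
    scale = 2.0 / system.l_p
    return Estimate("Sv", scale * R, "1/um", scale * se, len(x),
                    "cycloids" if system.kind == "cycloid_array" else "iur_lines",
                    structure, reference)


def sv_local_vertical_window(
    images: Sequence[SectionImage],
    label: str = "cisterna",
    tau: float = 0.25,
    cycloid_r: float = 0.05,
    point_d: float = 0.05,
    seed=None,
) -> Estimate:
    """Local vertical window Sv along the cis-trans axis of stack profiles.

    Profiles with apparent width within (1+tau) of the thinnest observed
    width are "chosen" as orthogonally sectioned stacks; the local horizontal
    is the profile mid-line, the local vertical the in-plane stack axis, and
    cycloids (minor axis along the local vertical) estimate Sv = 2I/L.
    """
    rng = as_rng(seed)
    widths = [p.apparent_width for img in images for p in img.by_label(label)
              if p.apparent_width is not None]
    if not widths:
        return Estimate("Sv", np.nan, "1/um", 0.0, 0, "lvw", label, label,
                        ["no profile passes selection"])
    t_min = min(widths)

    def run(tau_val):
        ys, xs = [], []
        n_sel = 0
        for img in images:
            I_tot = P_tot = 0
            for prof in img.by_label(label):
                if prof.apparent_width is None or prof.apparent_width > (1 + tau_val) * t_min:
                    continue
                n_sel += 1
                sys_c = make_test_system("cycloid_array", {"r": cycloid_r}, rng)
                sys_p = make_test_system("point_grid", {"d": point_d}, rng)
                bx0, bx1, by0, by1 = prof.bbox
                pad = 4 * cycloid_r
                window = (bx0 - pad, bx1 + pad, by0 - pad, by1 + pad)
                vert = prof.axis_dir  # local cis-trans direction
                for arc in sys_c.arcs(window, vertical=vert):
                    I_tot += prof.curve_crossings(arc)
                pts = sys_p.points(window)
                # line length inside the reference (the profile region itself)
                P_tot += int(prof.contains(pts).sum()) if len(pts) else 0
            ys.append(I_tot)
            xs.append(P_tot)
        y, x = np.array(ys, float), np.array(xs, float)
        if x.sum() <= 0:
            return np.nan, np.nan, n_sel
        R, se = _ratio_with_se(y, x)
        # L per point: cycloid length per cell area, expressed per point area
        l_per_area = (4 * cycloid_r) / (np.pi * cycloid_r * 4 * cycloid_r)
        scale = 2.0 / (point_d ** 2 * l_per_area)
        return scale * R, scale * (se if np.isfinite(se) else 0.0), n_sel

    value, se, n_sel = run(tau)
    if n_sel == 0:
        return Estimate("Sv", np.nan, "1/um", 0.0, len(images), "lvw", label, label,
                        ["no profile passes selection"])
    lo, _, _ = run(max(tau - 0.1, 0.0))
    hi, _, _ = run(tau + 0.1)
    return Estimate("Sv", value, "1/um", se, len(images), "lvw", label, label,
                    extra={"tau": tau, "sensitivity": {"tau_minus": lo, "tau_plus": hi},
                           "n_selected": n_sel})


# ---------------------------------------------------------------------------
# volume and number
# ---------------------------------------------------------------------------


def cavalieri_volume(records, k: float, a: float, label: str = "cell") -> Estimate:
    """Cavalieri volume V = sum(P) * a * k from point counts on an SUR stack."""
    if k is None or k <= 0:
        raise ValueError("section spacing k is required")
    per = _per_image(records, label, "P")
    P = sum(per.values())
    return Estimate("V", P * a * k, "um^3", 0.0, len(per), "cavalieri", label, label)


def cavalieri_volume_from_areas(areas: Sequence[float], k: float, label: str = "cell") -> Estimate:
    """Cavalieri volume V = sum(A) * k from exact (or segmented) profile areas."""
    if k <= 0:
        raise ValueError("section spacing k is required")
    areas = np.asarray(list(areas), dtype=float)
    return Estimate("V", float(areas.sum() * k), "um^3", 0.0, len(areas),
                    "cavalieri_areas", label, label)


def nv_disector(records, a: float, h: float, structure: str, reference: str) -> Estimate:
    """Numerical density Nv = sum(Q-) / (sum(P) * a * h)."""
    if h <= 0:
        raise ValueError("disector height h must be positive")
    y, x = _paired_arrays(records, structure, reference, "Qminus", "P")
    if x.sum() <= 0:
        return Estimate("Nv", np.nan, "1/um^3", 0.0, len(x), "disector",
                        structure, reference, ["undefined: zero reference volume"])
    R, se = _ratio_with_se(y, x)
    scale = 1.0 / (a * h)
    flags = ["low-count"] if y.sum() == 0 else []
    return Estimate("Nv", scale * R, "1/um^3", scale * (se if np.isfinite(se) else 0.0),
                    len(x), "disector", structure, reference, flags)


def total_number(records, spacing: int, label: str = "vesicle",
                 both_directions: bool = True) -> Estimate:
    """Total number N = sum(Q-) * spacing / directions (inverse sampling fraction).

    ``spacing`` is the number of sections between successive disector pairs;
    counting both directions halves the multiplier because each direction
    captures a different set of particle edges.
    """
    if spacing is None or spacing <= 0:
        raise ValueError("pair spacing is required")
    per = _per_image(records, label, "Qminus")
    q = np.array([per[i] for i in sorted(per)], dtype=float)
    directions = 2 if both_directions else 1
    mult = spacing / directions
    value = q.sum() * mult
    se = mult * np.sqrt(len(q)) * q.std(ddof=1) if len(q) >= 2 else 0.0
    return Estimate("N", value, "count", se, len(q), "fractionator_disector", label, label)


def one_section_disector_workup(
    scene,
    stack: SectionStack,
    label: str = "vesicle",
    frame: Optional[CountingFrame] = None,
    threshold: float = 0.80,
    min_profiles: int = 100,
) -> dict:
    """Check whether a one-section disector is admissible for this regime.

    Sweeps adjacent section pairs, measuring the fraction of frame-selected
    profiles that disappear in the neighbouring section.  The shortcut is
    applicable when a large majority vanish, i.e. when the section spacing is
    comparable to the particle size; for ideal sections spaced h through
    particles of diameter d the fraction is min(h/d, 1), so the canonical
    60 nm vesicle / 50 nm section regime sits at 5/6 and the default
    threshold is 0.80.  If the imaging depth is below the physical
    thickness, particle waists may be invisible and the verdict carries a
    waist-loss warning.
    """
    from .sectioning import SectionSpec, project_slab

    n_sampled = n_gone = 0
    if stack.h_img > 0:
        images = [
            project_slab(scene, stack.spec(i), image_id=i, include_reference=False)
            for i in range(stack.n_sections)
        ]
    else:
        images = [
            intersect(scene, SectionSpec(stack.normal, float(stack.offsets[i])),
                      include_reference=False, image_id=i)
            for i in range(stack.n_sections)
        ]
    for i in range(stack.n_sections - 1):
        profs = images[i].by_label(label)
        if frame is not None:
            profs = apply_counting_frame(profs, frame)
        nxt = {p.parent_id for p in images[i + 1].by_label(label)}
        n_sampled += len(profs)
        n_gone += sum(1 for p in profs if p.parent_id not in nxt)
    result = {
        "fraction_disappearing": n_gone / n_sampled if n_sampled else np.nan,
        "n_sampled": n_sampled,
        "flags": [],
    }
    if n_sampled < min_profiles:
        result["verdict"] = "insufficient_data"
        return result
    frac = result["fraction_disappearing"]
    if frac >= threshold:
        result["verdict"] = "applicable"
    else:
        result["verdict"] = "not_applicable"
        result["flags"].append("sections much thinner than particles; "
                               "consider ministack_projection")
    if 0 < stack.h_img < stack.h_phys:
        result["flags"].append("imaging depth below physical thickness: "
                               "waist-loss risk")
    return result


def mean_reference_volume(records, a: float, h: float, label: str = "cell") -> Estimate:
    """Number-weighted mean volume v = sum(P) * a * h / sum(Q-)."""
    y, x = _paired_arrays(records, label, label, "P", "Qminus")
    if x.sum() <= 0:
        return Estimate("v_mean", np.nan, "um^3", 0.0, len(x), "reference_disector",
                        label, label, ["undefined: zero Q-"])
    R, se = _ratio_with_se(y, x)
    scale = a * h
    return Estimate("v_mean", scale * R, "um^3", scale * (se if np.isfinite(se) else 0.0),
                    len(x), "reference_disector", label, label)


# ---------------------------------------------------------------------------
# specialised estimators
# ---------------------------------------------------------------------------


def star_area(records, label: str = "cisterna") -> Estimate:
    """Mean star area a* = (pi/3) * mean(l0^2) from point-sampled intercepts.

    Length-weighted intercept sampling plus the planar chord-power identity
    (integral of l^3 over lines equals 3 A^2) make this the area "seen" from
    a random point of the structure; it drops when cisternae fragment.
    """
    ys, xs = [], []
    n_tot = 0
    for r in records:
        if r.label != label:
            continue
        ls = np.asarray(r.intercepts, dtype=float)
        ys.append(float(np.sum(ls ** 2)))
        xs.append(float(len(ls)))
        n_tot += len(ls)
    if n_tot == 0:
        return Estimate("star_area", np.nan, "um^2", 0.0, 0, "point_sampled_intercepts",
                        label, label, ["no intercepts"])
    y, x = np.array(ys), np.array(xs)
    R, se = _ratio_with_se(y, x)
    c = np.pi / 3.0
    return Estimate("star_area", c * R, "um^2", c * (se if np.isfinite(se) else 0.0),
                    len(y), "point_sampled_intercepts", label, label)


def composition_fractions(records, label: str = "cisterna") -> Estimate:
    """Distribution of cisternae-per-location over the stack ribbon face."""
    counts: dict[int, int] = {}
    n_img = 0
    for r in records:
        if r.label != label or not r.ortho_counts:
            continue
        n_img += 1
        for c in r.ortho_counts:
            counts[int(c)] = counts.get(int(c), 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no orthogonal counts recorded")
    fractions = {k: v / total for k, v in sorted(counts.items())}
    assert abs(sum(fractions.values()) - 1.0) < 1e-9
    return Estimate("composition", np.nan, "fractions", 0.0, n_img,
                    "orthogonal_counts", label, label,
                    extra={"fractions": fractions, "n_hits": total})


def thickness(widths=None, method: str = "arithmetic", sv: Optional[float] = None) -> Estimate:
    """Cisternal/stack thickness from apparent widths or from Sv.

    arithmetic:  t = (pi/4) * mean(w)          (E[w] = 4t/pi on IUR hits)
    harmonic:    t = (8/(3*pi)) * harmonic_mean(w)
    sv:          t = 2 / Sv                     (flat-plate model)
    """
    if method == "sv":
        if sv is None or sv <= 0:
            raise ValueError("sv method needs a positive Sv")
        return Estimate("thickness", 2.0 / sv, "um", 0.0, 0, "2_over_sv")
    w = np.asarray(list(widths), dtype=float)
    if len(w) == 0 or np.any(w <= 0):
        raise ValueError("widths must be positive")
    if method == "arithmetic":
        val = (np.pi / 4.0) * w.mean()
        se = (np.pi / 4.0) * w.std(ddof=1) / np.sqrt(len(w)) if len(w) > 1 else 0.0
    elif method == "harmonic":
        inv = 1.0 / w
        hm = 1.0 / inv.mean()
        val = (8.0 / (3.0 * np.pi)) * hm
        se_inv = inv.std(ddof=1) / np.sqrt(len(w)) if len(w) > 1 else 0.0
        se = (8.0 / (3.0 * np.pi)) * se_inv * hm ** 2  # delta method
    else:
        raise ValueError(f"unknown thickness method {method!r}")
    return Estimate("thickness", float(val), "um", float(se), 0, method)


def total_surface(sv_estimate: Estimate, v_estimate: Estimate) -> Estimate:
    """Total surface S = Sv * V with first-order (independence) error propagation."""
    if sv_estimate.units != "1/um" or v_estimate.units != "um^3":
        raise ValueError("unit mismatch: need Sv in 1/um and V in um^3")
    s = sv_estimate.value * v_estimate.value
    if sv_estimate.value != 0 and v_estimate.value != 0:
        rel = np.sqrt((sv_estimate.se / sv_estimate.value) ** 2
                      + (v_estimate.se / v_estimate.value) ** 2)
        se = abs(s) * rel
    else:
        se = 0.0
    return Estimate("S", s, "um^2", se,
                    max(sv_estimate.n_images, v_estimate.n_images),
                    "sv_times_v", sv_estimate.label, v_estimate.label)


def select_cells_by_number(scene, stack: SectionStack, frame: Optional[CountingFrame],
                           label: str = "cell") -> list[int]:
    """Cardinality-based cell selection by an end-of-stack disector.

    The last section is the look-up and the last-but-one the sampling
    section; frame-selected profiles that disappear are the selected cells.
    Selection probability is independent of cell size.
    """
    if stack.n_sections < 2:
        raise ValueError("stack must have at least 2 sections")
    sampling = intersect(scene, stack.spec(stack.n_sections - 2),
                         include_reference=False, image_id=stack.n_sections - 2)
    lookup = intersect(scene, stack.spec(stack.n_sections - 1),
                       include_reference=False, image_id=stack.n_sections - 1)
    profs = sampling.by_label(label)
    if frame is not None:
        profs = apply_counting_frame(profs, frame)
    lookup_parents = {p.parent_id for p in lookup.by_label(label)}
    return sorted(p.parent_id for p in profs if p.parent_id not in lookup_parents)


def classify_profile(width: float, long_axis: float, short_axis: float,
                     vesicle_band=(0.055, 0.075), circular_tol: float = 1.5) -> str:
    """Identification criteria for sectioned profiles.

    A cisterna is a membrane-bound profile at most 60 nm wide whose long axis
    exceeds its short axis threefold; a vesicle is near-circular with a
    diameter in the configured band (60-70 nm class by default).
    """
    if width <= 0 or long_axis <= 0 or short_axis <= 0:
        raise ValueError("profile dimensions must be positive")
    if long_axis < short_axis:
        raise ValueError("long axis must be >= short axis")
    ratio = long_axis / short_axis
    in_band = vesicle_band[0] <= long_axis <= vesicle_band[1]
    if in_band and ratio >= 3.0:
        raise ValueError("inconsistent geometry: vesicle-sized diameter with "
                         "cisterna-like axis ratio")
    if width <= 0.060 and ratio >= 3.0:
        return "cisterna"
    if in_band and ratio <= circular_tol:
        return "vesicle"
    return "unclassified"


def ratio_of_counts(records, label_a: str, label_b: str) -> Estimate:
    """Number ratio of two structures from Q- counts in the same disectors."""
    y, x = _paired_arrays(records, label_a, label_b, "Qminus", "Qminus")
    if x.sum() <= 0:
        return Estimate("ratio", np.nan, "dimensionless", 0.0, len(x),
                        "count_ratio", label_a, label_b, ["undefined: zero denominator"])
    R, se = _ratio_with_se(y, x)
    return Estimate("ratio", R, "dimensionless", se if np.isfinite(se) else 0.0,
                    len(x), "count_ratio", label_a, label_b)
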