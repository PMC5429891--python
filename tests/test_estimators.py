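"""Estimator arithmetic and reduced-scale recovery checks."""

import numpy as np
import pytest

from stereovem import estimators as est
from stereovem import validation as V
from stereovem.phantom import Box, DiscPlate, Scene, Sphere, SphereRegion, make_vesicle_population
from stereovem.probes import CountRecord, TestSystem, make_test_system, sur_pairs
from stereovem.sectioning import SectionSpec, intersect, make_sur_stack


def rec(image_id, label, **kw):
    return CountRecord(image_id, label, **kw)


class TestPrintedFormulaArithmetic:
    def test_vv(self):
        records = [rec(0, "golgi", P=50), rec(0, "cell", P=200),
                   rec(1, "golgi", P=0), rec(1, "cell", P=0)]
        assert est.vv_point_count(records, "golgi", "cell").value == pytest.approx(0.25)

    def test_vv_identity(self):
        records = [rec(0, "cell", P=80), rec(1, "cell", P=20)]
        assert est.vv_point_count(records, "cell", "cell").value == pytest.approx(1.0)

    def test_vv_zero_reference_flagged(self):
        out = est.vv_point_count([rec(0, "golgi", P=5), rec(0, "cell", P=0)], "golgi", "cell")
        assert np.isnan(out.value) and out.flags

    def test_sv(self):
        # I=100 with L = 10 um of test line gives Sv = 20 per um
        records = [rec(0, "golgi", I=100), rec(0, "cell", P=100)]
        system = TestSystem(kind="line_grid", d=0.1)
        out = est.sv_lines(records, "golgi", "cell", system)
        assert out.value == pytest.approx(2 * 100 / (100 * 0.1))

    def test_cavalieri(self):
        records = [rec(i, "cell", P=p) for i, p in enumerate([4, 9, 9, 4])]
        out = est.cavalieri_volume(records, k=0.5, a=0.25)
        assert out.value == pytest.approx(3.25)

    def test_cavalieri_empty_stack(self):
        assert est.cavalieri_volume([], k=0.5, a=0.25).value == 0.0

    def test_cavalieri_requires_spacing(self):
        with pytest.raises(ValueError):
            est.cavalieri_volume([], k=None, a=0.25)

    def test_nv_disector(self):
        records = [rec(0, "vesicle", Qminus=5), rec(0, "cell", P=100)]
        out = est.nv_disector(records, a=0.01, h=0.1, structure="vesicle", reference="cell")
        assert out.value == pytest.approx(50.0)

    def test_nv_zero_counts_flagged_valid(self):
        records = [rec(0, "vesicle", Qminus=0), rec(0, "cell", P=100)]
        out = est.nv_disector(records, 0.01, 0.1, "vesicle", "cell")
        assert out.value == 0.0 and "low-count" in out.flags

    def test_total_number_worked_example(self):
        # 40 edges, pairs every 50 sections, both directions: 40 x 25 = 1000
        records = [rec(i, "vesicle", Qminus=q) for i, q in enumerate([8, 8, 8, 8, 8])]
        out = est.total_number(records, spacing=50, both_directions=True)
        assert out.value == pytest.approx(1000.0)

    def test_mean_reference_volume(self):
        records = [rec(0, "cell", P=400, Qminus=4)]
        out = est.mean_reference_volume(records, a=1.0, h=5.0)
        assert out.value == pytest.approx(500.0)

    def test_thickness_from_sv(self):
        assert est.thickness(method="sv", sv=50.0).value == pytest.approx(0.04)

    def test_star_area_degenerate(self):
        records = [rec(0, "cisterna", intercepts=[0.3] * 10)]
        assert est.star_area(records).value == pytest.approx(np.pi / 3 * 0.09)

    def test_total_surface(self):
        sv = est.Estimate("Sv", 20.0, "1/um", 1.0)
        v = est.Estimate("V", 3.0, "um^3", 0.1)
        out = est.total_surface(sv, v)
        assert out.value == pytest.approx(60.0)
        assert out.se == pytest.approx(60 * np.hypot(1 / 20, 0.1 / 3))

    def test_total_surface_zero_volume(self):
        out = est.total_surface(est.Estimate("Sv", 20.0, "1/um"),
                                est.Estimate("V", 0.0, "um^3"))
        assert out.value == 0.0

    def test_total_surface_unit_mismatch(self):
        with pytest.raises(ValueError):
            est.total_surface(est.Estimate("Sv", 20.0, "um"),
                              est.Estimate("V", 3.0, "um^3"))

    def test_ratio_of_counts(self):
        records = [rec(0, "a", Qminus=30), rec(0, "b", Qminus=10)]
        assert est.ratio_of_counts(records, "a", "b").value == pytest.approx(3.0)

    def test_ratio_zero_denominator_flagged(self):
        out = est.ratio_of_counts([rec(0, "a", Qminus=3), rec(0, "b", Qminus=0)], "a", "b")
        assert np.isnan(out.value) and out.flags

    def test_composition_trivial(self):
        records = [rec(0, "cisterna", ortho_counts=[5] * 12)]
        out = est.composition_fractions(records)
        assert out.extra["fractions"] == {5: 1.0}

    def test_composition_empty_rejected(self):
        with pytest.raises(ValueError):
            est.composition_fractions([rec(0, "cisterna")])


class TestClassifier:
    def test_band_is_cisterna(self):
        assert est.classify_profile(0.04, 0.5, 0.04) == "cisterna"

    def test_circle_in_band_is_vesicle(self):
        assert est.classify_profile(0.065, 0.065, 0.065) == "vesicle"

    def test_inconsistent_geometry_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            est.classify_profile(0.02, 0.065, 0.065 / 3.5)

    def test_unclassified(self):
        assert est.classify_profile(0.2, 0.4, 0.3) == "unclassified"


class TestThicknessEstimators:
    def test_constants_on_simulated_widths(self):
        out = V.thickness_factor_simulation(30_000, seed=5)
        assert out["thickness_arithmetic"] == pytest.approx(out["true_thickness"], rel=0.03)
        assert out["thickness_harmonic"] == pytest.approx(out["true_thickness"], rel=0.03)
        # the two estimators agree with each other
        assert out["thickness_arithmetic"] == pytest.approx(out["thickness_harmonic"], rel=0.03)

    def test_nonpositive_widths_rejected(self):
        with pytest.raises(ValueError):
            est.thickness([0.1, -0.2], "arithmetic")


class TestWorkupAndSelection:
    def test_one_section_disector_regimes(self):
        scene = make_vesicle_population(400, 0.060, 0.0, Box([0, 0, 0], [2, 2, 2]), seed=2)
        thick = est.one_section_disector_workup(
            scene, make_sur_stack(scene, [0, 0, 1], 0.050, seed=3), "vesicle")
        thin = est.one_section_disector_workup(
            scene, make_sur_stack(scene, [0, 0, 1], 0.005, seed=3), "vesicle")
        assert thick["verdict"] == "applicable"
        assert thin["verdict"] == "not_applicable"
        assert any("ministack" in f for f in thin["flags"])

    def test_waist_loss_flagged_for_shallow_imaging(self):
        scene = make_vesicle_population(300, 0.060, 0.0, Box([0, 0, 0], [2, 2, 2]), seed=2)
        stack = make_sur_stack(scene, [0, 0, 1], 0.050, seed=3, h_phys=0.05, h_img=0.005)
        out = est.one_section_disector_workup(scene, stack, "vesicle")
        assert any("waist" in f for f in out["flags"])

    def test_insufficient_data_verdict(self):
        scene = make_vesicle_population(3, 0.060, 0.0, Box([0, 0, 0], [2, 2, 2]), seed=2)
        stack = make_sur_stack(scene, [0, 0, 1], 0.050, seed=3)
        out = est.one_section_disector_workup(scene, stack, "vesicle")
        assert out["verdict"] == "insufficient_data"

    def test_cell_selection_is_cardinality_not_size(self, rng):
        """Bidisperse cells with matched vertical top-edge distributions are
        end-disector-selected at equal frequency (cardinality, not size),
        while naive single-section hits scale with cell diameter."""
        from stereovem.sectioning import SectionStack

        freq = {"small": 0, "large": 0}
        naive = {"small": 0, "large": 0}
        for _ in range(2000):
            tops = rng.uniform(6, 11, 2)  # same vertical support for both
            scene = Scene(
                [Sphere([rng.uniform(2, 10), rng.uniform(2, 10), tops[0] - 0.5],
                        0.5, "small"),
                 Sphere([rng.uniform(2, 10), rng.uniform(2, 10), tops[1] - 1.5],
                        1.5, "large")],
                Box([0, 0, 0], [12, 12, 12]),
            )
            # 20 sections at 0.5 um with random phase: the end gap falls
            # uniformly inside the cells' top-edge support
            stack = SectionStack(np.array([0, 0, 1.0]), float(rng.uniform(0, 0.5)),
                                 0.5, 20)
            for lab in freq:
                freq[lab] += len(est.select_cells_by_number(scene, stack, None, lab))
            img = intersect(scene, SectionSpec([0, 0, 1], rng.uniform(2, 11)),
                            include_reference=False)
            for lab in naive:
                naive[lab] += len(img.by_label(lab))
        assert freq["large"] / freq["small"] == pytest.approx(1.0, abs=0.25)
        assert naive["large"] / naive["small"] > 1.5  # profile counts are size biased

    def test_short_stack_rejected(self):
        scene = Scene([Sphere([1, 1, 1], 0.3, "cell")], Box([0, 0, 0], [2, 2, 2]))
        from stereovem.sectioning import SectionStack
        stack = SectionStack(np.array([0, 0, 1.0]), 0.0, 0.5, 1)
        with pytest.raises(ValueError):
            est.select_cells_by_number(scene, stack, None)


class TestRecoveryReduced:
    """Reduced-replicate unbiasedness checks (full scale in acceptance)."""

    def test_mean_volume_is_number_weighted(self, rng):
        """Bidisperse cells: the disector recovers the number-weighted mean
        volume, not the volume-weighted one."""
        r1, r2 = 1.0, 2.0
        v1, v2 = 4 / 3 * np.pi * r1 ** 3, 4 / 3 * np.pi * r2 ** 3
        number_weighted = (v1 + v2) / 2
        volume_weighted = (v1 ** 2 + v2 ** 2) / (v1 + v2)
        ys, xs = [], []
        for _ in range(500):
            scene = Scene(
                [Sphere(rng.uniform(3, 9, 3), r1, "cell"),
                 Sphere(rng.uniform(3, 9, 3), r2, "cell")],
                Box([0, 0, 0], [12, 12, 12]),
            )
            h = 0.8
            o = rng.uniform(0, 12 - h)
            img_s = intersect(scene, SectionSpec([0, 0, 1], o), include_reference=False)
            img_l = intersect(scene, SectionSpec([0, 0, 1], o + h), include_reference=False)
            from stereovem.probes import count_disector, count_points
            q = count_disector(img_s, img_l, None, ["cell"])[0].Qminus
            system = make_test_system("point_grid", {"d": 0.4}, rng)
            P = count_points(img_s, system, ["cell"])[0].P
            ys.append(P)
            xs.append(q)
        vbar = 0.4 ** 2 * 0.8 * np.sum(ys) / np.sum(xs)
        assert vbar == pytest.approx(number_weighted, rel=0.15)
        assert abs(vbar - number_weighted) < abs(vbar - volume_weighted)

    def test_star_area_drops_under_fragmentation(self, rng):
        """Splitting a cisterna into four discs of equal total area lowers
        the star area (the connectivity readout)."""
        whole = V.star_area_recovery(150, seed=11, R=0.8)
        # four discs of radius R/2 at separated sites: same total face area
        region = SphereRegion([0, 0, 0], 2.5)
        frags = Scene(
            [DiscPlate(c, [0, 0, 1], 0.4, 0.04)
             for c in ([1, 1, 0], [-1, 1, 0], [1, -1, 0], [-1, -1, 0])],
            region,
        )
        records = []
        from stereovem.probes import measure_point_sampled_intercepts
        for i in range(150):
            spec = V._iur_plane_in_region(region, rng)
            img = intersect(frags, spec, include_reference=False, image_id=i)
            system = make_test_system("line_grid", {"d": 0.1, "iur_rotation": True}, rng)
            records.append(measure_point_sampled_intercepts(img, system, "cisterna"))
        frag_star = est.star_area(records)
        assert frag_star.value < whole.estimate
        # fragments recover their own (smaller) disc area
        assert frag_star.value == pytest.approx(np.pi * 0.4 ** 2, rel=0.15)

    def test_lvw_recovers_plate_sv(self, rng):
        from stereovem.phantom import make_golgi_stack

        reg = SphereRegion([0, 0, 0], 1.4)
        scene = make_golgi_stack(3, [0.7] * 3, 0.05, 0.12, region=reg)
        images = [
            intersect(scene, V._iur_plane_in_region(reg, rng),
                      include_reference=False, image_id=i)
            for i in range(150)
        ]
        out = est.sv_local_vertical_window(images, "cisterna", tau=0.25, seed=8)
        # LVW carries a small, documented selection bias O(1 - E[sin gamma])
        assert out.value == pytest.approx(2 / 0.05, rel=0.12)
        assert "sensitivity" in out.extra


def test_sv_invariant_under_scene_rotation(rng):
    """With IUR orientation sampling, rotating an anisotropic scene leaves
    the surface-density estimate unchanged in expectation."""
    from stereovem.geometry import rotation_about
    from stereovem.phantom import DiscPlate, Scene, SphereRegion
    from stereovem.probes import count_intersections, count_points

    region = SphereRegion([0, 0, 0], 1.3)
    base = Scene([DiscPlate([0, 0, 0], [0, 0, 1], 0.8, 0.05)], region)
    rotated = base.rotated(rotation_about([1, 1, 0], 1.1))

    def sv(scene):
        ys, xs = [], []
        for i in range(400):
            spec = V._iur_plane_in_region(region, rng)
            img = intersect(scene, spec, include_reference=False, image_id=i)
            system = make_test_system("line_grid", {"d": 0.06, "iur_rotation": True}, rng)
            ys.append(count_intersections(img, system, ["cisterna"])[0].I)
            xs.append(count_points(img, system, ["cisterna"])[0].P)
        from stereovem.precision import cochran_ratio_se
        y, x = np.array(ys, float), np.array(xs, float)
        return (2 / 0.06) * y.sum() / x.sum(), (2 / 0.06) * cochran_ratio_se(x, y)

    v1, se1 = sv(base)
    v2, se2 = sv(rotated)
    assert abs(v1 - v2) <= 2 * np.hypot(se1, se2)


def test_estimate_se_non_negative_guard():
    with pytest.raises(ValueError):
        est.Estimate("Vv", 0.5, "dimensionless", se=-1.0)
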