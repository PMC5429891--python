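"""Virtual sectioning: orientation sampling, SUR stacks, slab projection."""

import numpy as np
import pytest
from scipy import stats

from stereovem.phantom import Box, DiscPlate, Scene, Sphere, SphereRegion, make_vesicle_population
from stereovem.sectioning import (
    SectionSpec,
    intersect,
    make_sur_stack,
    make_vertical_section,
    ministack_projection,
    project_slab,
    rasterize,
    sample_iur_orientation,
)

from oracles import holmes_projected_area


@pytest.fixture
def sphere_scene():
    return Scene([Sphere([0, 0, 0], 1.0, "vesicle")], SphereRegion([0, 0, 0], 1.5))


class TestIurOrientation:
    def test_mean_direction_vanishes(self, rng):
        vs = np.array([sample_iur_orientation(rng) for _ in range(100_000)])
        assert np.linalg.norm(vs.mean(axis=0)) < 0.01

    def test_z_component_uniform(self, rng):
        z = np.array([sample_iur_orientation(rng)[2] for _ in range(5000)])
        assert stats.kstest(z, stats.uniform(-1, 2).cdf).pvalue > 0.01

    def test_reproducible(self):
        assert np.allclose(sample_iur_orientation(7), sample_iur_orientation(7))


class TestSurStack:
    def test_sphere_hit_counts(self, sphere_scene, rng):
        hits = []
        for _ in range(200):
            stack = make_sur_stack(sphere_scene, [0, 0, 1], 0.25, rng)
            n_hit = sum(
                bool(intersect(sphere_scene, stack.spec(i), include_reference=False).profiles)
                for i in range(stack.n_sections)
            )
            hits.append(n_hit)
        assert set(hits) <= {8, 9}
        # caliper 2 um / 0.25 um -> 8 interior sections almost surely
        assert np.mean(hits) == pytest.approx(8.0, abs=0.2)

    def test_fine_spacing_limit(self, sphere_scene):
        stack = make_sur_stack(sphere_scene, [0, 0, 1], 0.001, seed=0)
        assert abs(stack.n_sections - 2.0 / 0.001) <= 2

    def test_volume_sem_series_dimensions(self):
        # a 5-um organelle shaved at 25 nm yields a ~200 section series
        scene = make_vesicle_population(50, 0.065, 0.005, Box([0, 0, 0], [5, 5, 5]), seed=0)
        stack = make_sur_stack(scene, [0, 0, 1], 0.025, seed=1)
        assert 195 <= stack.n_sections <= 205

    def test_sparse_spacing_flagged(self, sphere_scene):
        with pytest.warns(UserWarning, match="spacing"):
            stack = make_sur_stack(sphere_scene, [0, 0, 1], 10.0, seed=0)
        assert stack.flagged_sparse

    def test_offsets_arithmetic(self, sphere_scene):
        stack = make_sur_stack(sphere_scene, [0, 0, 1], 0.25, seed=0)
        assert np.allclose(np.diff(stack.offsets), 0.25)

    def test_invalid_spacing(self, sphere_scene):
        with pytest.raises(ValueError):
            make_sur_stack(sphere_scene, [0, 0, 1], -1.0, seed=0)


class TestVerticalSection:
    def test_normal_orthogonal_to_vertical(self, sphere_scene, rng):
        for _ in range(200):
            spec = make_vertical_section(sphere_scene, [0, 0, 1], rng)
            assert abs(np.dot(spec.normal, [0, 0, 1])) < 1e-12

    def test_rotation_uniform(self, sphere_scene, rng):
        angles = []
        for _ in range(3000):
            spec = make_vertical_section(sphere_scene, [0, 0, 1], rng)
            angles.append(np.arctan2(spec.normal[1], spec.normal[0]) % np.pi)
        assert stats.kstest(angles, stats.uniform(0, np.pi).cdf).pvalue > 0.01

    def test_vertical_axis_representable_in_plane(self, sphere_scene, rng):
        spec = make_vertical_section(sphere_scene, [0, 0, 1], rng)
        img = intersect(sphere_scene, spec, include_reference=False)
        vert3 = img.plane.e2
        assert abs(np.dot(vert3, spec.normal)) < 1e-12
        assert np.allclose(vert3, [0, 0, 1])


class TestIntersect:
    def test_sphere_pythagoras(self, sphere_scene):
        img = intersect(sphere_scene, SectionSpec([0, 0, 1], 0.6), include_reference=False)
        prof = img.profiles[0]
        assert prof.radius == pytest.approx(0.8)
        assert prof.area == pytest.approx(0.64 * np.pi)

    def test_plate_orthogonal_width(self):
        scene = Scene([DiscPlate([0, 0, 0], [0, 0, 1], 1.0, 0.04)],
                      SphereRegion([0, 0, 0], 2.0))
        img = intersect(scene, SectionSpec([1, 0, 0], 0.0), include_reference=False)
        assert img.profiles[0].apparent_width == pytest.approx(0.04)

    def test_hit_weighted_mean_width_is_4t_over_pi(self, rng):
        plate = DiscPlate([0, 0, 0], [0, 0, 1], 1.0, 0.04)
        bound = np.hypot(1.0, 0.02)
        widths = []
        while len(widths) < 4000:
            n = sample_iur_orientation(rng)
            spec = SectionSpec(n, rng.uniform(-bound, bound))
            prof = plate.section(spec.plane(), 0)
            if prof is not None and prof.apparent_width is not None and prof.area > 0:
                widths.append(prof.apparent_width)
        assert np.mean(widths) == pytest.approx(4 * 0.04 / np.pi, rel=0.05)

    def test_grazing_plane_counts_zero_area_hit(self, sphere_scene):
        img = intersect(sphere_scene, SectionSpec([0, 0, 1], 1.0), include_reference=False)
        assert len(img.profiles) == 1
        assert img.profiles[0].area == pytest.approx(0.0, abs=1e-12)

    def test_iur_hit_probability_proportional_to_caliper(self, rng):
        scene = Scene(
            [Sphere([-1, 0, 0], 0.2, "small"), Sphere([1, 0, 0], 0.4, "big")],
            SphereRegion([0, 0, 0], 2.0),
        )
        hits = {"small": 0, "big": 0}
        for _ in range(4000):
            n = sample_iur_orientation(rng)
            lo, hi = scene.reference_region.support(n)
            img = intersect(scene, SectionSpec(n, rng.uniform(lo, hi)),
                            include_reference=False)
            for lab in hits:
                hits[lab] += len(img.by_label(lab))
        assert hits["big"] / hits["small"] == pytest.approx(2.0, rel=0.1)


class TestSlabProjection:
    def test_slab_containing_equator_shows_full_radius(self):
        scene = Scene([Sphere([1, 1, 1], 0.03, "vesicle")], Box([0, 0, 0], [2, 2, 2]))
        spec = SectionSpec([0, 0, 1], 0.98, h_phys=0.06, h_img=0.06)
        img = project_slab(scene, spec, include_reference=False)
        assert img.profiles[0].radius == pytest.approx(0.03)

    def test_zero_depth_equals_intersect(self):
        scene = Scene([Sphere([1, 1, 1], 0.5, "vesicle")], Box([0, 0, 0], [2, 2, 2]))
        spec = SectionSpec([0, 0, 1], 1.2, h_phys=0.0, h_img=0.0)
        a = project_slab(scene, spec, include_reference=False)
        b = intersect(scene, SectionSpec([0, 0, 1], 1.2), include_reference=False)
        assert a.profiles[0].radius == pytest.approx(b.profiles[0].radius)

    def test_holmes_overprojection_inflates_area(self, rng):
        r, h = 0.03, 0.06
        scene = Scene([Sphere([1, 1, 1], r, "vesicle")], Box([0, 0, 0], [2, 2, 2]))
        areas = []
        for _ in range(2000):
            o = rng.uniform(1 - r - h, 1 + r)
            img = project_slab(scene, SectionSpec([0, 0, 1], o, h, h),
                               include_reference=False)
            areas.append(img.profiles[0].area if img.profiles else 0.0)
        plane_expectation = (2.0 / 3.0) * np.pi * r ** 2
        oracle = holmes_projected_area(r, h)
        assert np.mean(areas) > plane_expectation
        assert np.mean(areas) == pytest.approx(oracle, rel=0.05)

    def test_lost_caps_threshold_drops_small_profiles(self):
        scene = Scene([Sphere([1, 1, 1], 0.03, "vesicle")], Box([0, 0, 0], [2, 2, 2]))
        spec = SectionSpec([0, 0, 1], 1.029, h_phys=0.005, h_img=0.005)
        kept = project_slab(scene, spec, include_reference=False)
        dropped = project_slab(scene, spec, include_reference=False, lost_caps_eps=0.02)
        assert kept.profiles and not dropped.profiles

    def test_imaging_depth_cannot_exceed_thickness(self):
        with pytest.raises(ValueError):
            SectionSpec([0, 0, 1], 0.0, h_phys=0.01, h_img=0.02)

    def test_monotone_vs_plane_section(self, rng):
        """Full-depth slab projection area >= the mid-slab plane section."""
        scene = Scene([Sphere([1, 1, 1], 0.05, "vesicle")], Box([0, 0, 0], [2, 2, 2]))
        for _ in range(50):
            o = rng.uniform(0.93, 1.03)
            h = 0.04
            slab = project_slab(scene, SectionSpec([0, 0, 1], o, h, h),
                                include_reference=False)
            mid = intersect(scene, SectionSpec([0, 0, 1], o + h / 2),
                            include_reference=False)
            a_slab = slab.profiles[0].area if slab.profiles else 0.0
            a_mid = mid.profiles[0].area if mid.profiles else 0.0
            assert a_slab >= a_mid - 1e-12


class TestMinistack:
    def test_single_section_identity(self):
        scene = Scene([Sphere([1, 1, 1], 0.05, "vesicle")], Box([0, 0, 0], [2, 2, 2]))
        stack = make_sur_stack(scene, [0, 0, 1], 0.01, seed=0, h_phys=0.01)
        imgs = ministack_projection(scene, stack, 1)
        assert len(imgs) == stack.n_sections

    def test_tiling_partitions_stack(self):
        scene = Scene([Sphere([1, 1, 1], 0.05, "vesicle")], Box([0, 0, 0], [2, 2, 2]))
        stack = make_sur_stack(scene, [0, 0, 1], 0.01, seed=0, h_phys=0.01)
        imgs = ministack_projection(scene, stack, 3)
        assert len(imgs) == stack.n_sections // 3
        starts = [im.spec.offset for im in imgs]
        assert np.allclose(np.diff(starts), 3 * 0.01)

    def test_matched_depth_gives_one_equatorial_profile(self):
        """With ministack depth equal to the vesicle diameter, nearly every
        vesicle shows its maximal (equatorial) profile in exactly one group."""
        d = 0.06
        scene = make_vesicle_population(200, d, 0.0, Box([0, 0, 0], [2, 2, 2]), seed=3)
        stack = make_sur_stack(scene, [0, 0, 1], 0.005, seed=4, h_phys=0.005)
        m = int(round(d / 0.005))
        imgs = ministack_projection(scene, stack, m)
        equatorial = {pid: 0 for pid in range(200)}
        for im in imgs:
            for prof in im.by_label("vesicle"):
                if prof.radius >= 0.999 * scene.primitives[prof.parent_id].radius:
                    equatorial[prof.parent_id] += 1
        frac_single = np.mean([v == 1 for v in equatorial.values()])
        assert frac_single >= 0.95

    def test_oversized_ministack_rejected(self):
        scene = Scene([Sphere([1, 1, 1], 0.05, "vesicle")], Box([0, 0, 0], [2, 2, 2]))
        stack = make_sur_stack(scene, [0, 0, 1], 0.02, seed=0, h_phys=0.02)
        with pytest.raises(ValueError):
            ministack_projection(scene, stack, stack.n_sections + 1)


class TestRasterize:
    def test_circle_pixel_area_converges(self):
        scene = Scene([Sphere([1, 1, 1], 0.5, "vesicle")], Box([0, 0, 0], [2, 2, 2]))
        img = intersect(scene, SectionSpec([0, 0, 1], 1.0), include_reference=False)
        raster, label_map = rasterize(img, 0.005)
        n_px = int((raster == label_map["vesicle"]).sum())
        assert n_px * 0.005 ** 2 == pytest.approx(np.pi * 0.25, rel=0.005)

    def test_empty_profileset_all_zero(self):
        scene = Scene([Sphere([1, 1, 1], 0.3, "vesicle")], Box([0, 0, 0], [2, 2, 2]))
        img = intersect(scene, SectionSpec([0, 0, 1], 1.9), include_reference=False)
        raster, _ = rasterize(img, 0.01)
        assert raster.sum() == 0

    def test_label_collision_order_independent(self):
        scene = Scene(
            [Sphere([1, 1, 1], 0.4, "big_struct"), Sphere([1.2, 1, 1], 0.1, "small_struct")],
            Box([0, 0, 0], [2, 2, 2]),
        )
        img = intersect(scene, SectionSpec([0, 0, 1], 1.0), include_reference=False)
        r1, m = rasterize(img, 0.01)
        img.profiles.reverse()
        r2, m2 = rasterize(img, 0.01, m)
        assert np.array_equal(r1, r2)
        # the smaller structure wins the overlap
        assert (r1 == m["small_struct"]).sum() * 0.01 ** 2 == pytest.approx(np.pi * 0.01, rel=0.05)

    def test_resolution_warning(self):
        scene = Scene([Sphere([1, 1, 1], 0.01, "vesicle")], Box([0, 0, 0], [2, 2, 2]))
        img = intersect(scene, SectionSpec([0, 0, 1], 1.0), include_reference=False)
        with pytest.warns(UserWarning, match="pixel size"):
            rasterize(img, 0.05)


def test_cavalieri_consistency_exhaustive_sections():
    """Exhaustive thin sectioning reproduces ground-truth V to O(k)."""
    scene = Scene([Sphere([0, 0, 0], 0.8, "vesicle"),
                   DiscPlate([0, 0, 0.9], [0, 0, 1], 0.5, 0.05, "cisterna")],
                  SphereRegion([0, 0, 0], 1.5))
    k = 0.004
    stack = make_sur_stack(scene, [0, 0, 1], k, seed=0)
    vol = {"vesicle": 0.0, "cisterna": 0.0}
    for i in range(stack.n_sections):
        img = intersect(scene, stack.spec(i), include_reference=False)
        for lab in vol:
            vol[lab] += sum(p.area for p in img.by_label(lab)) * k
    gt = scene.ground_truth()
    assert vol["vesicle"] == pytest.approx(gt["vesicle"].V, rel=0.01)
    assert vol["cisterna"] == pytest.approx(gt["cisterna"].V, rel=0.05)
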