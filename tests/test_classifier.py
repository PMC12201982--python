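"""Centroid membership, sphere criterion and the A-E decision procedure."""

import numpy as np
import pytest

from doseclass import (
    DoseGrid,
    EmptyMaskError,
    Grid3D,
    PhantomSpec,
    build_sphere,
    build_structure_set,
    centroid,
    centroid_membership,
    classify,
    make_phantom_dose,
    plant_recurrence,
    sample_dose_at_point,
    segment_dose_structure,
    sphere_pass_fraction,
)


class TestSampleDoseAtPoint:
    def test_uniform_grid(self, small_grid):
        dose = DoseGrid(small_grid, np.full(small_grid.shape, 50.0))
        assert sample_dose_at_point(dose, (5.0, 5.0, 5.0)) == 50.0

    def test_nearest_voxel_not_interpolated(self):
        grid = Grid3D((4, 1, 1), (2.0, 2.0, 2.0))
        dose = DoseGrid(grid, np.array([10.0, 20.0, 30.0, 40.0]).reshape(4, 1, 1))
        # 0.4 * spacing past the centre of voxel 1 -> still voxel 1's value
        assert sample_dose_at_point(dose, (2.0 + 0.8, 0.0, 0.0)) == 20.0

    def test_random_points_match_floor_oracle(self):
        rng = np.random.default_rng(2)
        grid = Grid3D((9, 7, 11), (1.7, 2.3, 0.9), (-3.0, 4.0, 1.0))
        dose = DoseGrid(grid, rng.uniform(0, 70, grid.shape))
        for _ in range(50):
            f = rng.uniform(-0.49, np.array(grid.shape) - 0.51)
            p = np.array(grid.origin) + f * np.array(grid.spacing)
            idx = tuple(
                int(np.floor((p[a] - grid.origin[a]) / grid.spacing[a] + 0.5))
                for a in range(3)
            )
            assert sample_dose_at_point(dose, p) == dose.values[idx]

    def test_point_outside_raises(self, small_grid):
        dose = DoseGrid(small_grid, np.zeros(small_grid.shape))
        with pytest.raises(ValueError, match="outside"):
            sample_dose_at_point(dose, (500.0, 0.0, 0.0))


class TestCentroidMembership:
    def test_high_dose_centroid(self, phantom_structures):
        # thresholds: high 50.35, intermediate 38.0, low 34.2
        assert centroid_membership(52.8, phantom_structures) == "high"

    def test_below_single_high_threshold_is_none(self, phantom_dose):
        from doseclass import PrescriptionSet

        structs = build_structure_set(
            phantom_dose, PrescriptionSet.from_dict({"high": 50.0})
        )
        assert centroid_membership(18.3, structs) is None

    def test_exact_intermediate_boundary_is_inclusive(self, phantom_structures):
        inter = next(s for s in phantom_structures if s.risk_label == "intermediate")
        assert centroid_membership(inter.threshold, phantom_structures) == "intermediate"

    def test_low_structure_never_confers_membership(self, phantom_structures):
        low = next(s for s in phantom_structures if s.risk_label == "low")
        inter = next(s for s in phantom_structures if s.risk_label == "intermediate")
        dose_between = (low.threshold + inter.threshold) / 2
        assert centroid_membership(dose_between, phantom_structures) is None

    def test_structure_mean_rule(self, phantom_structures):
        high = next(s for s in phantom_structures if s.risk_label == "high")
        just_below_mean = high.mean_dose - 0.1
        assert centroid_membership(just_below_mean, phantom_structures) == "high"
        assert (
            centroid_membership(
                just_below_mean, phantom_structures, rule="structure_mean"
            )
            != "high"
        )


class TestSpherePassFraction:
    def test_uniform_dose_at_mean_passes_fully(self):
        grid = Grid3D((16, 16, 16))
        dose = DoseGrid(grid, np.full(grid.shape, 50.0))
        s = segment_dose_structure(dose, 45.0, "high")  # mean = 50
        sphere = build_sphere((8.0, 8.0, 8.0), 3.0, grid)
        assert sphere_pass_fraction(dose, sphere, s) == 1.0

    def test_cold_region_fails_fully(self):
        grid = Grid3D((24, 24, 24))
        values = np.zeros(grid.shape)
        values[:4, :, :] = 60.0  # hot slab far from the sphere
        dose = DoseGrid(grid, values)
        s = segment_dose_structure(dose, 55.0, "high")
        sphere = build_sphere((16.0, 16.0, 16.0), 4.0, grid)
        assert sphere_pass_fraction(dose, sphere, s) == 0.0

    def test_step_dose_gives_exact_voxel_ratio(self):
        """Sphere straddling a sharp dose step: fraction = k/N by enumeration."""
        grid = Grid3D((24, 24, 24))
        values = np.full(grid.shape, 30.0)
        values[12:, :, :] = 60.0
        dose = DoseGrid(grid, values)
        s = segment_dose_structure(dose, 57.0, "high")  # mean 60
        sphere = build_sphere((11.3, 11.5, 11.5), 4.1, grid)
        idx = np.argwhere(sphere.mask.voxels)
        k = sum(1 for i, j, l in idx if values[i, j, l] >= 60.0)
        assert sphere_pass_fraction(dose, sphere, s) == pytest.approx(
            k / len(idx), abs=1e-15
        )

    def test_empty_structure_is_an_error(self, small_grid):
        dose = DoseGrid(small_grid, np.full(small_grid.shape, 10.0))
        with pytest.warns(UserWarning):
            s = segment_dose_structure(dose, 50.0, "high")
        sphere = build_sphere((5.0, 5.0, 5.0), 2.0, small_grid)
        with pytest.raises(EmptyMaskError, match="undefined"):
            sphere_pass_fraction(dose, sphere, s)


class TestClassify:
    def test_deep_boost_centroid_is_type_a(
        self, default_spec, phantom_dose, phantom_structures
    ):
        centre = default_spec.shells[0][0]  # shell centre, inside the boost core
        sphere = build_sphere(centre, 5.0, phantom_dose.grid)
        res = classify(phantom_dose, phantom_structures, sphere, centre)
        assert res.category == "A"
        assert res.centroid_level == "high"
        assert res.sphere_pass_fraction["high"] == 1.0

    def test_periphery_centroid_is_type_e(
        self, default_spec, phantom_dose, phantom_structures
    ):
        point = (10.0, 10.0, 10.0)  # plateau corner, far outside all shells
        sphere = build_sphere(point, 5.0, phantom_dose.grid)
        res = classify(phantom_dose, phantom_structures, sphere, point)
        assert res.category == "E"
        assert res.centroid_level is None
        assert res.centroid_dose == default_spec.plateau_dose

    def test_straddling_sphere_is_type_b_with_enumerated_fraction(
        self, default_spec, phantom_dose, phantom_structures
    ):
        # just inside the 55 Gy boost surface (r=15 around the shell centre)
        centre = np.array(default_spec.shells[0][0]) + np.array([13.0, 0.0, 0.0])
        sphere = build_sphere(centre, 5.0, phantom_dose.grid)
        res = classify(phantom_dose, phantom_structures, sphere, centre)
        assert res.category == "B"
        high = next(s for s in phantom_structures if s.risk_label == "high")
        idx = np.argwhere(sphere.mask.voxels)
        k = sum(1 for i in idx if phantom_dose.values[tuple(i)] >= high.mean_dose)
        assert res.sphere_pass_fraction["high"] == pytest.approx(
            k / len(idx), abs=1e-15
        )
        assert res.sphere_pass_fraction["high"] < 0.95

    def test_zero_radius_collapses_sphere_criterion_to_centroid(
        self, default_spec, phantom_dose, phantom_structures
    ):
        """radius -> 0: the sphere is the centroid voxel, so B collapses to A
        whenever the centroid voxel's dose reaches the structure mean."""
        core_centre = default_spec.shells[0][0]  # dose 58 > high mean
        sphere = build_sphere(core_centre, 0.0, phantom_dose.grid)
        assert sphere.mask.voxel_count == 1
        res = classify(phantom_dose, phantom_structures, sphere, core_centre)
        assert res.category == "A"
        assert res.sphere_pass_fraction["high"] == 1.0
        # boundary voxel at 55 Gy: below the high mean, so the single-voxel
        # sphere fails and the call is B
        edge = np.array(core_centre) + np.array([13.0, 0.0, 0.0])
        sphere = build_sphere(edge, 0.0, phantom_dose.grid)
        res = classify(phantom_dose, phantom_structures, sphere, edge)
        assert res.category == "B"
        assert res.sphere_pass_fraction["high"] == 0.0

    def test_monotone_degradation_along_outward_ray(
        self, default_spec, phantom_dose, phantom_structures
    ):
        """Walking outward from the boost centre, categories degrade
        A/B -> C/D -> E and never recover."""
        centre = np.array(default_spec.shells[0][0])
        order = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 2}
        seen = []
        for r in np.arange(0.0, 48.0, 1.0):
            p = centre + np.array([r, 0.0, 0.0])
            sphere = build_sphere(p, 5.0, phantom_dose.grid)
            seen.append(
                order[classify(phantom_dose, phantom_structures, sphere, p).category]
            )
        assert seen == sorted(seen)

    def test_always_exactly_one_category(self, default_spec):
        rng = np.random.default_rng(9)
        spec = PhantomSpec(noise_sd=0.8, seed=5)
        dose = make_phantom_dose(spec)
        structs = build_structure_set(dose, spec.prescriptions)
        for _ in range(30):
            p = rng.uniform(20, 100, 3)
            sphere = build_sphere(p, float(rng.uniform(0, 8)), dose.grid)
            res = classify(dose, structs, sphere, p)
            assert res.category in "ABCDE"

    def test_planted_case_diagnostics_rederive_category(self, default_spec, phantom_dose, phantom_structures):
        """The reported diagnostics are sufficient to re-derive the category."""
        for cat in "ABCDE":
            pc = plant_recurrence(default_spec, cat, seed=1)
            c = centroid(pc.case.rgtv_mapped)
            sphere = build_sphere(c, 5.0, phantom_dose.grid)
            res = classify(phantom_dose, phantom_structures, sphere, c)
            if res.centroid_level == "high":
                expected = "A" if res.sphere_pass_fraction["high"] >= 0.95 else "B"
            elif res.centroid_level == "intermediate":
                expected = (
                    "C" if res.sphere_pass_fraction["intermediate"] >= 0.95 else "D"
                )
            else:
                expected = "E"
            assert res.category == expected == cat
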