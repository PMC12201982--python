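"""Mask warping, TRE computation, outlier flagging and sphere rasterisation."""

import numpy as np
import pytest

from doseclass import (
    DisplacementField,
    EmptyMaskError,
    Grid3D,
    StructureMask,
    build_sphere,
    centroid,
    cohort_tre,
    patient_tre,
)


def cube_mask(grid, lo, hi, name="cube"):
    voxels = np.zeros(grid.shape, bool)
    voxels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return StructureMask(name, grid, voxels)


class TestWarpMask:
    def test_identity_field_returns_input(self):
        grid = Grid3D((16, 16, 16))
        mask = cube_mask(grid, (4, 4, 4), (9, 9, 9))
        from doseclass import warp_mask

        out = warp_mask(mask, DisplacementField.identity(grid))
        assert np.array_equal(out.voxels, mask.voxels)

    def test_uniform_translation_shifts_by_field_vector(self):
        grid = Grid3D((20, 20, 20))  # 1 mm spacing
        mask = cube_mask(grid, (5, 5, 5), (10, 10, 10))
        from doseclass import warp_mask

        out = warp_mask(mask, DisplacementField.translation(grid, (2.0, 0.0, 0.0)))
        expected = np.zeros(grid.shape, bool)
        expected[7:12, 5:10, 5:10] = True
        assert np.array_equal(out.voxels, expected)

    def test_radial_field_matches_per_voxel_pullback(self):
        """Smooth synthetic radial field vs direct per-voxel transport."""
        grid = Grid3D((14, 14, 14), (1.5, 1.5, 1.5))
        mask = cube_mask(grid, (4, 4, 4), (10, 10, 10))
        centre = np.array([10.0, 10.0, 10.0])
        coords = np.stack(
            np.meshgrid(*[grid.axis_coords(a) for a in range(3)], indexing="ij"),
            axis=-1,
        )
        vectors = 0.15 * (coords - centre)  # expansion about the centre
        dvf = DisplacementField(grid, vectors)
        from doseclass import warp_mask

        out = warp_mask(mask, dvf)
        for i in range(14):
            for j in range(14):
                for k in range(14):
                    x = grid.index_to_world((i, j, k))
                    pulled = x - vectors[i, j, k]
                    src = np.floor(
                        (pulled - np.array(grid.origin)) / grid.spacing + 0.5
                    ).astype(int)
                    inside = np.all((src >= 0) & (src < 14))
                    expected = bool(inside and mask.voxels[tuple(src)])
                    assert out.voxels[i, j, k] == expected

    def test_field_not_covering_mask_raises(self):
        big = Grid3D((20, 20, 20))
        small_field = DisplacementField.identity(Grid3D((5, 5, 5)))
        mask = cube_mask(big, (10, 10, 10), (15, 15, 15))
        from doseclass import warp_mask

        with pytest.raises(ValueError, match="does not cover"):
            warp_mask(mask, small_field)


class TestPatientTRE:
    def test_identical_rois_have_zero_tre(self):
        grid = Grid3D((16, 16, 16))
        roi = cube_mask(grid, (3, 3, 3), (8, 8, 8))
        assert patient_tre(roi, roi) == 0.0

    def test_3_4_0_translation_gives_5mm(self):
        grid = Grid3D((20, 20, 20))
        roi = cube_mask(grid, (3, 3, 3), (8, 8, 8))
        shifted = cube_mask(grid, (6, 7, 3), (11, 12, 8))
        assert patient_tre(roi, shifted) == pytest.approx(5.0, abs=1e-12)

    def test_random_masks_match_brute_force_centroid_distance(self):
        from _brute import brute_centroid

        rng = np.random.default_rng(7)
        grid = Grid3D((12, 12, 12), (1.1, 2.0, 0.7), (3.0, -4.0, 0.0))
        a = StructureMask("a", grid, rng.random(grid.shape) < 0.2)
        b = StructureMask("b", grid, rng.random(grid.shape) < 0.2)
        ca = np.array(brute_centroid(a.voxels.tolist(), grid.spacing, grid.origin))
        cb = np.array(brute_centroid(b.voxels.tolist(), grid.spacing, grid.origin))
        assert patient_tre(a, b) == pytest.approx(np.linalg.norm(ca - cb), abs=1e-12)

    def test_empty_roi_error_identifies_side(self):
        grid = Grid3D((8, 8, 8))
        full = cube_mask(grid, (0, 0, 0), (4, 4, 4))
        empty = StructureMask("e", grid, np.zeros(grid.shape, bool))
        with pytest.raises(EmptyMaskError, match="fixed"):
            patient_tre(empty, full)
        with pytest.raises(EmptyMaskError, match="mapped"):
            patient_tre(full, empty)


class TestCohortTRE:
    def test_constant_cohort(self):
        c = cohort_tre([("p1", 5.0), ("p2", 5.0), ("p3", 5.0)])
        assert (c.mean_mm, c.sd_mm, c.outlier_ids) == (5.0, 0.0, ())

    def test_single_patient_has_zero_sd_and_no_outliers(self):
        c = cohort_tre([("p1", 5.2)])
        assert (c.mean_mm, c.sd_mm, c.outlier_ids) == (5.2, 0.0, ())

    def test_planted_outlier_is_flagged_alone(self):
        rng = np.random.default_rng(0)
        tres = [(f"p{i}", float(abs(rng.normal(5, 1)))) for i in range(20)]
        tres.append(("bad", 40.0))
        c = cohort_tre(tres)
        assert c.outlier_ids == ("bad",)

    def test_mean_sd_match_two_pass_computation(self):
        rng = np.random.default_rng(3)
        vals = [float(v) for v in np.abs(rng.normal(5, 2, size=17))]
        c = cohort_tre(list(zip([f"p{i}" for i in range(17)], vals)))
        mean = sum(vals) / len(vals)
        sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        assert c.mean_mm == pytest.approx(mean, abs=1e-12)
        assert c.sd_mm == pytest.approx(sd, abs=1e-12)

    def test_literal_3sd_rule(self):
        # mean 10, sd ~5: literal rule flags values > 3*sd, not mean + 3*sd
        tres = [("a", 5.0), ("b", 10.0), ("c", 15.0), ("d", 22.0)]
        sd = cohort_tre(tres).sd_mm
        literal = cohort_tre(tres, outlier_rule="3sd")
        assert literal.outlier_ids == tuple(
            pid for pid, t in tres if t > 3 * sd
        )

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            cohort_tre([])


class TestBuildSphere:
    def test_radius_zero_at_voxel_centre_is_one_voxel(self):
        grid = Grid3D((9, 9, 9), (2.0, 2.0, 2.0))
        s = build_sphere((8.0, 8.0, 8.0), 0.0, grid)
        assert s.mask.voxel_count == 1
        assert s.mask.voxels[4, 4, 4]

    def test_radius_zero_off_centre_is_containing_voxel(self):
        grid = Grid3D((9, 9, 9), (2.0, 2.0, 2.0))
        s = build_sphere((8.7, 7.4, 8.0), 0.0, grid)
        assert s.mask.voxel_count == 1
        assert s.mask.voxels[4, 4, 4]  # containing voxel of (8.7, 7.4, 8.0)

    def test_radius_equal_to_spacing_gives_seven_voxels(self):
        grid = Grid3D((9, 9, 9), (2.0, 2.0, 2.0))
        s = build_sphere((8.0, 8.0, 8.0), 2.0, grid)
        # centre plus 6 face neighbours at distance exactly the spacing
        assert s.mask.voxel_count == 7

    def test_voxel_count_near_continuum_volume(self):
        grid = Grid3D((31, 31, 31))  # 1 mm
        r = 5.2
        s = build_sphere((15.0, 15.0, 15.0), r, grid)
        continuum = 4 / 3 * np.pi * r**3
        assert abs(s.mask.voxel_count - continuum) / continuum < 0.15

    def test_reflection_symmetric_about_voxel_centre(self):
        grid = Grid3D((15, 15, 15), (1.0, 1.0, 1.0))
        s = build_sphere((7.0, 7.0, 7.0), 4.3, grid)
        v = s.mask.voxels
        for ax in range(3):
            assert np.array_equal(v, np.flip(v, axis=ax))

    def test_all_voxel_centres_within_radius(self):
        grid = Grid3D((20, 20, 20), (1.5, 1.5, 1.5))
        centre = np.array([14.2, 13.7, 15.1])
        r = 6.0
        s = build_sphere(centre, r, grid)
        idx = np.argwhere(s.mask.voxels)
        d = np.linalg.norm(grid.index_to_world(idx) - centre, axis=1)
        assert np.all(d <= r + 1e-6)

    def test_centre_outside_grid_raises(self):
        grid = Grid3D((10, 10, 10))
        with pytest.raises(ValueError, match="outside"):
            build_sphere((50.0, 0.0, 0.0), 2.0, grid)

    def test_clipped_sphere_warns(self):
        grid = Grid3D((10, 10, 10))
        with pytest.warns(UserWarning, match="clipped"):
            build_sphere((1.0, 5.0, 5.0), 4.0, grid)


class TestRoundTrips:
    def test_inverse_field_recovers_zero_tre(self):
        """Warp out by a translation, back by its inverse: TRE ~ 0."""
        from doseclass import warp_mask

        grid = Grid3D((24, 24, 24))
        roi = cube_mask(grid, (8, 8, 8), (14, 14, 14))
        t = (3.0, -2.0, 1.0)
        fwd = DisplacementField.translation(grid, t)
        back = DisplacementField.translation(grid, tuple(-x for x in t))
        recovered = warp_mask(warp_mask(roi, fwd), back)
        assert patient_tre(roi, recovered) <= grid.voxel_diagonal_mm / 2

    @pytest.mark.parametrize("t", [(3.0, 4.0, 0.0), (1.3, -2.1, 0.7), (0.0, 0.0, 6.0)])
    def test_planted_translation_recovers_magnitude(self, t):
        from doseclass import warp_mask

        grid = Grid3D((32, 32, 32))
        roi = cube_mask(grid, (10, 10, 10), (16, 16, 16))
        warped = warp_mask(roi, DisplacementField.translation(grid, t))
        tre = patient_tre(roi, warped)
        assert abs(tre - np.linalg.norm(t)) <= grid.voxel_diagonal_mm / 2
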