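import numpy as np
import pytest
from scipy.spatial import cKDTree

from alignfit.thickness import (
    CenterSurface,
    centerline_2d,
    extract_center_surface,
    measure_thickness,
    shrinkage_percent,
    summarize_thickness,
)


def _field(values, voxel_size=33.0):
    from alignfit.thickness import ThicknessField

    n = len(values)
    coords = np.column_stack([np.arange(n), np.zeros(n), np.zeros(n)]).astype(int)
    return ThicknessField(coords, np.asarray(values, float), voxel_size)


class TestCenterline2D:
    def test_empty_slice(self):
        assert not centerline_2d(np.zeros((10, 10), bool)).any()

    def test_five_wide_ribbon_middle_line(self):
        ribbon = np.zeros((5, 40), bool)
        ribbon[:, :] = True
        sk = centerline_2d(ribbon)
        for c in range(5, 35):  # away from the ribbon ends
            assert sk[2, c] and sk[:, c].sum() == 1

    def test_skeleton_inside_mask_and_unit_width(self, rng):
        from scipy import ndimage

        blob = ndimage.binary_dilation(rng.random((40, 40)) > 0.985, iterations=4)
        sk = centerline_2d(blob)
        assert not (sk & ~blob).any()
        # no fully-set 2x2 block anywhere (unit width)
        two = sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:]
        assert not two.any()


class TestCenterSurface:
    def test_slab_middle_layer_interior(self):
        m = np.zeros((40, 40, 24), bool)
        m[:, :, 10:15] = True
        cs = extract_center_surface(m).mask
        interior = np.zeros_like(m)
        interior[3:37, 3:37, :] = True
        mid = np.zeros_like(m)
        mid[:, :, 12] = True
        assert np.array_equal(cs & interior, mid & interior)

    def test_unit_sheet_is_its_own_center(self):
        m = np.zeros((30, 30, 12), bool)
        m[:, :, 6] = True
        cs = extract_center_surface(m).mask
        interior = np.zeros_like(m)
        interior[2:28, 2:28, :] = True
        assert np.array_equal(cs & interior, m & interior)

    def test_hollow_sphere_mid_radius(self):
        n = 44
        c = (n - 1) / 2
        x, y, z = np.indices((n, n, n))
        r = np.sqrt((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
        shell = (r >= 10.5) & (r < 15.5)  # 5-voxel wall, mid radius 13
        cs = extract_center_surface(shell)
        assert (np.abs(r[cs.mask] - 13.0) <= 1.0).all()

    def test_center_surface_subset_of_mask(self, arch_noisy):
        from alignfit.aligner_extraction import extract_aligner_mask, subtract_registered

        model, mpa, _ = arch_noisy
        mask = extract_aligner_mask(subtract_registered(mpa, model), 2)
        cs = extract_center_surface(mask)
        assert not (cs.mask & ~mask.data).any()

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            extract_center_surface(np.zeros((5, 5, 5), bool))


class TestMeasureThickness:
    def test_unit_sheet_floor_66um(self):
        m = np.zeros((20, 20, 9), bool)
        m[:, :, 4] = True
        cs = extract_center_surface(m)
        fld = measure_thickness(m, cs, voxel_size=33.0)
        assert (fld.values_um == 66.0).all()

    def test_five_layer_slab_198um(self):
        m = np.zeros((30, 30, 20), bool)
        m[:, :, 8:13] = True
        cs = CenterSurface(np.zeros_like(m))
        cs.mask[:, :, 10] = True
        fld = measure_thickness(m, cs, voxel_size=33.0)
        assert (fld.values_um == 2 * 3 * 33.0).all()

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(3):
            m = rng.random((20, 20, 20)) > 0.6
            m[0, 0, 0] = False  # keep at least one background voxel
            if not m.any():
                continue
            fg = np.argwhere(m)
            bg = np.argwhere(~m)
            tree = cKDTree(bg)
            d, _ = tree.query(fg)
            cs = CenterSurface(m)
            fld = measure_thickness(m, cs, voxel_size=33.0)
            expected = {tuple(c): 2 * dd * 33.0 for c, dd in zip(fg, d)}
            for c, v in zip(fld.coords, fld.values_um):
                assert v == pytest.approx(expected[tuple(c)], abs=1e-9)

    def test_lower_bound_two_voxels(self, arch_noisy):
        from alignfit.aligner_extraction import extract_aligner_mask, subtract_registered

        model, mpa, _ = arch_noisy
        mask = extract_aligner_mask(subtract_registered(mpa, model), 2)
        cs = extract_center_surface(mask)
        fld = measure_thickness(mask, cs)
        assert fld.values_um.min() >= 2 * mask.voxel_size

    def test_cs_outside_mask_rejected(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        cs = CenterSurface(np.ones_like(m))
        with pytest.raises(ValueError):
            measure_thickness(m, cs, voxel_size=33.0)

    def test_voxel_size_scaling(self):
        m = np.zeros((12, 12, 9), bool)
        m[:, :, 4] = True
        cs = extract_center_surface(m)
        d1 = measure_thickness(m, cs, voxel_size=33.0).values_um
        d2 = measure_thickness(m, cs, voxel_size=66.0).values_um
        assert np.allclose(d2, 2 * d1)


class TestSummarize:
    def test_constant_field(self):
        s = summarize_thickness(_field([330.0] * 200), n_points=100, n_reps=10, seed=1)
        assert s.mean == s.median == 330.0
        assert s.sd == 0.0
        assert np.allclose(s.resampled_means, 330.0)

    def test_three_value_field(self):
        vals = [66.0] * 50 + [330.0] * 50 + [594.0] * 50
        s = summarize_thickness(_field(vals), n_points=100, n_reps=5, seed=0)
        assert s.mean == pytest.approx(330.0)
        assert s.minimum == 66.0 and s.maximum == 594.0

    def test_resampled_grand_mean_close_to_full_mean(self, rng):
        vals = rng.normal(340.0, 60.0, 5000)
        s = summarize_thickness(_field(vals), n_points=100, n_reps=100, seed=7)
        assert len(s.resampled_means) == 100
        se = vals.std() / np.sqrt(100) / np.sqrt(100)  # SE of the grand mean
        assert abs(s.resampled_means.mean() - vals.mean()) < 4 * se

    def test_reproducible_for_fixed_seed(self):
        vals = list(np.linspace(100, 500, 400))
        a = summarize_thickness(_field(vals), seed=5).resampled_means
        b = summarize_thickness(_field(vals), seed=5).resampled_means
        assert np.array_equal(a, b)

    def test_n_points_too_large(self):
        with pytest.raises(ValueError):
            summarize_thickness(_field([1.0, 2.0]), n_points=5)


class TestShrinkage:
    @pytest.mark.parametrize(
        "mean,nominal,expected",
        [(334.0, 550.0, 60.7), (441.0, 750.0, 58.8), (550.0, 550.0, 100.0)],
    )
    def test_values(self, mean, nominal, expected):
        assert shrinkage_percent(mean, nominal) == expected

    def test_zero_nominal_errors(self):
        with pytest.raises(ValueError):
            shrinkage_percent(300.0, 0.0)


def test_phantom_median_within_two_voxels_of_design(arch_clean_nogaps):
    """On the arch phantom the median measured thickness tracks the designed
    base-shell thickness (the flat base region dominates the distribution)."""
    from alignfit.aligner_extraction import extract_aligner_mask, subtract_registered

    model, mpa, truth = arch_clean_nogaps
    mask = extract_aligner_mask(subtract_registered(mpa, model), 2)
    cs = extract_center_surface(mask)
    fld = measure_thickness(mask, cs)
    designed = truth.designed_thickness_um["base"]
    assert abs(np.median(fld.values_um) - designed) <= 2 * truth.voxel_size
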