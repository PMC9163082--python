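"""Post-processing morphology and cycle-metric oracles."""

import numpy as np
import pytest

from cinephase import (CineSeries, MaskStack, PostprocessSpec, ProbabilityMap,
                       class_imbalance, dice_score, generate, lv_volume,
                       postprocess, select_variance_slice, surface_area)
from cinephase.core import Phase

from conftest import small_spec


def _prob(arr, spacing=(1.0, 1.0, 1.0)):
    return ProbabilityMap(np.asarray(arr, dtype=float), spacing)


class TestPostprocess:
    def test_solid_block_preserved(self):
        p = np.zeros((9, 9, 9))
        p[2:7, 2:7, 2:7] = 0.9
        out = postprocess(_prob(p))
        expected = (p >= 0.5).astype(np.uint8)
        np.testing.assert_array_equal(out.voxels, expected)

    def test_full_array_solid_preserved(self):
        out = postprocess(_prob(np.full((5, 6, 7), 0.9)))
        assert out.voxels.all()

    def test_interior_hole_filled(self):
        p = np.zeros((9, 9, 9))
        p[2:7, 2:7, 2:7] = 1.0
        p[4, 4, 4] = 0.0
        out = postprocess(_prob(p))
        assert out.voxels[4, 4, 4] == 1
        assert out.voxels.sum() == 125

    def test_thin_protrusion_removed(self):
        p = np.zeros((11, 11, 11))
        p[3:8, 3:8, 3:8] = 1.0          # 5^3 cube = 125 voxels
        p[5, 5, 8:11] = 1.0             # 1-voxel-wide, 3-voxel protrusion
        out = postprocess(_prob(p))
        assert out.voxels.sum() == 125
        assert not out.voxels[5, 5, 8:]. any()

    def test_idempotent(self, rng):
        p = rng.random((8, 20, 22))
        spec = PostprocessSpec()
        once = postprocess(_prob(p), spec)
        twice = postprocess(_prob(once.voxels.astype(float)), spec)
        np.testing.assert_array_equal(once.voxels, twice.voxels)

    def test_empty_output_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = postprocess(_prob(np.zeros((4, 5, 6))))
        assert out.voxels.sum() == 0


class TestVolume:
    def test_hundred_voxels_study_spacing(self):
        vox = np.zeros((5, 10, 10), dtype=np.uint8)
        vox.flat[:100] = 1
        assert lv_volume(MaskStack(vox, (1.5, 0.5, 0.5))) == pytest.approx(37.5)

    def test_empty_mask_zero(self):
        assert lv_volume(MaskStack(np.zeros((3, 4, 5), dtype=np.uint8))) == 0.0

    def test_matches_per_slice_summation_oracle(self, rng):
        vox = np.zeros((6, 20, 25), dtype=np.uint8)
        idx = rng.choice(vox.size, size=1000, replace=False)
        vox.flat[idx] = 1
        m = MaskStack(vox, (1.5, 0.5, 0.5))
        oracle = sum(int(sl.sum()) for sl in vox) * 0.375
        assert lv_volume(m) == pytest.approx(oracle)

    def test_additive_over_disjoint_unions(self, rng):
        a = np.zeros((6, 10, 10), dtype=np.uint8)
        b = np.zeros_like(a)
        a[:3] = rng.random((3, 10, 10)) > 0.5
        b[3:] = rng.random((3, 10, 10)) > 0.5
        u = MaskStack(a | b)
        assert lv_volume(u) == pytest.approx(
            lv_volume(MaskStack(a)) + lv_volume(MaskStack(b)))

    def test_voxelised_ellipsoid_matches_analytic(self):
        a, b, c = 20, 15, 8
        zz, yy, xx = np.meshgrid(np.arange(50) - 24.5, np.arange(50) - 24.5,
                                 np.arange(50) - 24.5, indexing="ij")
        ell = (zz / c) ** 2 + (yy / b) ** 2 + (xx / a) ** 2 <= 1
        vol = lv_volume(MaskStack(ell.astype(np.uint8), (1, 1, 1)))
        analytic = 4 / 3 * np.pi * a * b * c
        assert abs(vol - analytic) / analytic < 0.02


class TestDice:
    def test_identity_and_disjoint(self, rng):
        vox = (rng.random((4, 6, 8)) > 0.5).astype(np.uint8)
        m = MaskStack(vox)
        assert dice_score(m, m) == 1.0
        inv = MaskStack(1 - vox)
        assert dice_score(m, inv) == 0.0

    def test_half_overlap(self):
        a = np.zeros((1, 2, 4), dtype=np.uint8)
        b = np.zeros_like(a)
        a[0, 0, :4] = 1          # |A| = 4
        b[0, 0, 2:], b[0, 1, :2] = 1, 1   # |B| = 4, overlap 2
        assert dice_score(MaskStack(a), MaskStack(b)) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        e = MaskStack(np.zeros((2, 3, 4), dtype=np.uint8))
        assert dice_score(e, e) == 1.0

    def test_symmetry(self, rng):
        a = MaskStack((rng.random((4, 6, 8)) > 0.4).astype(np.uint8))
        b = MaskStack((rng.random((4, 6, 8)) > 0.6).astype(np.uint8))
        assert dice_score(a, b) == dice_score(b, a)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice_score(MaskStack(np.zeros((2, 3, 4), dtype=np.uint8)),
                       MaskStack(np.zeros((2, 3, 5), dtype=np.uint8)))


class TestVarianceSlice:
    @staticmethod
    def _series(mask_list, spacing=(1.5, 0.5, 0.5)):
        return CineSeries([Phase(k, mask=MaskStack(m, spacing))
                           for k, m in enumerate(mask_list)], spacing_mm=spacing)

    def test_only_changing_slice_selected(self):
        masks = []
        for k in range(5):
            m = np.zeros((8, 10, 10), dtype=np.uint8)
            m[3, :5, :5] = 1                       # constant slice
            m[6, :k + 1, :k + 1] = 1               # changing slice
            masks.append(m)
        z, areas = select_variance_slice(self._series(masks))
        assert z == 6
        assert areas == pytest.approx([(k + 1) ** 2 * 0.25 for k in range(5)])

    def test_constant_masks_tie_warns_smallest_index(self):
        m = np.zeros((4, 6, 6), dtype=np.uint8)
        m[1, 2:4, 2:4] = 1
        with pytest.warns(UserWarning, match="tie"):
            z, _ = select_variance_slice(self._series([m.copy(), m.copy()]))
        assert z == 0

    def test_synthetic_selects_mid_slice(self):
        for seed in range(5):
            res = generate(small_spec(seed=seed))
            z, _ = select_variance_slice(res.series)
            d = res.series.phases[0].mask.voxels.shape[0]
            assert d // 3 <= z <= 2 * d // 3 + 1

    def test_all_empty_raises(self):
        m = np.zeros((4, 6, 6), dtype=np.uint8)
        with pytest.raises(ValueError, match="empty"):
            select_variance_slice(self._series([m.copy(), m.copy()]))


class TestSurfaceArea:
    def test_sphere_matches_analytic(self):
        r = 10
        g = np.arange(24) - 11.5
        zz, yy, xx = np.meshgrid(g, g, g, indexing="ij")
        sphere = (zz ** 2 + yy ** 2 + xx ** 2 <= r ** 2).astype(np.uint8)
        area = surface_area(MaskStack(sphere, (1, 1, 1)))
        assert abs(area - 4 * np.pi * r ** 2) / (4 * np.pi * r ** 2) < 0.05

    def test_single_voxel_positive(self):
        m = np.zeros((3, 3, 3), dtype=np.uint8)
        m[1, 1, 1] = 1
        a = surface_area(MaskStack(m, (1, 1, 1)))
        assert np.isfinite(a) and a > 0

    def test_doubling_spacing_quadruples_area(self):
        g = np.arange(16) - 7.5
        zz, yy, xx = np.meshgrid(g, g, g, indexing="ij")
        sphere = (zz ** 2 + yy ** 2 + xx ** 2 <= 36).astype(np.uint8)
        a1 = surface_area(MaskStack(sphere, (1, 1, 1)))
        a2 = surface_area(MaskStack(sphere, (2, 2, 2)))
        assert a2 / a1 == pytest.approx(4.0, rel=1e-6)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            surface_area(MaskStack(np.zeros((3, 3, 3), dtype=np.uint8)))


class TestClassImbalance:
    def test_half_full_is_one(self):
        m = np.zeros((2, 4, 4), dtype=np.uint8)
        m[0] = 1
        assert class_imbalance(MaskStack(m)) == 1.0

    def test_empty_is_zero(self):
        assert class_imbalance(MaskStack(np.zeros((2, 3, 4), dtype=np.uint8))) == 0.0

    def test_direct_count_on_study_grid(self):
        m = np.zeros((12, 86, 98), dtype=np.uint8)
        m.flat[:10] = 1
        assert class_imbalance(MaskStack(m)) == pytest.approx(10 / (12 * 86 * 98 - 10))

    def test_full_foreground_raises(self):
        with pytest.raises(ValueError, match="background"):
            class_imbalance(MaskStack(np.ones((2, 3, 4), dtype=np.uint8)))
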