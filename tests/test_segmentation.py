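"""MTV segmentation: seeding, growth, surface evolution, independence."""

import numpy as np
import pytest

from petquant import (
    DegenerateInputError,
    SegmentationConfig,
    SegmentationError,
    SUVImage,
    evolve_active_surface,
    find_max_suv_slice,
    make_phantom,
    region_grow_2d,
    segment_mtv,
)
from petquant.phantom import NOMINAL_META
from petquant.segmentation import _acwe_step

from conftest import BBOX64, sphere_spec


def _img(vox, spacing=(0.5, 0.5, 0.5)):
    return SUVImage(np.asarray(vox, dtype=float), spacing, NOMINAL_META)


FULL = ((0, 16), (0, 16), (0, 16))


class TestFindMaxSlice:
    def test_single_hot_voxel(self):
        vox = np.zeros((16, 16, 16))
        vox[7, 5, 9] = 3.0
        seed = find_max_suv_slice(_img(vox), FULL)
        assert seed.slice_index == 7
        assert seed.seed_voxel == (7, 5, 9)

    def test_tie_breaks_to_lowest_slice(self):
        vox = np.zeros((16, 16, 16))
        vox[3, 4, 4] = 2.0
        vox[9, 4, 4] = 2.0
        assert find_max_suv_slice(_img(vox), FULL).slice_index == 3

    def test_uniform_bbox_gives_lowest_slice(self):
        vox = np.ones((16, 16, 16))
        bbox = ((5, 12), (2, 10), (3, 11))
        assert find_max_suv_slice(_img(vox), bbox).slice_index == 5

    def test_all_zero_bbox_degenerate(self):
        vox = np.zeros((16, 16, 16))
        vox[0, 0, 0] = 1.0
        with pytest.raises(DegenerateInputError):
            find_max_suv_slice(_img(vox), ((8, 16), (8, 16), (8, 16)))

    def test_bad_bbox_rejected(self):
        with pytest.raises(ValueError):
            find_max_suv_slice(_img(np.ones((8, 8, 8))), ((0, 9), (0, 8), (0, 8)))
        with pytest.raises(ValueError):
            find_max_suv_slice(_img(np.ones((8, 8, 8))), ((4, 4), (0, 8), (0, 8)))


class TestRegionGrow:
    def test_uniform_disk_equals_threshold_oracle(self):
        vox = np.zeros((8, 32, 32))
        yy, xx = np.mgrid[:32, :32]
        disk = (yy - 16) ** 2 + (xx - 16) ** 2 <= 8 ** 2
        vox[4, disk] = 1.0
        img = _img(vox)
        seed = find_max_suv_slice(img, ((0, 8), (0, 32), (0, 32)))
        grown = region_grow_2d(img, seed)
        assert np.array_equal(grown, disk)

    def test_single_hot_voxel_is_its_own_mask(self):
        vox = np.zeros((8, 16, 16))
        vox[2, 7, 7] = 5.0
        img = _img(vox)
        seed = find_max_suv_slice(img, ((0, 8), (0, 16), (0, 16)))
        grown = region_grow_2d(img, seed)
        assert grown.sum() == 1 and grown[7, 7]

    def test_growth_respects_connectivity(self):
        # two disks separated by zeros: only the seeded one is returned
        vox = np.zeros((4, 16, 32))
        yy, xx = np.mgrid[:16, :32]
        a = (yy - 8) ** 2 + (xx - 8) ** 2 <= 9
        b = (yy - 8) ** 2 + (xx - 24) ** 2 <= 9
        vox[2, a] = 2.0  # hotter: seeds in A
        vox[2, b] = 1.9
        img = _img(vox)
        seed = find_max_suv_slice(img, ((0, 4), (0, 16), (0, 32)))
        grown = region_grow_2d(img, seed)
        assert np.array_equal(grown, a)


class TestActiveSurface:
    def test_sphere_volume_recovered(self, crisp_sphere):
        img, truth = crisp_sphere
        mask = segment_mtv(img, BBOX64)
        true_n = truth.masks[0].sum()
        assert abs(mask.voxel_count - true_n) / true_n < 0.05

    def test_converged_mask_is_fixed_point(self, crisp_sphere):
        img, _ = crisp_sphere
        mask = segment_mtv(img, BBOX64)
        inside = np.zeros(img.shape, dtype=bool)
        inside[tuple(slice(lo, hi) for lo, hi in BBOX64)] = True
        again = _acwe_step(img.voxels, mask.voxels, inside,
                           float(img.voxels.sum()), img.voxels.size, 0)
        assert np.array_equal(again, mask.voxels)

    def test_two_spheres_seeded_component_only(self):
        from petquant import Lesion, PhantomSpec

        spec = PhantomSpec(
            lesions=(Lesion((16, 16, 10), 3.0, 2.0), Lesion((16, 16, 24), 3.0, 1.5)),
            shape=(64, 64, 64), background_suv=0.0, psf_sigma_mm=0.0,
        )
        img, truth = make_phantom(spec)
        mask = segment_mtv(img, BBOX64)
        assert np.array_equal(mask.voxels, truth.masks[0])
        assert not np.any(mask.voxels & truth.masks[1])

    def test_empty_init_rejected(self, crisp_sphere):
        img, _ = crisp_sphere
        seed = find_max_suv_slice(img, BBOX64)
        with pytest.raises(SegmentationError):
            evolve_active_surface(img, np.zeros(img.shape[1:], dtype=bool), seed)


class TestSegmentMTV:
    def test_operator_independence(self, blurred_sphere):
        img, _ = blurred_sphere
        m1 = segment_mtv(img, ((20, 44), (20, 44), (20, 44)))
        m2 = segment_mtv(img, ((6, 58), (4, 62), (10, 55)))
        assert np.array_equal(m1.voxels, m2.voxels)

    def test_deterministic_across_runs(self, blurred_sphere):
        img, _ = blurred_sphere
        cfg = SegmentationConfig()
        a = segment_mtv(img, BBOX64, cfg)
        b = segment_mtv(img, BBOX64, cfg)
        assert np.array_equal(a.voxels, b.voxels)

    def test_mask_contains_bbox_maximum(self, blurred_sphere):
        img, _ = blurred_sphere
        mask = segment_mtv(img, BBOX64)
        seed = find_max_suv_slice(img, BBOX64)
        assert mask.voxels[seed.seed_voxel]

    def test_single_connected_component(self, blurred_sphere):
        from scipy import ndimage

        img, _ = blurred_sphere
        mask = segment_mtv(img, BBOX64)
        _, n = ndimage.label(mask.voxels, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_all_zero_image_degenerate(self):
        with pytest.raises(DegenerateInputError):
            segment_mtv(_img(np.zeros((16, 16, 16))), FULL)

    def test_noise_robustness_of_mtv(self):
        """<10% background noise moves the recovered MTV by <10%."""
        clean_img, _ = make_phantom(sphere_spec(4.0, psf=0.8))
        noisy_img, _ = make_phantom(
            sphere_spec(4.0, psf=0.8, noise="gaussian", noise_param=0.05, seed=42)
        )
        n_clean = segment_mtv(clean_img, BBOX64).voxel_count
        n_noisy = segment_mtv(noisy_img, BBOX64).voxel_count
        assert abs(n_noisy - n_clean) / n_clean < 0.10

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SegmentationConfig(rg_fraction=1.5)
        with pytest.raises(ValueError):
            SegmentationConfig(ac_max_iter=0)
        with pytest.raises(ValueError):
            SegmentationConfig(ac_converged_window=0)
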