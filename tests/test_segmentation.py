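"""Segmentation chain: threshold, morphology, tube removal, masking."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import disk

from spikect.errors import (
    EmptyMaskError,
    NoBimodalityError,
    ParameterError,
    StageError,
)
from spikect.phantom import generate_phantom
from spikect.segmentation import (
    BinaryMask,
    SegmentationParams,
    ThresholdResult,
    binarize,
    compute_threshold,
    filter_small_objects,
    mask_original,
    morphological_cleanup,
    remove_largest_component,
    segment_spike,
)
from spikect.volume_io import ScanMeta, Volume

from conftest import small_spec

META = ScanMeta(sample_id="t", voxel_pitch_um=68.8)


def bimodal_volume(plant_fraction=0.03, shape=(40, 64, 64), seed=0):
    """Two-mode grey volume: background 5000+/-800, plant 20000+/-1500."""
    rng = np.random.default_rng(seed)
    data = rng.normal(5000, 800, shape)
    n_plant = int(plant_fraction * data.size)
    flat = data.reshape(-1)
    flat[:n_plant] = rng.normal(20000, 1500, n_plant)
    return Volume(np.clip(data, 0, 65535).astype(np.uint16), META), n_plant


class TestThreshold:
    def test_valley_lies_between_the_modes(self):
        vol, _ = bimodal_volume()
        res = compute_threshold(vol)
        assert 8000 < res.grain_threshold < 17000
        assert res.mode_lo < res.grain_threshold < res.mode_hi

    def test_planted_fraction_is_recovered(self):
        vol, n_plant = bimodal_volume(plant_fraction=0.03)
        res = compute_threshold(vol)
        frac = (vol.data >= res.grain_threshold).mean()
        assert frac == pytest.approx(n_plant / vol.data.size, abs=0.01)

    def test_constant_volume_has_no_bimodality(self):
        vol = Volume(np.full((8, 8, 8), 1000, dtype=np.uint16), META)
        with pytest.raises(NoBimodalityError):
            compute_threshold(vol)

    def test_threshold_between_planted_mode_means_on_phantom(
        self, segmented_small
    ):
        _, _, _, _, thr = segmented_small
        assert 5000 < thr.grain_threshold < 20000

    def test_inverted_mode_order_is_rejected(self):
        with pytest.raises(ParameterError):
            ThresholdResult(
                grain_threshold=100,
                histogram=np.zeros(65536),
                mode_lo=200,
                mode_hi=300,
            )


class TestBinarize:
    def test_all_zero_gives_all_false(self):
        vol = Volume(np.zeros((4, 4, 4), dtype=np.uint16), META)
        assert not binarize(vol, 1).data.any()

    def test_saturated_volume_gives_all_true(self):
        vol = Volume(np.full((4, 4, 4), 65535, dtype=np.uint16), META)
        assert binarize(vol, 1).data.all()

    def test_count_matches_direct_scan(self):
        rng = np.random.default_rng(3)
        vol = Volume(rng.integers(0, 65536, (10, 12, 12)).astype(np.uint16), META)
        t = 30000
        assert binarize(vol, t).count() == int((vol.data >= t).sum())

    def test_out_of_range_threshold_is_rejected(self):
        vol = Volume(np.zeros((4, 4, 4), dtype=np.uint16), META)
        with pytest.raises(ParameterError):
            binarize(vol, 0)


class TestCleanup:
    def test_isolated_voxel_smaller_than_se_vanishes(self):
        mask = np.zeros((11, 31, 31), dtype=bool)
        mask[5, 15, 15] = True
        out = morphological_cleanup(BinaryMask(mask), SegmentationParams())
        assert not out.data.any()

    def test_matches_independently_composed_stages(self):
        # independent oracle: skimage 2D erosion/dilation per slice and a
        # true median filter, composed by hand
        rng = np.random.default_rng(7)
        mask = ndimage.binary_dilation(
            rng.random((12, 40, 40)) > 0.97, np.ones((3, 5, 5), bool)
        )
        params = SegmentationParams(se_radius=2, median_radius=1)
        got = morphological_cleanup(BinaryMask(mask), params).data

        se2d = disk(2)
        eroded = np.stack(
            [ndimage.binary_erosion(s, structure=se2d) for s in mask]
        )
        med = ndimage.median_filter(eroded.astype(np.uint8), size=3) > 0
        expected = np.stack(
            [ndimage.binary_dilation(s, structure=se2d) for s in med]
        )
        assert np.array_equal(got, expected)

    def test_cube_core_is_retained_and_output_within_dilated_erosion(self):
        mask = np.zeros((41, 41, 41), dtype=bool)
        mask[5:36, 5:36, 5:36] = True
        params = SegmentationParams(se_radius=5, median_radius=2)
        out = morphological_cleanup(BinaryMask(mask), params).data
        core = np.zeros_like(mask)
        core[10:31, 10:31, 10:31] = True  # >= 5 voxels from any face
        assert (out[core]).all()
        se = disk(5)[None]
        eroded = ndimage.binary_erosion(mask, structure=se)
        assert not (out & ~ndimage.binary_dilation(eroded, structure=se)).any()

    def test_nearly_idempotent_on_phantom(self, segmented_small):
        vol, _, _, _, _ = segmented_small
        thr = compute_threshold(vol)
        params = SegmentationParams()
        once = morphological_cleanup(
            binarize(vol, thr.grain_threshold), params
        )
        twice = morphological_cleanup(once, params)
        first_pass_changed = int(
            (binarize(vol, thr.grain_threshold).data != once.data).sum()
        )
        second_pass_changed = int((once.data != twice.data).sum())
        assert second_pass_changed < 0.05 * first_pass_changed

    def test_se_larger_than_mask_is_a_parameter_error(self):
        mask = BinaryMask(np.ones((3, 5, 5), dtype=bool))
        with pytest.raises(ParameterError):
            morphological_cleanup(mask, SegmentationParams(se_radius=5))


def _hollow_cylinder_with_blobs():
    shape = (40, 64, 64)
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:64, 0:64]
    r2 = (yy - 31.5) ** 2 + (xx - 31.5) ** 2
    shell = (r2 <= 30**2) & (r2 >= 27**2)
    mask[:] = shell
    centers = [(8, 31, 31), (16, 25, 35), (24, 38, 28), (31, 31, 40), (35, 25, 25)]
    for cz, cy, cx in centers:
        zz, yy2, xx2 = np.mgrid[-3:4, -3:4, -3:4]
        ball = zz**2 + yy2**2 + xx2**2 <= 9
        mask[cz - 3 : cz + 4, cy - 3 : cy + 4, cx - 3 : cx + 4] |= ball
    return mask, len(centers)


class TestRemoveLargest:
    def test_tube_is_removed_and_grains_remain(self):
        mask, n_blobs = _hollow_cylinder_with_blobs()
        out = remove_largest_component(BinaryMask(mask))
        _, n = ndimage.label(out.data, structure=np.ones((3, 3, 3)))
        assert n == n_blobs

    def test_single_component_becomes_empty(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        assert not remove_largest_component(BinaryMask(mask)).data.any()

    def test_empty_mask_is_an_error(self):
        with pytest.raises(EmptyMaskError):
            remove_largest_component(BinaryMask(np.zeros((4, 4, 4), bool)))

    def test_removed_component_has_maximal_size(self):
        rng = np.random.default_rng(11)
        mask = ndimage.binary_dilation(
            rng.random((20, 20, 20)) > 0.98, np.ones((3, 3, 3), bool)
        )
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        if n < 2:
            pytest.skip("degenerate draw")
        sizes = np.bincount(labels.ravel())[1:]
        out = remove_largest_component(BinaryMask(mask))
        assert mask.sum() - out.data.sum() == sizes.max()


class TestSizeFilter:
    def test_inclusive_boundary_at_min_size(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask.reshape(-1)[:999] = True  # a 999-voxel slab-like component
        out = filter_small_objects(BinaryMask(mask.copy()), 1000)
        assert not out.data.any()
        mask.reshape(-1)[:1000] = True
        out = filter_small_objects(BinaryMask(mask), 1000)
        assert out.data.sum() == 1000

    def test_empty_mask_passes_through(self):
        out = filter_small_objects(BinaryMask(np.zeros((4, 4, 4), bool)), 10)
        assert not out.data.any()

    def test_component_count_non_increasing_in_min_size(self):
        rng = np.random.default_rng(5)
        mask = ndimage.binary_dilation(
            rng.random((30, 30, 30)) > 0.985, np.ones((3, 3, 3), bool)
        )
        counts = []
        for ms in (1, 10, 100, 1000, 10000):
            out = filter_small_objects(BinaryMask(mask), ms)
            _, n = ndimage.label(out.data, structure=np.ones((3, 3, 3)))
            counts.append(n)
        assert counts == sorted(counts, reverse=True)


class TestMaskOriginal:
    def test_full_mask_is_identity(self):
        rng = np.random.default_rng(1)
        vol = Volume(rng.integers(0, 65536, (6, 8, 8)).astype(np.uint16), META)
        out = mask_original(vol, BinaryMask(np.ones(vol.shape, bool)))
        assert np.array_equal(out.data, vol.data)

    def test_empty_mask_zeroes_everything(self):
        rng = np.random.default_rng(2)
        vol = Volume(rng.integers(1, 65536, (6, 8, 8)).astype(np.uint16), META)
        out = mask_original(vol, BinaryMask(np.zeros(vol.shape, bool)))
        assert not out.data.any()

    def test_random_mask_keeps_grey_values_bit_identical(self):
        rng = np.random.default_rng(3)
        vol = Volume(rng.integers(0, 65536, (6, 8, 8)).astype(np.uint16), META)
        mask = BinaryMask(rng.random(vol.shape) > 0.5)
        out = mask_original(vol, mask)
        assert np.array_equal(out.data[mask.data], vol.data[mask.data])
        assert not out.data[~mask.data].any()

    def test_shape_mismatch_is_rejected(self):
        vol = Volume(np.zeros((4, 4, 4), dtype=np.uint16), META)
        with pytest.raises(ParameterError):
            mask_original(vol, BinaryMask(np.zeros((4, 4, 5), bool)))


class TestSegmentSpike:
    def test_recovers_planted_grain_count(self, segmented_small):
        _, truth, _, mask, _ = segmented_small
        _, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3)))
        assert n == len(truth.grains)

    def test_grey_values_inside_final_mask_are_unchanged(self, segmented_small):
        vol, _, masked, mask, _ = segmented_small
        assert np.array_equal(masked.data[mask.data], vol.data[mask.data])
        assert not masked.data[~mask.data].any()

    def test_tube_removal_guard_keeps_grains_without_tube(self):
        vol, truth = generate_phantom(
            small_spec(
                n_spikelet_pairs=4,
                volume_shape=(224, 96, 96),
                tube=False,
                n_noise_specks=0,
                seed=9,
            )
        )
        _, mask, _ = segment_spike(vol)
        _, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3)))
        assert n == len(truth.grains)

    def test_stage_errors_carry_the_stage_name(self):
        vol = Volume(np.full((8, 8, 8), 42, dtype=np.uint16), META)
        with pytest.raises(StageError, match="threshold"):
            segment_spike(vol)
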