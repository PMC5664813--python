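"""Rachis detection, spike height, portion rejoining, region assignment."""

import copy
from dataclasses import replace

import numpy as np
import pytest

from spikect.errors import NoMaterialError, ParameterError, PortionMismatchError
from spikect.morphometry import GrainRecord, measure_all
from spikect.phantom import generate_phantom
from spikect.segmentation import ThresholdResult, segment_spike
from spikect.separation import separate_grains
from spikect.spike import (
    Portion,
    RachisExtent,
    assign_regions,
    detect_rachis_extent,
    rejoin_portions,
    spike_height,
    summarize_spike,
)
from spikect.volume_io import ScanMeta, Volume

from conftest import small_spec

META = ScanMeta(sample_id="s1", voxel_pitch_um=68.8)


def make_grain(i, z, vol_mm3=1.0, spike="s1"):
    return GrainRecord(
        spike_id=spike,
        grain_index=i,
        centroid_vox=(10.0, 20.0, float(z)),
        z_mm=z * 68.8 / 1000,
        length_mm=6.0,
        width_mm=3.0,
        depth_mm=2.5,
        volume_vox=1000,
        volume_mm3=vol_mm3,
        surface_area_mm2=20.0,
        sphericity=0.9,
    )


class TestRachisDetection:
    def test_extent_matches_planted_rachis(self, segmented_small):
        vol, truth, _, _, thr = segmented_small
        ext = detect_rachis_extent(vol, thr)
        z_lo, z_hi = truth.rachis_extent
        assert abs(ext.z_low - z_lo) <= 2
        assert abs(ext.z_high - z_hi) <= 2
        assert ext.relaxed_threshold == int(round(0.8 * thr.grain_threshold))
        assert ext.relaxed_threshold < thr.grain_threshold

    def test_extent_covers_grain_centroids(self, labelled_small):
        vol, truth, masked, mask, thr, labels = labelled_small
        ext = detect_rachis_extent(vol, thr)
        for g in truth.grains:
            assert ext.z_low <= g.center_zyx[0] <= ext.z_high

    def test_material_in_every_slice_spans_the_volume(self):
        rng = np.random.default_rng(0)
        data = rng.normal(5000, 300, (40, 48, 48))
        yy, xx = np.mgrid[0:48, 0:48]
        core = (yy - 23.5) ** 2 + (xx - 23.5) ** 2 <= 15**2
        data[:, core] = rng.normal(20000, 500, (40, int(core.sum())))
        vol = Volume(np.clip(data, 0, 65535).astype(np.uint16), META)
        thr = ThresholdResult(12000, np.zeros(65536), 5000, 20000)
        ext = detect_rachis_extent(vol, thr)
        assert ext.z_low == 0 and ext.z_high == 39

    def test_empty_volume_has_no_material(self):
        vol = Volume(np.zeros((10, 16, 16), dtype=np.uint16), META)
        thr = ThresholdResult(12000, np.zeros(65536), 5000, 20000)
        with pytest.raises(NoMaterialError):
            detect_rachis_extent(vol, thr)


class TestSpikeHeight:
    def test_thousand_slices_at_routine_pitch(self):
        ext = RachisExtent(0, 999, 9000)
        assert spike_height(ext, META) == pytest.approx(68.8)

    def test_single_slice_is_one_voxel_tall(self):
        ext = RachisExtent(5, 5, 9000)
        assert spike_height(ext, META) == pytest.approx(68.8 / 1000)

    def test_scales_linearly_with_pitch(self):
        ext = RachisExtent(10, 109, 9000)
        h1 = spike_height(ext, ScanMeta("a", 50.0))
        h2 = spike_height(ext, ScanMeta("a", 100.0))
        assert h2 == pytest.approx(2 * h1)


class TestRejoin:
    def bottom(self, zs, n_slices=400, invert=False):
        meta = ScanMeta("s1", 68.8, portion="bottom")
        recs = [make_grain(i + 1, z, vol_mm3=1.0 + 0.001 * z) for i, z in enumerate(zs)]
        return Portion(recs, n_slices, meta, invert=invert)

    def top(self, zs, n_slices=600, invert=False):
        meta = ScanMeta("s1", 68.8, portion="top")
        recs = [make_grain(i + 1, z, vol_mm3=2.0 + 0.001 * z) for i, z in enumerate(zs)]
        return Portion(recs, n_slices, meta, invert=invert)

    def test_offset_arithmetic_without_inversion(self):
        joined = rejoin_portions(
            self.bottom([50, 200]), self.top([10, 500])
        )
        assert sorted(r.centroid_vox[2] for r in joined) == [50, 200, 410, 900]
        assert len(joined) == 4

    def test_inversion_formula_on_top_portion(self):
        joined = rejoin_portions(
            self.bottom([50], n_slices=400),
            self.top([10], n_slices=500, invert=True),
        )
        top_rec = max(joined, key=lambda r: r.centroid_vox[2])
        assert top_rec.centroid_vox[2] == (500 - 1) - 10 + 400

    def test_non_positional_traits_are_preserved_bit_exactly(self):
        b = self.bottom([50, 200])
        t = self.top([10, 500], invert=True)
        originals = [copy.deepcopy(r) for r in b.records + t.records]
        joined = rejoin_portions(b, t)
        by_vol = {r.volume_mm3 for r in joined}
        for orig in originals:
            assert orig.volume_mm3 in by_vol
        for rec, orig in zip(
            sorted(joined, key=lambda r: r.length_mm),
            sorted(originals, key=lambda r: r.length_mm),
        ):
            assert rec.length_mm == orig.length_mm
            assert rec.width_mm == orig.width_mm
            assert rec.depth_mm == orig.depth_mm
            assert rec.volume_vox == orig.volume_vox
            assert rec.surface_area_mm2 == orig.surface_area_mm2
            assert rec.sphericity == orig.sphericity

    def test_pitch_mismatch_is_rejected(self):
        b = self.bottom([50])
        t = self.top([10])
        t.meta = ScanMeta("s1", 34.4, portion="top")
        with pytest.raises(PortionMismatchError, match="pitch"):
            rejoin_portions(b, t)

    def test_duplicate_roles_are_rejected(self):
        with pytest.raises(PortionMismatchError):
            rejoin_portions(self.bottom([50]), self.bottom([60]))

    def test_different_spikes_are_rejected(self):
        b = self.bottom([50])
        t = self.top([10])
        t.meta = ScanMeta("s2", 68.8, portion="top")
        with pytest.raises(PortionMismatchError):
            rejoin_portions(b, t)


@pytest.fixture(scope="module")
def whole_and_split():
    spec = small_spec(
        n_spikelet_pairs=6,
        volume_shape=(320, 96, 96),
        seed=21,
        n_noise_specks=0,
        split_at_slice=None,
    )

    def process(vol):
        masked, mask, thr = segment_spike(vol)
        return measure_all(separate_grains(mask), masked, vol.meta)

    whole_vol, _ = generate_phantom(spec)
    whole = process(whole_vol)
    (bot, top), _ = generate_phantom(
        replace(spec, split_at_slice=160, flip_top_portion=False)
    )
    joined = rejoin_portions(
        Portion(process(bot), bot.n_slices, bot.meta, invert=False),
        Portion(process(top), top.n_slices, top.meta, invert=False),
    )
    return whole, joined


class TestSplitRejoinIdentity:
    """Splitting a phantom into portions and rejoining reproduces the
    whole-spike measurements; only z changes, by a constant per-portion
    offset (plus optional inversion)."""

    def test_grain_count_is_the_sum_of_portions(self, whole_and_split):
        whole, joined = whole_and_split
        assert len(joined) == len(whole)

    def test_z_positions_reproduced_exactly(self, whole_and_split):
        whole, joined = whole_and_split
        wz = sorted(r.centroid_vox[2] for r in whole)
        jz = sorted(r.centroid_vox[2] for r in joined)
        assert np.allclose(wz, jz, atol=1e-9)
        assert [round(z) for z in wz] == [round(z) for z in jz]

    def test_all_other_traits_bit_exact(self, whole_and_split):
        whole, joined = whole_and_split
        for w, j in zip(
            sorted(whole, key=lambda r: r.centroid_vox[2]),
            sorted(joined, key=lambda r: r.centroid_vox[2]),
        ):
            assert j.volume_vox == w.volume_vox
            assert j.length_mm == w.length_mm
            assert j.width_mm == w.width_mm
            assert j.depth_mm == w.depth_mm
            assert j.surface_area_mm2 == w.surface_area_mm2
            assert j.sphericity == w.sphericity


class TestRegions:
    EXT = RachisExtent(0, 100, 9000)

    @pytest.mark.parametrize(
        "z,region",
        [(50, "middle"), (33, "bottom"), (34, "middle"), (66, "middle"),
         (67, "top"), (0, "bottom"), (100, "top")],
    )
    def test_boundary_rule(self, z, region):
        recs = assign_regions([make_grain(1, z)], self.EXT)
        assert recs[0].region == region

    def test_all_grains_at_base_are_bottom(self):
        recs = assign_regions([make_grain(i, 0) for i in range(5)], self.EXT)
        assert all(r.region == "bottom" for r in recs)

    def test_uniform_positions_give_middle_fraction(self):
        rng = np.random.default_rng(4)
        zs = rng.uniform(0, 1000, 10_000)
        ext = RachisExtent(0, 1000, 9000)
        recs = assign_regions([make_grain(i, z) for i, z in enumerate(zs)], ext)
        frac = np.mean([r.region == "middle" for r in recs])
        assert frac == pytest.approx(0.32, abs=0.01)

    def test_out_of_extent_positions_are_clamped(self, caplog):
        recs = assign_regions([make_grain(1, 150)], self.EXT)
        assert recs[0].region == "top"

    def test_degenerate_single_slice_extent_is_middle(self):
        recs = assign_regions([make_grain(1, 5)], RachisExtent(5, 5, 9000))
        assert recs[0].region == "middle"


class TestSummary:
    def test_twenty_unit_grains(self):
        recs = assign_regions(
            [make_grain(i, z=i * 5) for i in range(1, 21)],
            RachisExtent(0, 100, 9000),
        )
        summary = summarize_spike(recs, RachisExtent(0, 100, 9000), META)
        assert summary.n_grains == 20
        assert summary.total_grain_volume_mm3 == pytest.approx(20.0)
        assert sum(summary.region_counts.values()) == 20
        assert summary.height_mm == pytest.approx(101 * 68.8 / 1000)

    def test_empty_spike_has_zero_counts(self):
        summary = summarize_spike([], RachisExtent(0, 10, 9000), META)
        assert summary.n_grains == 0
        assert sum(summary.region_counts.values()) == 0

    def test_unassigned_regions_are_rejected(self):
        with pytest.raises(ParameterError, match="unassigned"):
            summarize_spike(
                [make_grain(1, 5)], RachisExtent(0, 10, 9000), META
            )


def test_rejoin_three_portions_by_sequential_offsetting():
    meta_b = ScanMeta("s1", 68.8, portion="bottom")
    meta_m = ScanMeta("s1", 68.8, portion="top")
    meta_t = ScanMeta("s1", 68.8, portion="top")
    portions = [
        Portion([make_grain(1, 10)], 100, meta_b),
        Portion([make_grain(1, 20)], 150, meta_m),
        Portion([make_grain(1, 30)], 200, meta_t),
    ]
    joined = rejoin_portions(*portions)
    assert sorted(r.centroid_vox[2] for r in joined) == [10, 120, 280]
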