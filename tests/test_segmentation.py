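import numpy as np
import pandas as pd
import pytest

from damagemap.segmentation import (
    MarkerMask,
    SegmentationConfig,
    ThresholdMethod,
    build_cell_table,
    extract_patch,
    extract_patches,
    superimpose_filter,
    threshold_channel,
)
from damagemap.volume_io import ChannelName, ChannelVolume, LabelVolume


def make_mask(arr):
    return MarkerMask(mask=np.asarray(arr, dtype=bool), threshold_value=0.5,
                      method=ThresholdMethod.FIXED)


class TestThresholdChannel:
    def test_fixed_threshold_recovers_blob_exactly(self):
        data = np.zeros((4, 16, 16), dtype=np.float32)
        data[1:3, 4:8, 4:8] = 255.0
        vol = ChannelVolume(data, ChannelName.GH2AX)
        mask = threshold_channel(vol, ThresholdMethod.FIXED, 100.0)
        np.testing.assert_array_equal(mask.mask, data > 100)
        assert mask.threshold_value == 100.0

    def test_otsu_covers_planted_foci(self, small_region):
        channels, _, truth = small_region
        mask = threshold_channel(channels[ChannelName.GH2AX])
        assert mask.mask[truth.foci_mask].mean() >= 0.99

    def test_constant_channel_with_otsu_advises_fixed(self):
        vol = ChannelVolume(np.full((2, 8, 8), 7.0), ChannelName.CD8)
        with pytest.raises(ValueError, match="FIXED"):
            threshold_channel(vol, ThresholdMethod.OTSU)
        with pytest.raises(ValueError, match="fixed_value"):
            threshold_channel(vol, ThresholdMethod.FIXED)


class TestSuperimposeFilter:
    def _nucleus_and_mask(self):
        labels = np.zeros((5, 10, 10), dtype=np.int32)
        labels[0:1, 0:10, 0:10] = 1  # 100 voxels
        mask = np.zeros_like(labels, dtype=bool)
        mask[0, 0:6, 0:10] = True  # covers 60 of them
        return LabelVolume(labels), make_mask(mask)

    def test_hand_counted_overlap_fraction(self):
        labels, mask = self._nucleus_and_mask()
        [(cid, frac, pos)] = superimpose_filter(labels, mask, 0.5, 0)
        assert (cid, frac, pos) == (1, 0.6, True)

    def test_disjoint_mask_gives_zero_negative(self):
        labels = np.zeros((3, 8, 8), dtype=np.int32)
        labels[0, :4, :4] = 1
        mask = np.zeros_like(labels, dtype=bool)
        mask[2, 6:, 6:] = True
        [(_, frac, pos)] = superimpose_filter(LabelVolume(labels), make_mask(mask), 0.5, 0)
        assert frac == 0.0 and not pos

    def test_monotone_in_overlap_threshold(self):
        labels, mask = self._nucleus_and_mask()
        positives = []
        for thr in (0.2, 0.4, 0.6, 0.8, 1.0):
            res = superimpose_filter(labels, mask, thr, 0)
            positives.append(sum(p for _, _, p in res))
        assert positives == sorted(positives, reverse=True)

    def test_zero_dilation_matches_brute_force_voxel_loop(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, size=(8, 12, 12)).astype(np.int32)
        mask = rng.random((8, 12, 12)) < 0.3
        res = {cid: frac for cid, frac, _ in
               superimpose_filter(LabelVolume(labels), make_mask(mask), 0.5, 0)}
        for cid in (1, 2, 3):
            inter = size = 0
            for z in range(8):
                for y in range(12):
                    for x in range(12):
                        if labels[z, y, x] == cid:
                            size += 1
                            inter += bool(mask[z, y, x])
            assert res[cid] == pytest.approx(inter / size)

    def test_intersections_bounded_by_mask_size(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 5, size=(6, 10, 10)).astype(np.int32)
        mask = rng.random((6, 10, 10)) < 0.4
        lv = LabelVolume(labels)
        total_inter = 0
        for cid, frac, _ in superimpose_filter(lv, make_mask(mask), 0.5, 0):
            total_inter += frac * (labels == cid).sum()
        assert total_inter <= mask.sum() + 1e-9

    def test_membrane_shell_flips_with_dilation(self):
        """A 1-voxel-offset shell overlaps only after the nucleus is dilated."""
        labels = np.zeros((20, 20, 20), dtype=np.int32)
        zz, yy, xx = np.mgrid[0:20, 0:20, 0:20]
        r2 = (zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2
        labels[r2 <= 5**2] = 1
        shell = (r2 > 6**2) & (r2 <= 8**2)
        [(_, f0, p0)] = superimpose_filter(LabelVolume(labels), make_mask(shell), 0.2, 0)
        [(_, f2, p2)] = superimpose_filter(LabelVolume(labels), make_mask(shell), 0.2, 2)
        assert f0 == 0.0 and not p0
        assert f2 > 0.2 and p2

    def test_dilation_never_merges_instances(self):
        labels = np.zeros((1, 5, 12), dtype=np.int32)
        labels[0, 1:4, 1:4] = 1
        labels[0, 1:4, 8:11] = 2
        mask = np.ones_like(labels, dtype=bool)
        res = superimpose_filter(LabelVolume(labels), make_mask(mask), 0.5, 3)
        assert {cid for cid, _, _ in res} == {1, 2}
        # contested middle voxels go to the nearest instance; fractions stay 1.0 here
        for _, frac, _ in res:
            assert frac == 1.0

    def test_shape_mismatch_rejected(self):
        labels = LabelVolume(np.zeros((2, 4, 4), dtype=np.int32))
        with pytest.raises(ValueError, match="mismatch"):
            superimpose_filter(labels, make_mask(np.zeros((2, 4, 5), dtype=bool)), 0.5, 0)


class TestBuildCellTable:
    def test_empty_labels_give_empty_table(self):
        labels = LabelVolume(np.zeros((2, 4, 4), dtype=np.int32))
        empty = make_mask(np.zeros((2, 4, 4), dtype=bool))
        table = build_cell_table(labels, empty, empty)
        assert len(table.df) == 0

    def test_centroid_is_unweighted_voxel_mean(self):
        labels = np.zeros((6, 8, 8), dtype=np.int32)
        labels[2:4, 3:6, 3:6] = 1
        empty = make_mask(np.zeros_like(labels, dtype=bool))
        table = build_cell_table(LabelVolume(labels), empty, empty)
        row = table.df.iloc[0]
        assert (row.centroid_z, row.centroid_y, row.centroid_x) == (2.5, 4.0, 4.0)
        assert (row.z0, row.y0, row.x0, row.z1, row.y1, row.x1) == (2, 3, 3, 4, 6, 6)
        assert row.voxel_count == 2 * 3 * 3

    def test_positivity_calls_match_ground_truth(self, segmented_region):
        """With 3-sigma-separated intensities, calls equal the planted flags exactly."""
        truth = segmented_region["truth"].cells
        df = segmented_region["table"].df
        merged = df.merge(truth, on="cell_id", suffixes=("", "_true"))
        assert (merged.gh2ax_pos == merged.gh2ax_pos_true).all()
        assert (merged.cd8_pos == merged.cd8_pos_true).all()
        assert df.gh2ax_pos.sum() == truth.gh2ax_pos.sum()


class TestExtractPatch:
    def _square_record(self):
        labels = np.zeros((3, 30, 30), dtype=np.int32)
        labels[1, 10:20, 10:20] = 1
        data = np.zeros((3, 30, 30), dtype=np.float32)
        data[1, 10:20, 10:20] = np.linspace(50, 250, 100).reshape(10, 10)
        record = pd.Series(dict(cell_id=1, z0=1, y0=10, x0=10, z1=2, y1=20, x1=20))
        vol = ChannelVolume(data, ChannelName.GH2AX)
        return vol, record, LabelVolume(labels)

    def test_square_nucleus_centered_and_scaled(self):
        vol, record, labels = self._square_record()
        patch = extract_patch(vol, record, labels, size=64)
        assert patch.shape == (64, 64)
        assert patch.max() == pytest.approx(1.0) and patch.min() == 0.0
        ys, xs = np.nonzero(patch)
        assert ys.min() == 27 and ys.max() == 36  # 10 px block centered on 64
        assert xs.min() == 27 and xs.max() == 36

    def test_constant_slice_maps_to_zeros(self):
        labels = np.zeros((1, 20, 20), dtype=np.int32)
        labels[0, 5:15, 5:15] = 1
        data = np.full((1, 20, 20), 99.0, dtype=np.float32)
        record = pd.Series(dict(cell_id=1, z0=0, y0=5, x0=5, z1=1, y1=15, x1=15))
        patch = extract_patch(ChannelVolume(data, ChannelName.GH2AX), record,
                              LabelVolume(labels), size=64, mask_background=False)
        assert np.all(patch == 0.0)

    def test_oversized_nucleus_is_rescaled_into_canvas(self):
        labels = np.zeros((1, 200, 120), dtype=np.int32)
        labels[0, 10:190, 10:110] = 1
        data = np.zeros((1, 200, 120), dtype=np.float32)
        data[0, 10:190, 10:110] = np.linspace(50, 100, 100)[None, :]
        record = pd.Series(dict(cell_id=1, z0=0, y0=10, x0=10, z1=1, y1=190, x1=110))
        patch = extract_patch(ChannelVolume(data, ChannelName.GH2AX), record,
                              LabelVolume(labels), size=64)
        assert patch.shape == (64, 64)
        assert patch.max() == pytest.approx(1.0)

    def test_degenerate_bbox_skipped_with_warning(self):
        labels = np.zeros((1, 5, 5), dtype=np.int32)
        labels[0, 2, 2] = 1
        record = pd.Series(dict(cell_id=1, z0=0, y0=2, x0=2, z1=1, y1=3, x1=3))
        vol = ChannelVolume(np.ones((1, 5, 5)), ChannelName.GH2AX)
        with pytest.warns(UserWarning, match="degenerate"):
            assert extract_patch(vol, record, LabelVolume(labels)) is None

    def test_one_patch_per_positive_cell(self, segmented_region):
        table = segmented_region["table"]
        patches = extract_patches(
            segmented_region["channels"][ChannelName.GH2AX], table, segmented_region["labels"]
        )
        assert len(patches) == int(table.df.gh2ax_pos.sum())
        for p in patches.values():
            assert p.shape == (64, 64) and 0 <= p.min() and p.max() <= 1
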