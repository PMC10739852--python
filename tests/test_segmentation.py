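"""Background correction, binarization, labeling, measurement, debris."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgccscope.io import MultiChannelField
from pgccscope.segmentation import (
    LabelImage,
    SegmentationParams,
    binarize,
    correct_background,
    extract_records,
    filter_debris,
    label_components,
    segment_field,
)


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Independent brute-force connected-component oracle (BFS flood fill)."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    labels = np.zeros((H, W), dtype=int)
    nxt = 0
    for r0 in range(H):
        for c0 in range(W):
            if mask[r0, c0] and labels[r0, c0] == 0:
                nxt += 1
                stack = [(r0, c0)]
                labels[r0, c0] = nxt
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = nxt
                            stack.append((rr, cc))
    return labels


def labelings_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """Same partition of foreground pixels, up to label permutation."""
    if (a > 0).sum() != (b > 0).sum() or a.max() != b.max():
        return False
    fg = a > 0
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    return len(pairs) == a.max() and len({p[0] for p in pairs}) == a.max()


class TestCorrectBackground:
    def test_constant_image_maps_to_zero(self):
        out = correct_background(np.full((64, 64), 7.0), radius=5)
        np.testing.assert_array_equal(out, np.zeros((64, 64)))

    def test_contrast_enhancement_of_small_disk_on_ramp(self):
        """A bright disk smaller than the structuring element on a linear ramp
        gains contrast over the background after correction."""
        H = W = 128
        r, c = np.mgrid[:H, :W]
        img = 100.0 + 0.5 * c  # linear ramp
        disk_mask = (r - 64) ** 2 + (c - 64) ** 2 <= 5**2
        img[disk_mask] += 80.0
        out = correct_background(img, radius=20)
        in_contrast = img[disk_mask].mean() / img[~disk_mask].mean()
        out_bg = out[~disk_mask]
        out_contrast = out[disk_mask].mean() / max(out_bg.mean(), 1e-9)
        assert out_contrast > in_contrast

    def test_planar_background_suppressed(self):
        """On a field with a steep illumination plane, the corrected image
        correlates with the plane far less than the raw image does."""
        from pgccscope.simulate import SimParams, simulate_field

        params = SimParams(
            image_shape=(512, 512), n_non_pgcc=15, n_pgcc=2, n_dead=0, n_debris=0,
            background_slope=(3.0, 2.0), n_background_blobs=0, seed=2,
        )
        field, _ = simulate_field(params)
        img = field["nuclei"]
        H, W = img.shape
        r, c = np.mgrid[:H, :W]
        plane = 3.0 * r + 2.0 * c
        out = correct_background(img, radius=50)
        corr_in = np.corrcoef(img.ravel(), plane.ravel())[0, 1]
        corr_out = np.corrcoef(out.ravel(), plane.ravel())[0, 1]
        assert corr_in > 0.5  # the raw image is dominated by the plane
        assert abs(corr_out) < abs(corr_in)

    def test_radius_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            correct_background(np.zeros((32, 32)), radius=32)


class TestBinarize:
    def test_two_level_image(self):
        img = np.full((16, 16), 0.1)
        img[4:8, 4:8] = 0.9
        mask = binarize(img, SegmentationParams())
        np.testing.assert_array_equal(mask, img == 0.9)

    def test_fixed_threshold(self):
        img = np.array([[0.4, 0.6], [0.6, 0.4]])
        p = SegmentationParams(binarize_method="fixed", fixed_threshold=0.5)
        np.testing.assert_array_equal(binarize(img, p), img == 0.6)

    def test_single_valued_image_warns_empty(self):
        with pytest.warns(UserWarning, match="single-valued"):
            mask = binarize(np.full((8, 8), 0.5), SegmentationParams())
        assert not mask.any()

    def test_simulated_field_jaccard(self, default_field_truth):
        """At default SNR the binarized mask overlaps the true nucleus mask
        with Jaccard >= 0.8."""
        from pgccscope.simulate import SimParams, simulate_field

        field, truth, labels = simulate_field(SimParams(seed=1), return_labels=True)
        p = SegmentationParams.for_magnification(10)
        corr = correct_background(field["nuclei"], p.tophat_radius_px)
        mask = binarize(corr, p)
        true_mask = labels > 0
        jac = (mask & true_mask).sum() / (mask | true_mask).sum()
        assert jac >= 0.8


class TestLabelComponents:
    def test_two_squares(self):
        mask = np.zeros((10, 10), bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True
        li = label_components(mask, SegmentationParams(exclude_border=False))
        assert li.n_objects == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_plus_shape_single_object(self, connectivity):
        mask = np.zeros((7, 7), bool)
        mask[3, 2:5] = True
        mask[2:5, 3] = True
        li = label_components(
            mask, SegmentationParams(connectivity=connectivity, exclude_border=False)
        )
        assert li.n_objects == 1

    def test_diagonal_pixels_split_by_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        p4 = SegmentationParams(connectivity=4, exclude_border=False)
        p8 = SegmentationParams(connectivity=8, exclude_border=False)
        assert label_components(mask, p4).n_objects == 2
        assert label_components(mask, p8).n_objects == 1

    def test_empty_mask(self):
        li = label_components(np.zeros((8, 8), bool), SegmentationParams())
        assert li.n_objects == 0

    def test_exclude_border_removes_touching(self):
        mask = np.zeros((8, 8), bool)
        mask[0:3, 0:3] = True  # touches two edges
        mask[4:7, 4:7] = True  # interior
        li = label_components(mask, SegmentationParams(exclude_border=True))
        assert li.n_objects == 1

    def test_labels_consecutive(self):
        mask = np.zeros((12, 12), bool)
        mask[0:2, 0:2] = True  # removed by border exclusion
        mask[4:6, 4:6] = True
        mask[8:10, 8:10] = True
        li = label_components(mask, SegmentationParams(exclude_border=True))
        assert sorted(np.unique(li.labels)) == [0, 1, 2]

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle_random(self, connectivity, rng):
        """scipy-based labeling agrees with a brute-force flood fill on
        random 16x16 masks."""
        p = SegmentationParams(connectivity=connectivity, exclude_border=False)
        for _ in range(100):
            mask = rng.random((16, 16)) < 0.4
            ours = label_components(mask, p).labels
            oracle = flood_fill_label(mask, connectivity)
            assert labelings_equivalent(ours, oracle)


class TestExtractRecords:
    def _field(self, channels, pixel_size=None):
        return MultiChannelField(
            channels=channels, magnification=10, pixel_size_um=pixel_size
        )

    def test_single_object_area_and_mean(self):
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[3:8, 4:6] = 1  # 10 px
        field = self._field(
            {"nuclei": np.ones((12, 12)), "live": np.full((12, 12), 7.0)}
        )
        rec = extract_records(LabelImage(labels, 1), field)
        assert len(rec) == 1
        assert rec.area_px.iloc[0] == 10
        assert rec.mean_live.iloc[0] == pytest.approx(7.0)

    def test_area_um2_from_pixel_size(self):
        labels = np.zeros((100, 100), dtype=np.int32)
        labels[10:35, 10:85] = 1  # 25*75 = 1875 px
        field = self._field({"nuclei": np.ones((100, 100))}, pixel_size=0.66)
        rec = extract_records(LabelImage(labels, 1), field)
        assert rec.area_um2.iloc[0] == pytest.approx(1875 * 0.66**2)  # 816.75

    def test_centroid_is_mask_mean(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[2:5, 6:8] = 1
        field = self._field({"nuclei": np.zeros((10, 10))})
        rec = extract_records(LabelImage(labels, 1), field)
        assert rec.row.iloc[0] == pytest.approx(3.0)
        assert rec.col.iloc[0] == pytest.approx(6.5)

    def test_shape_mismatch_rejected(self):
        field = self._field({"nuclei": np.zeros((8, 8))})
        with pytest.raises(ValueError, match="match"):
            extract_records(LabelImage(np.zeros((9, 9), np.int32), 0), field)

    def test_simulated_areas_close_to_truth(self, default_field_truth):
        """Measured areas stay within 15% of rendered truth for >= 95% of
        nuclei (debris excluded)."""
        from pgccscope.simulate import SimParams

        field, truth = default_field_truth
        records, _ = segment_field(field)
        cells = truth[truth["class"] != "debris"]
        good = 0
        for t in cells.itertuples():
            d = np.hypot(records.row - t.row, records.col - t.col)
            i = d.idxmin()
            if d[i] < 5 and abs(records.area_px[i] - t.true_area_px) <= 0.15 * t.true_area_px:
                good += 1
        assert good / len(cells) >= 0.95


class TestFilterDebris:
    def test_small_objects_flagged(self):
        rec = pd.DataFrame(
            {"area_px": [10, 400], "ploidy_class": ["unassigned", "unassigned"]}
        )
        out = filter_debris(rec, SegmentationParams(min_area_px=50))
        assert list(out.ploidy_class) == ["debris", "unassigned"]

    def test_min_area_one_flags_nothing(self):
        rec = pd.DataFrame({"area_px": [1, 5], "ploidy_class": ["unassigned"] * 2})
        out = filter_debris(rec, SegmentationParams(min_area_px=1))
        assert (out.ploidy_class == "unassigned").all()

    @given(cutoffs=st.lists(st.integers(1, 500), min_size=2, max_size=2))
    @settings(max_examples=30, deadline=None)
    def test_debris_count_monotone_in_cutoff(self, cutoffs):
        """Raising min_area_px never decreases the debris count."""
        rng = np.random.default_rng(0)
        rec = pd.DataFrame(
            {"area_px": rng.integers(1, 600, 50), "ploidy_class": ["unassigned"] * 50}
        )
        lo, hi = sorted(cutoffs)
        n_lo = (filter_debris(rec, SegmentationParams(min_area_px=lo)).ploidy_class == "debris").sum()
        n_hi = (filter_debris(rec, SegmentationParams(min_area_px=hi)).ploidy_class == "debris").sum()
        assert n_hi >= n_lo


class TestPipelineInvariants:
    def test_conservation(self, default_field):
        records, li = segment_field(default_field)
        assert len(records) == li.n_objects
        n_debris = (records.ploidy_class == "debris").sum()
        assert n_debris + (records.ploidy_class != "debris").sum() == len(records)

    def test_translation_equivariance(self, rng):
        """Shifting all channels by (dr, dc) shifts centroids by exactly
        (dr, dc) and leaves areas and intensity means unchanged."""
        mask = np.zeros((128, 128), bool)
        mask[20:35, 30:48] = True
        mask[60:90, 70:95] = True
        channels = {
            "nuclei": np.where(mask, 3000.0, 100.0) + rng.normal(0, 5, mask.shape),
            "live": np.where(mask, 1500.0, 80.0),
        }
        p = SegmentationParams(exclude_border=False, min_area_px=1)
        dr, dc = 13, 21
        field0 = MultiChannelField(channels=channels, magnification=10)
        field1 = MultiChannelField(
            channels={ch: np.roll(np.roll(im, dr, 0), dc, 1) for ch, im in channels.items()},
            magnification=10,
        )
        rec0 = extract_records(label_components(mask, p), field0)
        rec1 = extract_records(
            label_components(np.roll(np.roll(mask, dr, 0), dc, 1), p), field1
        )
        np.testing.assert_allclose(rec1.row, rec0.row + dr)
        np.testing.assert_allclose(rec1.col, rec0.col + dc)
        np.testing.assert_array_equal(rec1.area_px, rec0.area_px)
        np.testing.assert_allclose(rec1.mean_live, rec0.mean_live)
        np.testing.assert_allclose(rec1.mean_nuclei, rec0.mean_nuclei)

    def test_debris_flagged_on_simulated_field(self, default_field_truth, classified_records):
        field, truth = default_field_truth
        n_true_debris = (truth["class"] == "debris").sum()
        n_flagged = (classified_records.ploidy_class == "debris").sum()
        assert n_flagged >= 0.95 * n_true_debris
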