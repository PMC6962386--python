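import numpy as np
import pytest

from uhdog.hessian_convexity import ConvexityMap
from uhdog.image_io import ImageGrid
from uhdog.joint_detector import (
    BlobSet,
    DetectConfig,
    blob_statistics,
    detect,
    extract_blobs,
    joint_map,
    threshold_probability,
)
from uhdog import synthetic


def flood_fill_count(binary):
    """Independent component counter (iterative flood fill, full neighborhood)."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    offsets = [
        np.array(o)
        for o in np.ndindex(*(3,) * binary.ndim)
        if any(v != 1 for v in o)
    ]
    count = 0
    for idx in np.argwhere(binary):
        if seen[tuple(idx)]:
            continue
        count += 1
        stack = [idx]
        seen[tuple(idx)] = True
        while stack:
            cur = stack.pop()
            for off in offsets:
                nb = cur + off - 1
                if np.any(nb < 0) or np.any(nb >= binary.shape):
                    continue
                t = tuple(nb)
                if binary[t] and not seen[t]:
                    seen[t] = True
                    stack.append(nb)
    return count


class TestThreshold:
    def test_strict_inequality_at_threshold(self):
        u = np.array([[0.5, 0.51], [0.49, 1.0]])
        ind = threshold_probability(u, 0.5)
        np.testing.assert_array_equal(ind, [[False, True], [False, True]])

    def test_zero_threshold(self, rng):
        u = rng.random((8, 8)) * (rng.random((8, 8)) > 0.5)
        np.testing.assert_array_equal(threshold_probability(u, 0.0), u > 0)

    def test_unit_threshold_gives_all_zero(self, rng):
        assert not threshold_probability(rng.random((8, 8)), 1.0).any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            threshold_probability(np.zeros((2, 2)), 1.5)


class TestJointMap:
    def test_intersection_semantics(self, rng):
        hi = rng.random((16, 16)) > 0.5
        ind = rng.random((16, 16)) > 0.5
        uh = joint_map(ConvexityMap(hi, 1.0), ind)
        np.testing.assert_array_equal(uh, hi & ind)
        assert np.all(uh <= hi) and np.all(uh <= ind)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            joint_map(np.ones((4, 4), bool), np.ones((5, 5), bool))


class TestExtractBlobs:
    def test_diagonal_touch_is_one_component_2d(self):
        j = np.zeros((6, 6), bool)
        j[2, 2] = j[3, 3] = True
        blobs = extract_blobs(j, np.ones((6, 6)))
        assert blobs.n_blobs == 1

    def test_gap_gives_two_components(self):
        j = np.zeros((6, 6), bool)
        j[1, 1] = j[1, 3] = True
        assert extract_blobs(j, np.ones((6, 6))).n_blobs == 2

    def test_component_count_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            j = rng.random((20, 20)) > 0.7
            blobs = extract_blobs(j, rng.random((20, 20)))
            assert blobs.n_blobs == flood_fill_count(j)

    def test_3d_corner_connectivity(self):
        j = np.zeros((4, 4, 4), bool)
        j[1, 1, 1] = j[2, 2, 2] = True  # corner neighbors in the 27-neighborhood
        assert extract_blobs(j, np.ones((4, 4, 4))).n_blobs == 1

    def test_centroids_inside_bounding_boxes(self, rng):
        j = rng.random((30, 30)) > 0.75
        resp = rng.normal(size=(30, 30))
        blobs = extract_blobs(j, resp)
        for k in range(1, blobs.n_blobs + 1):
            coords = np.argwhere(blobs.label_image == k)
            lo, hi = coords.min(axis=0), coords.max(axis=0)
            assert np.all(blobs.centroids[k - 1] >= lo - 1e-9)
            assert np.all(blobs.centroids[k - 1] <= hi + 1e-9)

    def test_empty_joint_map(self):
        blobs = extract_blobs(np.zeros((5, 5), bool), np.zeros((5, 5)))
        assert blobs.n_blobs == 0
        assert blobs.centroids.shape == (0, 2)

    def test_min_size_filter_keeps_labels_contiguous(self):
        j = np.zeros((8, 8), bool)
        j[0, 0] = True  # size 1
        j[4:6, 4:6] = True  # size 4
        blobs = extract_blobs(j, np.ones((8, 8)), min_blob_voxels=2)
        assert blobs.n_blobs == 1
        assert set(np.unique(blobs.label_image)) == {0, 1}


class TestBlobStatistics:
    def test_voxel_volume_arithmetic(self):
        labels = np.zeros((4, 4, 4), np.int32)
        labels[:2, :2, :2] = 1  # 8 voxels
        blobs = BlobSet(labels, np.zeros((1, 3)), np.array([8]), 1.0, (0.1, 0.1, 0.1))
        stats = blob_statistics(blobs)
        assert stats.n_glom == 1
        assert stats.mean_av == pytest.approx(8e-3)

    def test_mean_median_of_two_blobs(self):
        blobs = BlobSet(np.zeros((4, 4), np.int32), np.zeros((2, 2)),
                        np.array([1, 3]), 1.0, (1.0, 1.0))
        stats = blob_statistics(blobs)
        assert stats.mean_av == pytest.approx(2.0)
        assert stats.median_av == pytest.approx(2.0)

    def test_matches_sort_oracle_on_random_sizes(self, rng):
        for _ in range(100):
            sizes = rng.integers(1, 50, size=int(rng.integers(1, 20)))
            blobs = BlobSet(np.zeros((2, 2), np.int32), np.zeros((len(sizes), 2)),
                            sizes, 1.0, (1.0, 1.0))
            stats = blob_statistics(blobs)
            srt = np.sort(sizes).astype(float)
            assert stats.mean_av == pytest.approx(srt.sum() / len(srt))
            mid = len(srt) // 2
            expected_median = srt[mid] if len(srt) % 2 else (srt[mid - 1] + srt[mid]) / 2
            assert stats.median_av == pytest.approx(expected_median)

    def test_empty_blobset_flags_volumes(self):
        blobs = BlobSet(np.zeros((4, 4), np.int32), np.empty((0, 2)),
                        np.empty(0, int), 1.0)
        stats = blob_statistics(blobs)
        assert stats.n_glom == 0
        assert np.isnan(stats.mean_av) and np.isnan(stats.median_av)


class TestDetect:
    def test_well_separated_blobs_with_oracle_map(self, blob_sample):
        blobs = detect(blob_sample.image, blob_sample.mask.astype(float))
        assert blobs.n_blobs == blob_sample.dots.count

    def test_all_zero_image_yields_empty_blobset(self):
        blobs = detect(ImageGrid(np.zeros((48, 48))), np.zeros((48, 48)))
        assert blobs.n_blobs == 0

    def test_dominance_of_both_constraints(self, blob_sample):
        blobs = detect(blob_sample.image, blob_sample.mask.astype(float))
        sel = blobs.selection
        detected = blobs.label_image > 0
        assert np.all(detected <= sel.map_star.data)
        assert np.all(detected <= (blob_sample.mask.astype(float) > 0.5))

    def test_voxel_set_shrinks_with_probability_threshold(self, blob_sample):
        prob = blob_sample.image.data  # a graded map with values across [0, 1]
        cfg_lo = DetectConfig.for_ndim(2, prob_threshold=0.3)
        cfg_hi = DetectConfig.for_ndim(2, prob_threshold=0.7)
        lo = detect(blob_sample.image, prob, cfg_lo)
        hi = detect(blob_sample.image, prob, cfg_hi)
        assert np.all((hi.label_image > 0) <= (lo.label_image > 0))

    def test_probability_map_shape_must_match(self, blob_sample):
        with pytest.raises(ValueError):
            detect(blob_sample.image, np.zeros((8, 8)))

    def test_splits_overlapping_pair_merged_in_probability_map(self):
        from scipy import ndimage

        sample = synthetic.generate_overlapping_pair(5.0, 6.5, seed=0)
        n_mask_components = ndimage.label(sample.mask, np.ones((3, 3)))[0].max()
        assert n_mask_components == 1
        blobs = detect(sample.image, sample.mask.astype(float))
        assert blobs.n_blobs == 2
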