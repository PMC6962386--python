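import numpy as np
import pytest

from uhdog.hessian_convexity import (
    NoBlobsDetectableError,
    average_dog_score,
    convexity_map,
    hessian_field,
    select_optimal_scale,
)
from uhdog.image_io import ImageGrid
from uhdog.scale_space import ScaleSpec, normalized_dog_transform
from uhdog import synthetic


def stencil_oracle(data, idx):
    """Independent per-voxel difference-quotient Hessian at one interior voxel."""
    d = data.ndim
    H = np.zeros((d, d))
    for i in range(d):
        up = list(idx); up[i] += 1
        dn = list(idx); dn[i] -= 1
        H[i, i] = data[tuple(up)] - 2 * data[idx] + data[tuple(dn)]
        for j in range(i + 1, d):
            val = 0.0
            for oi, oj, sgn in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
                p = list(idx); p[i] += oi; p[j] += oj
                val += sgn * data[tuple(p)]
            H[i, j] = H[j, i] = val / 4.0
    return H


def eig_negative_definite(field):
    """Eigenvalue-sign oracle for negative definiteness."""
    return np.linalg.eigvalsh(field).max(axis=-1) < 0


class TestHessianField:
    def test_quadratic_bowl_gives_minus_identity(self):
        n = 15
        yy, xx = np.mgrid[:n, :n] - n // 2
        resp = -(yy.astype(float) ** 2 + xx.astype(float) ** 2) / 2.0
        H = hessian_field(resp)
        interior = H[3:-3, 3:-3]
        np.testing.assert_allclose(
            interior, np.broadcast_to(-np.eye(2), interior.shape), atol=1e-12
        )

    def test_constant_response_gives_zero(self):
        H = hessian_field(np.full((6, 6, 6), 3.3))
        np.testing.assert_array_equal(H, 0.0)

    @pytest.mark.parametrize("shape", [(9, 9, 9), (11, 13)])
    def test_matches_stencil_oracle(self, rng, shape):
        data = rng.random(shape)
        H = hessian_field(data)
        for _ in range(25):
            idx = tuple(int(rng.integers(1, s - 1)) for s in shape)
            np.testing.assert_allclose(H[idx], stencil_oracle(data, idx), atol=1e-13)

    def test_symmetry(self, rng):
        H = hessian_field(rng.random((8, 8, 8)))
        np.testing.assert_array_equal(H, np.swapaxes(H, -1, -2))

    def test_tiny_image_rejected(self):
        with pytest.raises(ValueError):
            hessian_field(np.zeros((2, 5)))


class TestConvexityMap:
    def test_minus_identity_everywhere_is_all_ones(self):
        field = np.broadcast_to(-np.eye(3), (5, 5, 5, 3, 3)).copy()
        cmap = convexity_map(field, sigma=1.0)
        assert cmap.data.all()
        assert cmap.convex_count == 125

    def test_zero_matrix_is_not_definite(self):
        cmap = convexity_map(np.zeros((4, 4, 2, 2)), sigma=1.0)
        assert not cmap.data.any()

    @pytest.mark.parametrize("d", [2, 3])
    def test_matches_eigenvalue_oracle_on_random_matrices(self, rng, d):
        A = rng.normal(size=(200, d, d))
        field = (A + np.swapaxes(A, -1, -2)) / 2.0
        cmap = convexity_map(field, sigma=1.0)
        np.testing.assert_array_equal(cmap.data, eig_negative_definite(field))

    def test_positive_scaling_invariance(self, rng):
        A = rng.normal(size=(50, 3, 3))
        field = A + np.swapaxes(A, -1, -2)
        a = convexity_map(field, 1.0).data
        b = convexity_map(37.5 * field, 1.0).data
        np.testing.assert_array_equal(a, b)

    def test_negation_duality(self, rng):
        A = rng.normal(size=(100, 2, 2))
        field = A + np.swapaxes(A, -1, -2)
        nd_of_neg = convexity_map(-field, 1.0).data
        pd_oracle = np.linalg.eigvalsh(field).min(axis=-1) > 0
        np.testing.assert_array_equal(nd_of_neg, pd_oracle)

    def test_nonfinite_entries_are_zero(self):
        field = np.broadcast_to(-np.eye(2), (4, 2, 2)).copy()
        field[1, 0, 0] = np.nan
        cmap = convexity_map(field, 1.0)
        assert not cmap.data[1]
        assert cmap.data[[0, 2, 3]].all()


class TestAverageDoGScore:
    def test_constant_response_full_mask(self):
        cmap = convexity_map(np.broadcast_to(-np.eye(2), (6, 6, 2, 2)).copy(), 1.0)
        resp = np.full((6, 6), 2.5)
        assert average_dog_score(resp, cmap) == pytest.approx(2.5)

    def test_two_voxel_mask(self):
        from uhdog.hessian_convexity import ConvexityMap

        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[2, 2] = True
        resp = np.zeros((4, 4))
        resp[0, 0], resp[2, 2] = 1.0, 3.0
        assert average_dog_score(resp, ConvexityMap(mask, 1.0)) == pytest.approx(2.0)

    def test_matches_masked_mean_oracle(self, rng):
        from uhdog.hessian_convexity import ConvexityMap

        resp = rng.normal(size=(12, 12))
        mask = rng.random((12, 12)) > 0.6
        expected = resp[mask].sum() / mask.sum()
        got = average_dog_score(resp, ConvexityMap(mask, 1.0))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_empty_mask_is_flagged_nan(self):
        from uhdog.hessian_convexity import ConvexityMap

        score = average_dog_score(np.ones((3, 3)), ConvexityMap(np.zeros((3, 3)), 1.0))
        assert np.isnan(score)


class TestScaleSelection:
    def test_single_scale_grid(self, blob_sample):
        sel = select_optimal_scale(blob_sample.image, [1.0])
        assert sel.sigma_star == 1.0

    def test_blob_center_flagged_at_best_scale(self, single_blob_image):
        image, (cy, cx), _ = single_blob_image
        sel = select_optimal_scale(image, np.arange(0.5, 3.01, 0.5))
        assert sel.map_star.data[int(cy), int(cx)]

    def test_larger_blobs_select_larger_scale(self):
        stars = {}
        for radius, n in ((2.0, 15), (5.0, 15)):
            spec = synthetic.BlobSpec(
                n_blobs=n, radius_range=(radius, radius), dims=(128, 128),
                noise_sigma=0.02, seed=11,
            )
            sample = synthetic.generate_blob_image(spec)
            sel = select_optimal_scale(sample.image, np.arange(0.5, 3.01, 0.5))
            stars[radius] = sel.sigma_star
        assert stars[5.0] >= stars[2.0]

    def test_pure_noise_image_returns_contractual_selection(self, rng):
        image = ImageGrid(rng.random((40, 40)))
        grid = np.arange(0.5, 2.01, 0.5)
        sel = select_optimal_scale(image, grid)
        assert sel.sigma_star in grid
        assert sel.map_star.data.shape == image.shape
        assert np.isfinite(sel.scores[~np.isnan(sel.scores)]).all()

    def test_flat_image_raises_no_blobs(self):
        with pytest.raises(NoBlobsDetectableError):
            select_optimal_scale(ImageGrid(np.zeros((24, 24))), [0.5, 1.0])

    def test_descending_grid_rejected(self, blob_sample):
        with pytest.raises(ValueError):
            select_optimal_scale(blob_sample.image, [2.0, 1.0])
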