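import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imcseg.errors import AnnotationError, BoundsError, ConfigurationError, InputError
from imcseg.preprocess import (
    AugmentConfig,
    BoundaryAnnotation,
    GradientPair,
    UltrasoundImage,
    augment_pair,
    crop_frame,
    gradient_direction,
    make_pair,
    normalize,
    rasterize_mask,
    split_dataset,
)

# Standard 3x3 derivative kernels used by the independent oracle below.
_KERNELS = {
    "sobel": (np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float),      # d/dcol
              np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], float)),     # d/drow
    "prewitt": (np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], float),
                np.array([[-1, -1, -1], [0, 0, 0], [1, 1, 1]], float)),
}


def oracle_direction(arr: np.ndarray, operator: str) -> np.ndarray:
    """Brute-force gradient direction: explicit replicate padding and 3x3
    correlation, independent of scipy."""
    kx, ky = _KERNELS[operator]
    padded = np.pad(arr.astype(float), 1, mode="edge")
    h, w = arr.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            win = padded[r : r + 3, c : c + 3]
            gx = float((win * kx).sum())
            gy = float((win * ky).sum())
            if gx == 0.0 and gy == 0.0:
                out[r, c] = 0.5
            else:
                theta = np.arctan2(gy, gx)
                val = (theta + np.pi) / (2 * np.pi)
                out[r, c] = 1.0 if val == 0.0 else val
    return out


class TestCropFrame:
    def test_full_frame_identity(self):
        img = UltrasoundImage(np.random.default_rng(0).random((20, 30), dtype=np.float32))
        out = crop_frame(img, (0, 0, 20, 30))
        np.testing.assert_array_equal(out.pixels, img.pixels)
        assert out.pixel_density == img.pixel_density

    def test_subrect_shape(self):
        img = UltrasoundImage(np.zeros((100, 100), dtype=np.float32))
        assert crop_frame(img, (0, 0, 10, 20)).shape == (10, 20)

    @pytest.mark.parametrize("rect", [(0, 90, 10, 20), (95, 0, 10, 10), (-1, 0, 5, 5),
                                      (0, 0, 0, 10)])
    def test_out_of_bounds(self, rect):
        img = UltrasoundImage(np.zeros((100, 100), dtype=np.float32))
        with pytest.raises(BoundsError):
            crop_frame(img, rect)


class TestNormalize:
    def test_grey_levels(self):
        grid = np.arange(256).reshape(16, 16)
        out = normalize(grid)
        assert out.pixels.min() == 0.0
        assert out.pixels.max() == 1.0

    def test_constant_maps_to_zero(self):
        out = normalize(np.full((5, 5), 42))
        assert (out.pixels == 0).all()

    def test_three_values(self):
        out = normalize(np.array([[10.0, 20.0, 30.0]] * 3))
        np.testing.assert_allclose(out.pixels[0], [0.0, 0.5, 1.0])

    def test_empty_grid(self):
        with pytest.raises(InputError):
            normalize(np.zeros((0, 3)))


class TestGradientDirection:
    def test_vertical_step_edge_maps_to_half(self):
        # left half 0, right half 1: gx > 0, gy = 0 -> atan2 = 0 -> 0.5
        img = np.zeros((9, 10))
        img[:, 5:] = 1.0
        for op in ("sobel", "prewitt"):
            out = gradient_direction(img, op)
            edge_cols = out[1:-1, 4:6]
            np.testing.assert_allclose(edge_cols, 0.5)

    def test_constant_image_all_half(self):
        out = gradient_direction(np.full((8, 8), 0.3), "sobel")
        np.testing.assert_allclose(out, 0.5)

    @pytest.mark.parametrize("op", ["sobel", "prewitt"])
    def test_matches_bruteforce_oracle(self, op):
        arr = np.random.default_rng(3).random((7, 9))
        np.testing.assert_allclose(gradient_direction(arr, op),
                                   oracle_direction(arr, op), atol=1e-6)

    @pytest.mark.parametrize("op", ["sobel", "prewitt"])
    def test_transpose_swaps_gradient_components(self, op):
        arr = np.random.default_rng(4).random((8, 8))
        np.testing.assert_allclose(gradient_direction(arr.T, op),
                                   oracle_direction(arr.T, op), atol=1e-6)

    def test_output_range(self):
        arr = np.random.default_rng(5).random((16, 16))
        out = gradient_direction(arr, "sobel")
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_too_small(self):
        with pytest.raises(InputError):
            gradient_direction(np.zeros((2, 5)), "sobel")

    def test_unknown_operator(self):
        with pytest.raises(ConfigurationError):
            gradient_direction(np.zeros((5, 5)), "canny")


class TestMakePair:
    def test_shapes_and_difference(self):
        img = UltrasoundImage(np.random.default_rng(1).random((12, 16), dtype=np.float32))
        pair = make_pair(img)
        assert pair.prewitt_dir.shape == pair.sobel_dir.shape == (12, 16)
        # kernels differ, so directions differ somewhere on a generic image
        assert not np.allclose(pair.prewitt_dir, pair.sobel_dir)

    def test_constant_image_both_half(self):
        pair = make_pair(UltrasoundImage(np.full((8, 8), 0.7, dtype=np.float32)))
        np.testing.assert_allclose(pair.prewitt_dir, 0.5)
        np.testing.assert_allclose(pair.sobel_dir, 0.5)


class TestRasterizeMask:
    def test_flat_band(self):
        ann = BoundaryAnnotation(li_points=[(0, 10), (99, 10)], ma_points=[(0, 14), (99, 14)])
        mask = rasterize_mask(ann, (100, 100))
        assert (mask.sum(axis=0) == 5).all()
        assert (mask[10:15, :] == 1).all()
        assert mask[9].sum() == 0 and mask[15].sum() == 0

    def test_identical_lines_one_px_band(self):
        ann = BoundaryAnnotation(li_points=[(0, 7), (49, 7)], ma_points=[(0, 7), (49, 7)])
        mask = rasterize_mask(ann, (20, 50))
        assert (mask.sum(axis=0) == 1).all()

    def test_crossing_interfaces_raise(self):
        ann = BoundaryAnnotation(li_points=[(0, 20), (99, 20)], ma_points=[(0, 10), (99, 10)])
        with pytest.raises(AnnotationError):
            rasterize_mask(ann, (100, 100))

    def test_out_of_bounds_points(self):
        ann = BoundaryAnnotation(li_points=[(0, 10), (99, 10)], ma_points=[(0, 14), (99, 14)])
        with pytest.raises(BoundsError):
            rasterize_mask(ann, (100, 50))

    def test_too_few_points(self):
        ann = BoundaryAnnotation(li_points=[(0, 10)], ma_points=[(0, 14), (9, 14)])
        with pytest.raises(AnnotationError):
            rasterize_mask(ann, (20, 20))

    def test_interpolation_rounds_half_up(self):
        # LI goes 10 -> 11 over 2 columns: midpoint 10.5 rounds to 11
        ann = BoundaryAnnotation(li_points=[(0, 10), (2, 11)], ma_points=[(0, 14), (2, 14)])
        mask = rasterize_mask(ann, (20, 3))
        assert mask[:, 1].nonzero()[0][0] == 11


class TestAugmentPair:
    @staticmethod
    def _sample(shape=(16, 24)):
        rng = np.random.default_rng(0)
        pair = GradientPair(rng.random(shape, dtype=np.float32),
                            rng.random(shape, dtype=np.float32))
        mask = (rng.random(shape) > 0.7).astype(np.uint8)
        return pair, mask

    def test_zero_magnitudes_identity(self):
        pair, mask = self._sample()
        cfg = AugmentConfig(rotation_deg=0, shift_frac=0, zoom_frac=0, seed=1)
        out_pair, out_mask = augment_pair(pair, mask, cfg, draw=5)
        np.testing.assert_array_equal(out_pair.prewitt_dir, pair.prewitt_dir)
        np.testing.assert_array_equal(out_pair.sobel_dir, pair.sobel_dir)
        np.testing.assert_array_equal(out_mask, mask)

    def test_deterministic_per_draw(self):
        pair, mask = self._sample()
        cfg = AugmentConfig(seed=2)
        a = augment_pair(pair, mask, cfg, draw=3)
        b = augment_pair(pair, mask, cfg, draw=3)
        np.testing.assert_array_equal(a[0].sobel_dir, b[0].sobel_dir)
        np.testing.assert_array_equal(a[1], b[1])
        c = augment_pair(pair, mask, cfg, draw=4)
        assert not np.array_equal(a[1], c[1]) or not np.allclose(a[0].sobel_dir, c[0].sobel_dir)

    def test_mask_binarity_and_shape_over_draws(self):
        pair, mask = self._sample()
        cfg = AugmentConfig(seed=3)
        for draw in range(100):
            out_pair, out_mask = augment_pair(pair, mask, cfg, draw)
            assert out_mask.shape == mask.shape
            assert set(np.unique(out_mask)) <= {0, 1}
            assert out_pair.shape == pair.shape

    def test_shape_mismatch(self):
        pair, _ = self._sample()
        with pytest.raises(InputError):
            augment_pair(pair, np.zeros((4, 4), np.uint8), AugmentConfig(), 0)

    def test_bad_config(self):
        pair, mask = self._sample()
        with pytest.raises(ConfigurationError):
            augment_pair(pair, mask, AugmentConfig(shift_frac=0.7), 0)


class TestSplitDataset:
    def test_paper_split_100(self):
        train, test = split_dataset(list(range(100)), 0.8, seed=0)
        assert len(train) == 80 and len(test) == 20

    def test_five_items(self):
        train, test = split_dataset(list(range(5)), 0.8, seed=1)
        assert len(train) == 4 and len(test) == 1

    def test_same_seed_identical(self):
        items = list(range(37))
        assert split_dataset(items, 0.8, seed=7) == split_dataset(items, 0.8, seed=7)

    @given(n=st.integers(1, 200), seed=st.integers(0, 1000),
           frac=st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_partition_property(self, n, seed, frac):
        items = list(range(n))
        train, test = split_dataset(items, frac, seed=seed)
        assert sorted(train + test) == items
        assert not set(train) & set(test)

    def test_empty_list(self):
        with pytest.raises(InputError):
            split_dataset([], 0.8, seed=0)

    def test_bad_fraction(self):
        with pytest.raises(ConfigurationError):
            split_dataset([1, 2], 1.2, seed=0)
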