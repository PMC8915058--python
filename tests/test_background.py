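import numpy as np
import pytest

from mammopipe.background import (
    StructuringElement,
    bottom_hat,
    default_structuring_element,
    top_hat,
    uniformize,
    uniformize_rgb,
)
from mammopipe.imgio import ImageRGB
from mammopipe.metrics import contrast_db


def sliding_erode(f, fp):
    """Brute-force min over the footprint with edge replication."""
    rh, rw = fp.shape[0] // 2, fp.shape[1] // 2
    padded = np.pad(f, ((rh, rh), (rw, rw)), mode="edge")
    out = np.empty_like(f, dtype=float)
    for i in range(f.shape[0]):
        for j in range(f.shape[1]):
            out[i, j] = padded[i : i + fp.shape[0], j : j + fp.shape[1]][fp].min()
    return out


def sliding_dilate(f, fp):
    rh, rw = fp.shape[0] // 2, fp.shape[1] // 2
    padded = np.pad(f, ((rh, rh), (rw, rw)), mode="edge")
    out = np.empty_like(f, dtype=float)
    for i in range(f.shape[0]):
        for j in range(f.shape[1]):
            out[i, j] = padded[i : i + fp.shape[0], j : j + fp.shape[1]][fp].max()
    return out


def oracle_closing(f, fp):
    return sliding_erode(sliding_dilate(f, fp), fp)


def oracle_opening(f, fp):
    return sliding_dilate(sliding_erode(f, fp), fp)


SQUARE3 = StructuringElement.square(3)


class TestStructuringElement:
    def test_even_footprint_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            StructuringElement(np.ones((2, 3), dtype=bool))

    def test_empty_footprint_rejected(self):
        with pytest.raises(ValueError):
            StructuringElement(np.zeros((3, 3), dtype=bool))

    def test_anchor_must_be_true(self):
        fp = np.ones((3, 3), dtype=bool)
        fp[1, 1] = False
        with pytest.raises(ValueError, match="anchor"):
            StructuringElement(fp)

    def test_default_scales_with_size(self):
        assert default_structuring_element((1024, 1024)).footprint.shape == (31, 31)
        small = default_structuring_element((64, 64))
        assert small.footprint.shape == (3, 3)


class TestHats:
    def test_bottom_hat_flat_image(self):
        assert np.all(bottom_hat(np.full((5, 5), 7.0), SQUARE3) == 0.0)

    def test_top_hat_flat_image(self):
        assert np.all(top_hat(np.full((5, 5), 7.0), SQUARE3) == 0.0)

    def test_bottom_hat_dark_center_pixel(self):
        f = np.full((5, 5), 10.0)
        f[2, 2] = 0.0
        out = bottom_hat(f, SQUARE3)
        oracle = oracle_closing(f, SQUARE3.footprint) - f
        np.testing.assert_array_equal(out, oracle)
        assert out[2, 2] == 10.0
        assert out.sum() == 10.0

    def test_top_hat_bright_center_pixel(self):
        f = np.zeros((5, 5))
        f[2, 2] = 255.0
        out = top_hat(f, SQUARE3)
        assert out[2, 2] == 255.0
        assert out.sum() == 255.0

    def test_bottom_hat_dark_line_oracle(self):
        f = np.full((7, 7), 50.0)
        f[:, 3] = 0.0
        out = bottom_hat(f, SQUARE3)
        oracle = oracle_closing(f, SQUARE3.footprint) - f
        np.testing.assert_array_equal(out, oracle)
        assert np.all(out[:, 3] == 50.0)

    def test_duality(self, rng):
        f = rng.integers(0, 256, (10, 10)).astype(float)
        for se in (SQUARE3, StructuringElement.disk(2)):
            np.testing.assert_allclose(
                top_hat(f, se), bottom_hat(255.0 - f, se), atol=1e-12
            )

    @pytest.mark.parametrize("trial", range(5))
    def test_hats_match_sliding_window_oracle(self, rng, trial):
        f = rng.integers(0, 256, (12, 14)).astype(float)
        se = StructuringElement.disk(2) if trial % 2 else SQUARE3
        np.testing.assert_array_equal(
            bottom_hat(f, se), oracle_closing(f, se.footprint) - f
        )
        np.testing.assert_array_equal(
            top_hat(f, se), f - oracle_opening(f, se.footprint)
        )

    def test_non_negativity(self, rng):
        for _ in range(10):
            f = rng.uniform(0, 255, (9, 9))
            assert bottom_hat(f, SQUARE3).min() >= -1e-12
            assert top_hat(f, SQUARE3).min() >= -1e-12

    def test_opening_closing_idempotent(self, rng):
        from scipy import ndimage

        f = rng.integers(0, 256, (16, 16)).astype(float)
        opened = oracle_opening(f, SQUARE3.footprint)
        closed = oracle_closing(f, SQUARE3.footprint)
        np.testing.assert_array_equal(
            ndimage.grey_opening(opened, footprint=SQUARE3.footprint, mode="nearest"), opened
        )
        np.testing.assert_array_equal(
            ndimage.grey_closing(closed, footprint=SQUARE3.footprint, mode="nearest"), closed
        )


class TestUniformize:
    def test_constant_maps_to_zero(self):
        assert np.all(uniformize(np.full((6, 6), 33.0), SQUARE3) == 0.0)

    def test_impulse_composition_oracle(self):
        f = np.full((9, 9), 100.0)
        f[2, 2] = 200.0  # bright impulse
        f[6, 6] = 10.0   # dark impulse
        composite = (
            f
            + (f - oracle_opening(f, SQUARE3.footprint))
            - (oracle_closing(f, SQUARE3.footprint) - f)
        )
        lo, hi = composite.min(), composite.max()
        np.testing.assert_allclose(
            uniformize(f, SQUARE3), (composite - lo) * 255.0 / (hi - lo), atol=1e-9
        )
        # bright impulse amplified, dark impulse suppressed relative to the field
        assert composite[2, 2] - 100.0 > f[2, 2] - 100.0
        assert composite[6, 6] < f[6, 6]

    def test_output_range(self, rng):
        for _ in range(100):
            f = rng.uniform(0, 255, (8, 8))
            out = uniformize(f, SQUARE3)
            assert out.min() >= 0.0 and out.max() <= 255.0

    def test_contrast_increase_on_bright_impulse(self):
        f = np.full((15, 15), 100.0)
        f[7, 7] = 200.0
        assert contrast_db(uniformize(f, SQUARE3)) > contrast_db(f)

    def test_rgb_green_only(self, rng):
        img = ImageRGB(*(rng.uniform(0, 255, (8, 8)) for _ in range(3)))
        out = uniformize_rgb(img, SQUARE3, per_channel=False)
        np.testing.assert_array_equal(out.red, img.red)
        np.testing.assert_array_equal(out.blue, img.blue)
        assert not np.array_equal(out.green, img.green)
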