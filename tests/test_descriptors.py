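"""Descriptor correctness against analytic cases and brute-force references."""

import numpy as np
import pytest

import synthdetect as sd
from synthdetect.descriptors import (JPEG_AC_RANGE, block_dct_coefficients,
                                     resolve_filter_id, zigzag_indices)

from _references import (colour_layout_naive, correlogram_naive, dct2_direct,
                         jpeg_features_naive, zigzag_direct)


class TestZigzag:
    def test_matches_walked_order(self):
        assert zigzag_indices(8) == zigzag_direct(8)

    def test_first_entries_are_the_jpeg_order(self):
        assert zigzag_indices(8)[:6] == [(0, 0), (0, 1), (1, 0), (2, 0),
                                         (1, 1), (0, 2)]


class TestJpegCoefficients:
    def test_constant_image_is_dc_only(self):
        img = np.full((28, 28), 128, dtype=np.uint8)
        coeffs = block_dct_coefficients(img)
        assert np.allclose(coeffs[:, 0, 0], 8 * 128.0)
        ac = coeffs.copy()
        ac[:, 0, 0] = 0
        assert np.abs(ac).max() < 1e-9
        vec = sd.jpeg_coefficient_features(img).values
        # every AC histogram concentrates in the bin containing zero
        n_bins = 16
        lo, hi = JPEG_AC_RANGE
        zero_bin = int((0 - lo) / ((hi - lo) / n_bins))
        for c in range(1, 9):
            hist = vec[c * n_bins:(c + 1) * n_bins]
            assert hist[zero_bin] == 16
            assert hist.sum() == 16

    def test_unit_impulse_block_matches_direct_dct(self):
        block = np.zeros((8, 8))
        block[0, 0] = 1.0
        expected = dct2_direct(block)
        from scipy.fft import dctn
        assert np.allclose(dctn(block, norm="ortho"), expected, atol=1e-12)

    def test_parseval_energy_identity(self, random_images):
        for img in random_images[:3]:
            coeffs = block_dct_coefficients(img)
            padded = np.pad(img.astype(np.float64), ((0, 4), (0, 4)),
                            mode="edge")
            blocks = padded.reshape(4, 8, 4, 8).transpose(0, 2, 1, 3)
            blocks = blocks.reshape(16, 8, 8)
            assert np.allclose((coeffs ** 2).sum(axis=(1, 2)),
                               (blocks ** 2).sum(axis=(1, 2)))

    def test_constant_shift_moves_dc_only(self, random_images):
        img = (random_images[0] // 2).astype(np.uint8)  # headroom for +k
        k = 40
        base = block_dct_coefficients(img)
        shifted = block_dct_coefficients(img + k)
        assert np.allclose(shifted[:, 0, 0] - base[:, 0, 0], 8 * k)
        base_ac, shifted_ac = base.copy(), shifted.copy()
        base_ac[:, 0, 0] = shifted_ac[:, 0, 0] = 0
        assert np.allclose(base_ac, shifted_ac, atol=1e-9)

    def test_non_28x28_rejected(self):
        with pytest.raises(ValueError):
            sd.jpeg_coefficient_features(np.zeros((16, 16), dtype=np.uint8))

    def test_vector_length_is_content_independent(self, random_images):
        lengths = {len(sd.jpeg_coefficient_features(img))
                   for img in random_images}
        assert lengths == {9 * 16}


class TestQuantize:
    @pytest.mark.parametrize("value, levels, expected", [
        (0, 64, 0), (255, 64, 63), (128, 4, 2),
    ])
    def test_bin_assignment(self, value, levels, expected):
        img = np.full((28, 28), value, dtype=np.uint8)
        q = sd.quantize(img, levels)
        assert np.all(q.labels == expected)

    def test_monotone_in_intensity(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        labels = sd.quantize(img, 7).labels.ravel()
        assert np.all(np.diff(labels) >= 0)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            sd.quantize(np.zeros((28, 28), dtype=np.uint8), 1)


class TestCorrelogram:
    def test_uniform_image(self):
        img = np.full((28, 28), 200, dtype=np.uint8)
        vec = sd.auto_color_correlogram(img, levels=8).values.reshape(8, 4)
        color = (200 * 8) // 256
        assert np.all(vec[color] == 1.0)
        vec[color] = 0
        assert np.abs(vec).max() == 0.0

    def test_checkerboard_matches_enumeration(self):
        board = np.zeros((4, 4), dtype=np.uint8)
        board[::2, 1::2] = 255
        board[1::2, ::2] = 255
        got = sd.auto_color_correlogram(board, levels=2, distances=[1]).values
        expected = correlogram_naive(board, levels=2, distances=[1])
        assert np.allclose(got, expected, atol=1e-12)
        # diagonal neighbours share colour, orthogonal do not: value in (0, 1)
        assert 0 < got[0] < 1 and 0 < got[1] < 1

    def test_tiny_image_matches_enumeration(self):
        img = np.array([[10, 10], [10, 200]], dtype=np.uint8)
        got = sd.auto_color_correlogram(img, levels=2, distances=[1]).values
        expected = correlogram_naive(img, levels=2, distances=[1])
        assert np.allclose(got, expected, atol=1e-12)

    def test_values_lie_in_unit_interval(self, random_images):
        for img in random_images[:3]:
            v = sd.auto_color_correlogram(img).values
            assert v.min() >= 0.0 and v.max() <= 1.0
            assert len(v) == 64 * 4

    def test_oversized_distance_yields_zeros(self):
        img = np.random.default_rng(0).integers(
            0, 256, (28, 28)).astype(np.uint8)
        vec = sd.auto_color_correlogram(img, levels=4,
                                        distances=[28]).values
        assert np.all(vec == 0)

    def test_invalid_distances_rejected(self):
        img = np.zeros((28, 28), dtype=np.uint8)
        with pytest.raises(ValueError):
            sd.auto_color_correlogram(img, distances=[])
        with pytest.raises(ValueError):
            sd.auto_color_correlogram(img, distances=[0])


class TestColourLayout:
    def test_constant_image(self):
        g = 77
        vec = sd.colour_layout(np.full((28, 28), g, dtype=np.uint8)).values
        assert vec[0] == pytest.approx(8.0 * g)
        assert np.abs(vec[1:6]).max() < 1e-9  # Y AC
        assert vec[6] == pytest.approx(8.0 * 128)  # Cb DC
        assert np.abs(vec[7:9]).max() < 1e-9
        assert vec[9] == pytest.approx(8.0 * 128)  # Cr DC

    def test_vertical_step_excites_horizontal_frequencies_only(self):
        img = np.zeros((28, 28), dtype=np.uint8)
        img[:, 14:] = 255
        vec = sd.colour_layout(img, n_y=10).values[:10]
        from scipy.fft import dctn
        means = np.zeros((8, 8))
        means[:, 4:] = 255.0
        expected = dctn(means, norm="ortho")
        order = zigzag_indices(8)[:10]
        assert np.allclose(vec, [expected[r, c] for r, c in order])
        for value, (r, c) in zip(vec, order):
            if r > 0 and c == 0:  # vertical-only frequency
                assert abs(value) < 1e-9

    def test_y_coefficients_scale_linearly(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 80, (28, 28)).astype(np.uint8)
        base = sd.colour_layout(img).values
        tripled = sd.colour_layout((img * 3).astype(np.uint8)).values
        assert np.allclose(tripled[:6], 3 * base[:6])
        assert np.allclose(tripled[6:], base[6:])

    def test_default_length(self, random_images):
        assert len(sd.colour_layout(random_images[0])) == 12


class TestBatchExtraction:
    def test_reference_agreement_on_random_images(self, random_images):
        refs = {
            "jpeg_coefficient": jpeg_features_naive,
            "auto_color_correlogram": correlogram_naive,
            "colour_layout": colour_layout_naive,
        }
        for fid, ref in refs.items():
            got = sd.extract_features(random_images[:3], fid)
            expected = np.stack([ref(img) for img in random_images[:3]])
            assert np.abs(got - expected).max() < 1e-9, fid

    def test_determinism_and_order_independence(self, random_images):
        a = sd.extract_features(random_images, "colour_layout")
        b = sd.extract_features(random_images[::-1], "colour_layout")[::-1]
        assert np.array_equal(a, b)

    def test_alias_resolution(self):
        assert resolve_filter_id("jpeg") == "jpeg_coefficient"
        assert resolve_filter_id("acc") == "auto_color_correlogram"
        assert resolve_filter_id("cld") == "colour_layout"
        with pytest.raises(ValueError):
            resolve_filter_id("sift")
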