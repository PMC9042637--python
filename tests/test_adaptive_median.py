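"""Unit and property tests for the two-stage adaptive median filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from usenhance import (
    FilterParams,
    GrayImage,
    NoiseSpec,
    PhantomSpec,
    PixelLabel,
    add_impulse_noise,
    brute_force_denoise,
    classify_candidate,
    confirm_noise,
    denoise,
    make_phantom,
    psnr,
    slope_k1,
    slope_k2,
    sorted_window,
    threshold_q,
)

# the worked 3x3 window: values {10,10,10,20,30,40,50,60,200}, centre 10
WORKED_MIN = GrayImage(np.array([[20, 30, 40], [50, 10, 60], [200, 10, 10]], dtype=np.int64))
# same multiset rearranged so the centre is the maximum 200
WORKED_MAX = GrayImage(np.array([[20, 30, 40], [50, 200, 60], [10, 10, 10]], dtype=np.int64))


class TestSortedWindow:
    def test_worked_example_statistics(self):
        w = sorted_window(WORKED_MIN, 1, 1, 3)
        assert w.s.tolist() == [10, 10, 10, 20, 30, 40, 50, 60, 200]
        assert (w.s_min, w.s_max, w.s_med) == (10, 200, 30)
        assert (w.n1, w.n2) == (3, 7)
        assert w.center == 10

    def test_constant_window_has_undefined_interior(self):
        img = GrayImage(np.full((3, 3), 5, dtype=np.uint8))
        w = sorted_window(img, 1, 1, 3)
        assert w.s_min == w.s_max == w.s_med == 5
        assert w.n1 is None and w.n2 is None

    def test_border_uses_reflect_extension(self):
        img = GrayImage(np.array([[0, 1, 2, 3]], dtype=np.uint8))
        w = sorted_window(img, 0, 0, 3)
        # reflect pad of the 1x4 row around (0,0): rows mirror to the same
        # row, columns mirror 1|0 1 -> window values {1,0,1} x 3
        assert w.s.tolist() == [0, 0, 0, 1, 1, 1, 1, 1, 1]

    @pytest.mark.parametrize("m", [2, 4, 0, -3])
    def test_even_or_nonpositive_window_rejected(self, m):
        img = GrayImage(np.zeros((5, 5), dtype=np.uint8))
        with pytest.raises(ValueError):
            sorted_window(img, 2, 2, m)


class TestClassification:
    def test_extreme_centre_with_clean_median_is_quasi_noise(self):
        assert classify_candidate(sorted_window(WORKED_MIN, 1, 1, 3)) is PixelLabel.QUASI_NOISE
        assert classify_candidate(sorted_window(WORKED_MAX, 1, 1, 3)) is PixelLabel.QUASI_NOISE

    def test_non_extreme_centre_is_signal(self):
        img = GrayImage(np.array([[20, 10, 40], [50, 30, 60], [200, 10, 10]], dtype=np.int64))
        assert classify_candidate(sorted_window(img, 1, 1, 3)) is PixelLabel.SIGNAL

    def test_constant_window_is_signal(self):
        img = GrayImage(np.full((3, 3), 5, dtype=np.uint8))
        assert classify_candidate(sorted_window(img, 1, 1, 3)) is PixelLabel.SIGNAL

    def test_extreme_median_blocks_candidacy(self):
        # two-valued window: the median coincides with an extreme
        img = GrayImage(np.array([[0, 0, 0], [0, 255, 0], [0, 0, 0]], dtype=np.int64))
        assert classify_candidate(sorted_window(img, 1, 1, 3)) is PixelLabel.SIGNAL


class TestSlopes:
    def test_k1_minimum_case(self):
        # K1 = (S[N1] - F) / ((N1+1)/2) = (20-10)/2 = 5
        assert slope_k1(sorted_window(WORKED_MIN, 1, 1, 3)) == 5.0

    def test_k1_maximum_case_both_variants(self):
        w = sorted_window(WORKED_MAX, 1, 1, 3)
        # as printed: (F - S[N1]) / (M*M - 1 - N2) = (200-20)/1
        assert slope_k1(w, "as_printed") == 180.0
        # symmetric: (F - S[N2]) / (M*M - 1 - N2) = (200-60)/1
        assert slope_k1(w, "symmetric") == 140.0

    def test_k2_average_interior_slope(self):
        # (S[N2] - S[N1]) / (N2 - N1) = (60-20)/4
        assert slope_k2(sorted_window(WORKED_MIN, 1, 1, 3)) == 10.0

    def test_k2_flat_interior_is_zero(self):
        img = GrayImage(np.array([[0, 5, 5], [5, 0, 5], [5, 5, 255]], dtype=np.int64))
        w = sorted_window(img, 1, 1, 3)
        assert w.s[w.n1] == w.s[w.n2] == 5
        assert slope_k2(w) == 0.0

    def test_single_interior_point_collapses_to_zero(self):
        # {0,...,0,100,255}: n1 == n2 -> K2 = 0 by convention
        img = GrayImage(np.array([[0, 0, 0], [0, 0, 0], [0, 100, 255]], dtype=np.int64))
        w = sorted_window(img, 1, 1, 3)
        assert w.n1 == w.n2
        assert slope_k2(w) == 0.0

    def test_constant_window_raises(self):
        w = sorted_window(GrayImage(np.full((3, 3), 9, dtype=np.uint8)), 1, 1, 3)
        with pytest.raises(ValueError):
            slope_k1(w)
        with pytest.raises(ValueError):
            slope_k2(w)

    def test_non_extreme_centre_rejected_for_k1(self):
        img = GrayImage(np.array([[20, 10, 40], [50, 30, 60], [200, 10, 10]], dtype=np.int64))
        with pytest.raises(ValueError):
            slope_k1(sorted_window(img, 1, 1, 3))


class TestThresholdAndConfirmation:
    @pytest.mark.parametrize("s_med,eps,expected", [(30, 3, 10.0), (0, 5, 0.0), (77, 1, 77.0)])
    def test_threshold_q(self, s_med, eps, expected):
        assert threshold_q(s_med, eps) == expected

    def test_epsilon_must_be_positive_integer(self):
        with pytest.raises(ValueError):
            threshold_q(30, 0)
        with pytest.raises(ValueError):
            FilterParams(epsilon=0)

    def test_default_rule_compares_k1_to_q(self):
        assert not confirm_noise(5.0, 10.0, 10.0)      # worked min-case: keep
        assert confirm_noise(180.0, 10.0, 10.0)        # worked max-case: noise
        assert confirm_noise(-12.0, 0.0, 10.0)         # magnitude comparison

    def test_strict_rule_also_requires_k1_above_k2(self):
        assert confirm_noise(180.0, 10.0, 10.0, rule="k1_vs_k2_and_q")
        assert not confirm_noise(8.0, 10.0, 5.0, rule="k1_vs_k2_and_q")

    def test_zero_threshold_flags_any_nonzero_slope(self):
        assert confirm_noise(0.5, 0.0, 0.0)


class TestDenoise:
    def test_constant_image_is_fixed_point(self):
        img = GrayImage(np.full((9, 9), 42, dtype=np.uint8))
        out, labels = denoise(img)
        assert out == img
        assert np.all(labels == PixelLabel.SIGNAL)

    def test_single_impulse_on_textured_field_is_replaced_by_local_median(self):
        # smooth ramp background: every 3x3 median is clean, so the impulse
        # is screened, confirmed (K1 = 206 >= Q = 25), and replaced by S_med
        rows, cols = np.mgrid[0:11, 0:11]
        arr = 40 + rows + cols
        arr[5, 5] = 255
        out, labels = denoise(GrayImage(arr), FilterParams(epsilon=2))
        assert out.pixels[5, 5] == 50  # the window median
        assert labels[5, 5] == PixelLabel.NOISE
        assert np.count_nonzero(labels == PixelLabel.NOISE) == 1
        changed = out.pixels.astype(int) != arr
        assert changed.sum() == 1 and changed[5, 5]

    def test_single_impulse_on_constant_field_is_screened_out(self):
        # in a flat window the median coincides with an extreme, so the
        # screening rule treats the median as unreliable and never flags
        # the centre: the impulse survives (a property of the rule itself)
        arr = np.full((11, 11), 50, dtype=np.int64)
        arr[5, 5] = 255
        out, labels = denoise(GrayImage(arr), FilterParams(epsilon=2))
        assert out.pixels[5, 5] == 255
        assert np.all(labels == PixelLabel.SIGNAL)

    def test_noise_free_ramp_passes_untouched(self):
        arr = np.tile(np.arange(32, dtype=np.int64), (32, 1))
        img = GrayImage(arr)
        out, labels = denoise(img)
        assert out == img
        assert np.all(labels == PixelLabel.SIGNAL)

    def test_signal_pixels_are_bit_identical(self, noisy_phantom):
        _, noisy, _ = noisy_phantom
        out, labels = denoise(noisy)
        signal = labels != PixelLabel.NOISE
        assert np.array_equal(out.pixels[signal], noisy.pixels[signal])

    def test_matches_brute_force_oracle(self, random_image):
        img = random_image(5)
        params = FilterParams(epsilon=2)
        fast, fast_labels = denoise(img, params)
        slow, slow_labels = brute_force_denoise(img, params)
        assert fast == slow
        assert np.array_equal(fast_labels, slow_labels)

    def test_second_pass_confirms_no_more_noise_than_first(self):
        """Monotone cleanup on salt-and-pepper phantoms over 20 seeds."""
        for seed in range(20):
            clean, _ = make_phantom(PhantomSpec(height=64, width=64, seed=seed))
            noisy, _ = add_impulse_noise(clean, NoiseSpec(density=0.10, seed=1000 + seed))
            pass1, labels1 = denoise(noisy)
            _, labels2 = denoise(pass1)
            assert (labels2 == PixelLabel.NOISE).sum() <= (labels1 == PixelLabel.NOISE).sum()

    def test_denoising_raises_psnr_on_corrupted_phantoms(self):
        gains = []
        for seed in range(20):
            clean, _ = make_phantom(PhantomSpec(height=64, width=64, seed=seed))
            noisy, _ = add_impulse_noise(clean, NoiseSpec(density=0.10, seed=2000 + seed))
            out, _ = denoise(noisy)
            gains.append(psnr(clean, out) - psnr(clean, noisy))
        assert np.mean(gains) > 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arr=hnp.arrays(np.uint8, hnp.array_shapes(min_dims=2, max_dims=2, min_side=3, max_side=12)),
        eps=st.sampled_from([1, 2, 4, 8]),
    )
    def test_output_in_range_and_signal_preserved(self, arr, eps):
        img = GrayImage(arr)
        out, labels = denoise(img, FilterParams(epsilon=eps))
        assert out.pixels.min() >= 0 and out.pixels.max() <= img.g_max
        signal = labels != PixelLabel.NOISE
        assert np.array_equal(out.pixels[signal], img.pixels[signal])


class TestFilterParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"m0": 4},
            {"m_max": 6},
            {"m0": 9, "m_max": 7},
            {"k1_variant": "bogus"},
            {"confirm_rule": "bogus"},
            {"border_mode": "wrap"},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FilterParams(**kwargs)
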