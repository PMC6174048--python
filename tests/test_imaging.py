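"""Unit tests for the per-frame eye-state classifier chain."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blinkwatch import imaging as im
from blinkwatch.errors import DegenerateImageError, FormatError, ParameterError
from blinkwatch.imaging import EyeState
from blinkwatch.synthetic import EyeImageParams, generate_eye_image


def brute_force_otsu(img: np.ndarray) -> int:
    """Independent exhaustive search over all 255 candidate thresholds."""
    pixels = img.ravel().astype(float)
    n = pixels.size
    best_t, best_var = 0, -1.0
    for t in range(255):
        c0 = pixels[pixels <= t]
        c1 = pixels[pixels > t]
        if c0.size == 0 or c1.size == 0:
            var = 0.0
        else:
            w0, w1 = c0.size / n, c1.size / n
            var = w0 * w1 * (c0.mean() - c1.mean()) ** 2
        if var > best_var:
            best_t, best_var = t, var
    return best_t


class TestToGrayscale:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((255, 255, 255), 255), ((0, 0, 0), 0), ((100, 150, 200), 141)],
    )
    def test_luminance_weights(self, rgb, expected):
        frame = np.full((2, 2, 3), rgb, dtype=np.uint8)
        assert im.to_grayscale(frame)[0, 0] == expected

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(FormatError):
            im.to_grayscale(np.zeros((4, 4, 4)))
        with pytest.raises(FormatError):
            im.to_grayscale(np.zeros((4, 4)))


class TestNormalizeIllumination:
    def test_constant_image_hits_target(self):
        out = im.normalize_illumination(np.full((4, 4), 64, dtype=np.uint8))
        assert (out == 128).all()

    def test_mean_128_image_unchanged(self):
        img = np.array([[100, 156], [128, 128]], dtype=np.uint8)
        assert (im.normalize_illumination(img) == img).all()

    def test_invariant_to_global_gain(self):
        rng = np.random.default_rng(7)
        img = rng.integers(10, 120, size=(8, 8)).astype(np.uint8)
        doubled = (img.astype(int) * 2).astype(np.uint8)  # stays below 255
        np.testing.assert_array_equal(
            im.normalize_illumination(img), im.normalize_illumination(doubled)
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(DegenerateImageError):
            im.normalize_illumination(np.zeros((4, 4), dtype=np.uint8))


class TestOtsu:
    def test_perfect_bimodal_ties_break_small(self):
        img = np.array([0] * 50 + [255] * 50, dtype=np.uint8).reshape(10, 10)
        assert im.otsu_threshold(img) == 0

    def test_two_pixel_image(self):
        assert im.otsu_threshold(np.array([[10, 20]], dtype=np.uint8)) == 10

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            im.otsu_threshold(np.full((4, 4), 7, dtype=np.uint8))

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
            assert im.otsu_threshold(img) == brute_force_otsu(img)

    def test_matches_scikit_image_on_bimodal_images(self):
        """Independent library cross-check of the threshold value."""
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(3)
        for _ in range(50):
            lo = rng.normal(50, 10, 100).clip(0, 255)
            hi = rng.normal(200, 10, 100).clip(0, 255)
            img = np.rint(np.concatenate([lo, hi])).astype(np.uint8)
            assert im.otsu_threshold(img) == threshold_otsu(img.reshape(10, 20))


class TestBinarize:
    def test_rule_examples(self):
        assert (im.binarize(np.zeros((2, 2), dtype=np.uint8), 0) == 1).all()
        assert (im.binarize(np.full((2, 2), 255, np.uint8), 254) == 0).all()
        np.testing.assert_array_equal(
            im.binarize(np.array([[10, 20]], dtype=np.uint8), 10),
            np.array([[1, 0]]),
        )

    @given(st.integers(0, 254), st.integers(0, 10_000))
    @settings(max_examples=30, derandomize=True)
    def test_partitions_pixels(self, t, seed):
        img = np.random.default_rng(seed).integers(
            0, 256, size=(6, 6)
        ).astype(np.uint8)
        b = im.binarize(img, t)
        assert b.sum() + (1 - b).sum() == img.size
        assert set(np.unique(b)) <= {0, 1}


class TestCleanBinary:
    def test_removes_isolated_speck(self):
        img = np.zeros((7, 7), dtype=np.uint8)
        img[3, 3] = 1
        assert im.clean_binary(img).sum() == 0

    def test_preserves_shapes_open_under_the_element(self):
        # Opening preserves unions of translates of the structuring
        # element; a plain square is not one (the cross cannot cover its
        # corners), so the reference shape is the square's own opening.
        img = np.zeros((9, 9), dtype=np.uint8)
        img[2:7, 2:7] = 1
        opened = im.clean_binary(img)
        assert opened.sum() >= img.sum() - 4  # only the 4 corners may go
        np.testing.assert_array_equal(im.clean_binary(opened), opened)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, derandomize=True)
    def test_idempotent_and_anti_extensive(self, seed):
        img = (np.random.default_rng(seed).random((16, 16)) < 0.4).astype(
            np.uint8
        )
        once = im.clean_binary(img)
        np.testing.assert_array_equal(im.clean_binary(once), once)
        assert (once <= img).all()  # never adds dark pixels


class TestSplitAndRatio:
    def test_all_dark(self):
        f = im.split_and_ratio(np.ones((4, 4), dtype=np.uint8))
        assert f.upper_ratio == f.lower_ratio == 1.0

    def test_top_half_dark(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        img[:2] = 1
        f = im.split_and_ratio(img)
        assert (f.upper_ratio, f.lower_ratio) == (1.0, 0.0)
        assert f.compound == pytest.approx(1.0 / 1e-6)

    def test_odd_height_gives_extra_row_to_lower_half(self):
        # 5 rows x 2 cols: rows 0-1 upper, rows 2-4 lower
        img = np.array(
            [[1, 1], [1, 0], [0, 1], [0, 0], [0, 0]], dtype=np.uint8
        )
        f = im.split_and_ratio(img)
        assert f.upper_ratio == pytest.approx(3 / 4)  # hand count
        assert f.lower_ratio == pytest.approx(1 / 6)

    def test_single_row_rejected(self):
        with pytest.raises(ParameterError):
            im.split_and_ratio(np.ones((1, 4), dtype=np.uint8))

    def test_halves_cover_whole_image(self):
        rng = np.random.default_rng(5)
        for h in (2, 5, 8, 9):
            img = (rng.random((h, 6)) < 0.5).astype(np.uint8)
            mid = h // 2
            dark = img[:mid].sum() + img[mid:].sum()
            assert dark == img.sum()


class TestClassify:
    def test_open_when_upper_dominates(self):
        f = im.EyeFeatures(0.6, 0.1, 0.6 / (0.1 + 1e-6))
        assert im.classify_eye_state(f) is EyeState.OPEN

    def test_closed_when_lower_dominates(self):
        f = im.EyeFeatures(0.05, 0.4, 0.05 / (0.4 + 1e-6))
        assert im.classify_eye_state(f) is EyeState.CLOSED

    def test_tie_classifies_closed(self):
        f = im.EyeFeatures(0.2, 0.2, 1.0)
        assert im.classify_eye_state(f, ratio_threshold=1.0) is EyeState.CLOSED


class TestFrameToFeatures:
    def test_synthetic_ground_truth(self, noise_free_params):
        for state in (EyeState.OPEN, EyeState.CLOSED):
            img = generate_eye_image(state, noise_free_params, seed=0)
            _, pred = im.frame_to_features(img)
            assert pred is state

    def test_constant_crop_is_closed_with_warning(self):
        img = np.full((8, 8), 128, dtype=np.uint8)
        with pytest.warns(UserWarning, match="degenerate"):
            feats, state = im.frame_to_features(img)
        assert state is EyeState.CLOSED
        assert feats.compound == 0.0

    def test_decision_invariant_to_gain(self, noise_free_params):
        """Illumination normalization cancels global gain in [0.5, 1.5]."""
        for gain in (0.5, 0.75, 1.25, 1.5):
            for state in (EyeState.OPEN, EyeState.CLOSED):
                base = generate_eye_image(state, noise_free_params, seed=2)
                gained = generate_eye_image(
                    state,
                    dataclasses.replace(
                        noise_free_params, illumination_gain=gain
                    ),
                    seed=2,
                )
                assert im.frame_to_features(base)[1] is \
                    im.frame_to_features(gained)[1] is state


def test_calibrate_ratio_threshold_separates_labeled_set():
    compounds = np.array([0.1, 0.2, 0.3, 3.0, 4.0, 5.0])
    states = [EyeState.CLOSED] * 3 + [EyeState.OPEN] * 3
    t = im.calibrate_ratio_threshold(compounds, states)
    assert 0.3 < t < 3.0
    preds = [
        im.classify_eye_state(im.EyeFeatures(0, 0, c), t) for c in compounds
    ]
    assert preds == states
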