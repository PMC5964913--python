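import numpy as np
import pytest

from pelviseg.keyframes import (
    candidate_set,
    candidates_from_diffs,
    extract_keyframes,
    interesting_image,
    mutual_information,
    ncc,
    pixel_diff,
    roi_mask,
    roi_threshold,
    select_target,
)
from pelviseg.preprocess import SliceStack

from oracles import histogram_entropy_bits, sad_reference


class TestRoiThreshold:
    def test_mean_over_nonzero_pixels(self):
        recon = np.zeros((3, 3))
        recon[0, 0], recon[0, 1], recon[0, 2] = 10, 20, 30
        t1 = roi_threshold(recon)
        assert t1 == pytest.approx(20.0)
        mask = roi_mask(recon, t1)
        assert mask.sum() == 1 and mask[0, 2]  # only the pixel above the mean

    def test_constant_image_yields_empty_mask(self):
        recon = np.full((4, 4), 7.0)
        t1 = roi_threshold(recon)
        assert t1 == pytest.approx(7.0)
        assert not roi_mask(recon, t1).any()  # strict inequality

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError):
            roi_threshold(np.zeros((4, 4)))


class TestPixelDiff:
    def test_zero_iff_equal_and_single_pixel(self, rng):
        a = rng.integers(0, 255, (8, 8)).astype(float)
        assert pixel_diff(a, a) == 0.0
        b = a.copy()
        b[3, 4] += 5
        assert pixel_diff(a, b) == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self, rng):
        a = rng.integers(0, 255, (8, 8)).astype(float)
        b = rng.integers(0, 255, (8, 8)).astype(float)
        assert pixel_diff(a, b) == pytest.approx(sad_reference(a, b))
        assert pixel_diff(a, b) == pixel_diff(b, a)  # pseudometric symmetry

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pixel_diff(np.zeros((3, 3)), np.zeros((4, 4)))


class TestCandidateRule:
    def test_hand_evaluated_series(self):
        diffs, cands = candidates_from_diffs(np.array([10.0, 10.0, 40.0]))
        assert diffs.t2 == pytest.approx(14.0)
        assert cands == [1, 4]

    def test_identical_slices_give_only_slice_one(self):
        _, cands = candidates_from_diffs(np.zeros(5))
        assert cands == [1]

    def test_uniform_series_admits_everything(self):
        diffs, cands = candidates_from_diffs(np.array([10.0, 10.0, 10.0]))
        assert diffs.t2 == pytest.approx(7.0)
        assert cands == [1, 2, 3, 4]

    def test_needs_two_slices(self):
        with pytest.raises(ValueError):
            candidate_set(np.zeros((1, 4, 4)))


class TestMutualInformation:
    def test_self_mi_equals_histogram_entropy(self, rng):
        img = np.zeros((4, 4), dtype=np.uint8)
        img[:2] = 255  # half/half two-level image: entropy = 1 bit
        assert mutual_information(img, img) == pytest.approx(1.0)
        noisy = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        assert mutual_information(noisy, noisy) == pytest.approx(
            histogram_entropy_bits(noisy)
        )

    def test_degenerate_marginal_gives_zero(self, rng):
        a = np.full((8, 8), 9, dtype=np.uint8)
        b = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        assert mutual_information(a, b) == pytest.approx(0.0)

    def test_symmetric_and_nonnegative(self, rng):
        for _ in range(20):
            a = rng.integers(0, 256, (8, 8)).astype(np.uint8)
            b = rng.integers(0, 256, (8, 8)).astype(np.uint8)
            mab = mutual_information(a, b)
            assert mab == pytest.approx(mutual_information(b, a), abs=1e-12)
            assert mab >= -1e-12


class TestNcc:
    def test_perfect_correlation_and_anticorrelation(self, rng):
        a = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        assert ncc(a, a) == pytest.approx(1.0)
        assert ncc(a, 255 - a) == pytest.approx(-1.0)

    def test_bounded(self, rng):
        for _ in range(50):
            a = rng.integers(0, 256, (8, 8)).astype(float)
            b = rng.integers(0, 256, (8, 8)).astype(float)
            assert -1.0 - 1e-12 <= ncc(a, b) <= 1.0 + 1e-12

    def test_constant_image_is_an_error(self):
        with pytest.raises(ValueError):
            ncc(np.full((4, 4), 3.0), np.arange(16.0).reshape(4, 4))


class TestSelectTarget:
    def _stack(self, images):
        return SliceStack(images=np.stack(images))

    def test_single_candidate_passes_through(self, rng):
        imgs = [rng.integers(0, 256, (8, 8)).astype(np.uint8) for _ in range(3)]
        sets = select_target(self._stack(imgs), [1])
        assert sets.candidate == sets.intermediate == sets.target == [1]

    def test_equal_similarities_all_pass_the_mean_rule(self, rng):
        # identical images: every pairwise MI (and NCC) equals the mean,
        # and ties pass under the <= comparator
        img = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        sets = select_target(self._stack([img] * 4), [1, 2, 3, 4])
        assert sets.intermediate == [1, 2, 3, 4]
        assert sets.target == [1, 2, 3, 4]

    def test_dissimilar_pair_is_kept_similar_pair_dropped(self, rng):
        # A ~ B (high similarity), C unrelated (low): the mean rule keeps
        # the frame that follows the dissimilar pair and drops the redundant one
        a = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        b = a.copy()
        b[0, 0] ^= 1  # nearly identical
        c = rng.permuted(a.ravel()).reshape(a.shape)
        sets = select_target(self._stack([a, b, c]), [1, 2, 3])
        assert 3 in sets.target
        assert 2 not in sets.intermediate

    def test_subset_chain_on_phantom(self, small_phantom):
        result = extract_keyframes(small_phantom.stack)
        s = result.sets
        assert set(s.target) <= set(s.intermediate) <= set(s.candidate)
        assert 1 in s.target and 1 in s.intermediate and 1 in s.candidate
        assert all(a < b for a, b in zip(s.target, s.target[1:]))
        assert set(s.candidate) <= set(range(1, len(small_phantom.stack) + 1))


class TestInterestingImage:
    def test_all_zero_slice_is_an_error(self):
        with pytest.raises(ValueError):
            interesting_image(np.zeros((16, 16)))

    def test_invalid_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            interesting_image(rng.random((8, 8)) + 1, sigma=0.0)

    def test_keeps_bright_region_only(self, small_phantom):
        # on a phantom slice the interesting image concentrates on bone:
        # everything it keeps is brighter than the slice mean of its support
        img = small_phantom.stack.images[0]
        roi = interesting_image(img)
        truth = small_phantom.truth_masks[0]
        kept = roi > 0
        # bone pixels dominate the kept area
        assert (kept & truth).sum() > 0.5 * truth.sum()

    def test_odd_sized_slices_keep_their_shape(self, rng):
        img = rng.integers(1, 255, (17, 23)).astype(np.uint8)
        assert interesting_image(img).shape == (17, 23)


def test_recall_on_phantom_changes(small_phantom):
    """Every scheduled topology change lands within one slice of a target
    key frame on the session phantom."""
    result = extract_keyframes(small_phantom.stack)
    target = result.sets.target
    for change in small_phantom.truth_keyslices:
        assert min(abs(change - t) for t in target) <= 1
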