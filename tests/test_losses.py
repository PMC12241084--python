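"""Hybrid loss: hand-computed oracles, contour extraction, boundary-loss
surrogate equivalence, and algebraic properties."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ranet import autodiff as ad
from ranet.autodiff import Tensor
from ranet.losses import (LossWeights, boundary_loss, boundary_loss_surrogate,
                          compute_class_weight, dice_loss, extract_contour,
                          total_loss, weighted_ce_loss)
from .conftest import random_blob_mask


class TestDiceLoss:
    def test_perfect_overlap_is_zero_for_any_epsilon(self):
        y = (np.arange(16).reshape(4, 4) % 3 == 0).astype(float)
        for eps in (1e-6, 1.0, 10.0):
            assert dice_loss(y, y, eps) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_toy_case(self):
        pred = np.array([[1.0, 0.0], [0.0, 0.0]])
        true = np.array([[1, 1], [0, 0]])
        assert dice_loss(pred, true, 1.0) == pytest.approx(0.25)

    def test_empty_masks_guarded_by_epsilon(self):
        z = np.zeros((3, 3))
        assert dice_loss(z, z, 1.0) == pytest.approx(0.0)

    def test_range_and_monotone_improvement(self, rng):
        y = random_blob_mask(rng).astype(float)
        worse = np.clip(y * 0.6 + 0.2, 0, 1)
        better = np.clip(y * 0.9 + 0.05, 0, 1)
        lw, lb = dice_loss(worse, y), dice_loss(better, y)
        assert 0 <= lb < lw < 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestClassWeight:
    @pytest.mark.parametrize("fg_frac,expected", [(0.5, 1.0), (0.25, 3.0)])
    def test_inverse_foreground_frequency(self, fg_frac, expected):
        y = np.zeros(16)
        y[: int(16 * fg_frac)] = 1
        assert compute_class_weight(y.reshape(4, 4)) == pytest.approx(expected)

    def test_two_foreground_of_32(self):
        y = np.zeros(32)
        y[:2] = 1
        assert compute_class_weight(y.reshape(4, 8)) == pytest.approx(15.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no foreground"):
            compute_class_weight(np.zeros((4, 4)))


class TestWeightedCE:
    def test_weight_one_reduces_to_mean_bce(self, rng):
        y = random_blob_mask(rng).astype(float)
        p = np.clip(rng.random(y.shape), 1e-6, 1 - 1e-6)
        expected = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        for mode in ("foreground_weighted", "global_scale"):
            assert weighted_ce_loss(p, y, 1.0, mode) == pytest.approx(expected)

    def test_single_pixel_hand_value(self):
        p = np.array([[0.5]])
        y = np.array([[1]])
        for mode in ("foreground_weighted", "global_scale"):
            assert weighted_ce_loss(p, y, 2.0, mode) == pytest.approx(
                2 * np.log(2))

    def test_near_perfect_prediction_near_zero(self, rng):
        y = random_blob_mask(rng).astype(float)
        assert weighted_ce_loss(y, y, 3.0) < 1e-5


class TestExtractContour:
    def test_single_pixel_is_its_own_contour(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 3] = 1
        assert extract_contour(m).tolist() == [[2, 3]]

    def test_solid_square_yields_border_ring(self):
        m = np.zeros((7, 7), dtype=np.uint8)
        m[2:5, 2:5] = 1
        contour = extract_contour(m)
        assert len(contour) == 8  # 3x3 square minus its centre
        assert [2, 2] in contour.tolist() and [3, 3] not in contour.tolist()

    def test_empty_mask_gives_empty_contour(self):
        assert len(extract_contour(np.zeros((4, 4)))) == 0

    def test_contour_points_touch_background(self, rng):
        m = random_blob_mask(rng)
        padded = np.pad(m, 1)
        for r, c in extract_contour(m):
            neigh = [padded[r, c + 1], padded[r + 2, c + 1],
                     padded[r + 1, c], padded[r + 1, c + 2]]
            assert m[r, c] == 1 and min(neigh) == 0


def brute_force_boundary(pred, true, normalize):
    """All-pairs nearest-neighbour oracle for the symmetric contour distance."""
    cp, ct = extract_contour(pred), extract_contour(true)
    d = cdist(ct, cp)
    total = d.min(axis=1).sum() + d.min(axis=0).sum()
    return total / (len(cp) + len(ct)) if normalize else total


class TestBoundaryLoss:
    def test_identical_masks_zero(self, rng):
        m = random_blob_mask(rng)
        assert boundary_loss(m, m) == 0.0

    def test_three_four_five_pixels(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        b = np.zeros((8, 8), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 4] = 1
        assert boundary_loss(a, b, normalize=False) == pytest.approx(10.0)
        assert boundary_loss(a, b, normalize=True) == pytest.approx(5.0)

    def test_shifted_square_matches_all_pairs_oracle(self):
        a = np.zeros((10, 10), dtype=np.uint8)
        a[3:6, 3:6] = 1
        b = np.roll(a, 1, axis=1)
        for normalize in (True, False):
            assert boundary_loss(a, b, normalize=normalize) == pytest.approx(
                brute_force_boundary(b, a, normalize))

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = random_blob_mask(rng), random_blob_mask(rng)
            assert boundary_loss(a, b) == pytest.approx(boundary_loss(b, a))

    def test_empty_contour_returns_penalty_with_warning(self):
        a = np.zeros((6, 6), dtype=np.uint8)
        b = np.zeros((6, 6), dtype=np.uint8)
        b[2, 2] = 1
        with pytest.warns(UserWarning, match="empty"):
            assert boundary_loss(a, b, empty_penalty=42.0) == 42.0
        assert boundary_loss(a, a) == 0.0  # both empty: identical masks


class TestBoundarySurrogate:
    def test_equals_exact_on_binary_masks(self, rng):
        for _ in range(50):
            a, b = random_blob_mask(rng), random_blob_mask(rng)
            if a.sum() == 0 or b.sum() == 0:
                continue
            for normalize in (True, False):
                exact = boundary_loss(a, b, normalize=normalize)
                surr = boundary_loss_surrogate(a.astype(float), b,
                                               normalize=normalize)
                assert abs(surr - exact) < 1e-6

    def test_gradient_lives_on_prediction_contour(self, rng):
        true = random_blob_mask(rng)
        pred_bin = np.roll(true, 2, axis=0)
        pred = Tensor(pred_bin.astype(float), requires_grad=True)
        out = boundary_loss_surrogate(pred, true)
        out.backward()
        contour = set(map(tuple, extract_contour(pred_bin)))
        nz = set(map(tuple, np.argwhere(pred.grad != 0)))
        assert nz <= contour and len(nz) > 0


class TestTotalLoss:
    def test_dice_only_reduction(self, rng):
        y = random_blob_mask(rng)
        p = np.clip(rng.random(y.shape), 0, 1)
        w = LossWeights(lambda_dice=1.0, lambda_wce=0.0, lambda_boundary=0.0)
        total, breakdown = total_loss(p, y, w)
        assert total == pytest.approx(dice_loss(p, y, w.epsilon))
        assert breakdown["wce"] == 0.0

    def test_all_zero_weights_give_zero(self, rng):
        y = random_blob_mask(rng)
        total, _ = total_loss(rng.random(y.shape), y,
                              LossWeights(0.0, 0.0, 0.0))
        assert total == 0.0

    def test_weighted_sum_linearity(self, rng):
        y = random_blob_mask(rng)
        p = np.clip(rng.random(y.shape) * 0.8 + 0.1, 0, 1)
        w = LossWeights(lambda_dice=0.5, lambda_wce=0.3, lambda_boundary=0.2)
        total, parts = total_loss(p, y, w)
        assert total == pytest.approx(0.5 * parts["dice"] + 0.3 * parts["wce"]
                                      + 0.2 * parts["boundary"])

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_dice=-1.0)
        with pytest.raises(ValueError):
            LossWeights(epsilon=0.0)
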