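"""Loss-function tests against independent brute-force implementations.

Every loss is checked on small random inputs against a plain double-loop
(or direct formula) implementation kept free of any package code.
"""

import numpy as np
import pytest

from virtustain.imaging_io import BinaryMask
from virtustain.losses import (
    LossConfig,
    SegWeightMask,
    downscale_mean,
    downscale_nearest,
    gradient_loss,
    lipid_total_loss,
    multiscale_lwm_loss,
    nuclei_total_loss,
    ralsgan_discriminator_loss,
    ralsgan_generator_loss,
    segmentation_bce,
    segmentation_weight_mask,
    weighted_l1,
)
from virtustain.networks import GeneratorOutput
from virtustain.nn.autograd import Tensor


# -------------------------------------------------------- brute-force oracles
def brute_weighted_l1(pred, gt, z, reduction):
    total = 0.0
    h, w = pred.shape
    for i in range(h):
        for j in range(w):
            total += z[i, j] * abs(pred[i, j] - gt[i, j])
    return total / (h * w) if reduction == "mean" else total


def brute_gradient_loss(pred, gt, reduction):
    h, w = pred.shape
    total, n = 0.0, 0
    for i in range(h):
        for j in range(w - 1):
            total += abs((pred[i, j + 1] - pred[i, j]) - (gt[i, j + 1] - gt[i, j]))
            n += 1
    for i in range(h - 1):
        for j in range(w):
            total += abs((pred[i + 1, j] - pred[i, j]) - (gt[i + 1, j] - gt[i, j]))
            n += 1
    return total / n if reduction == "mean" else total


def brute_ralsgan(d_real, d_fake, generator):
    s = 1.0 if generator else -1.0
    mr, mf = np.mean(d_real), np.mean(d_fake)
    return np.mean((d_real - mf + s) ** 2) + np.mean((d_fake - mr - s) ** 2)


def brute_swm(prob, gt, eta, thr):
    out = np.ones_like(prob)
    h, w = prob.shape
    for i in range(h):
        for j in range(w):
            if (prob[i, j] >= thr) != (gt[i, j] > 0.5):
                out[i, j] = eta
    return out


# ------------------------------------------------------------------ SWM
class TestSegmentationWeightMask:
    def test_misclassified_pixel_gets_eta(self):
        swm = segmentation_weight_mask(np.array([[0.3]]), np.array([[1]]))
        assert swm.weights[0, 0] == 2.0

    def test_correct_pixel_gets_one(self):
        swm = segmentation_weight_mask(np.array([[0.9]]), np.array([[1]]))
        assert swm.weights[0, 0] == 1.0

    def test_perfect_segmentation_all_ones(self):
        gt = np.array([[0, 1], [1, 0]])
        swm = segmentation_weight_mask(gt.astype(float), gt)
        assert np.all(swm.weights == 1.0)

    def test_matches_brute_force(self, rng):
        prob = rng.random((8, 8))
        gt = (rng.random((8, 8)) > 0.5).astype(float)
        swm = segmentation_weight_mask(prob, gt)
        np.testing.assert_allclose(swm.weights, brute_swm(prob, gt, 2.0, 0.5), rtol=1e-6)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            segmentation_weight_mask(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_values_restricted_to_one_and_eta(self):
        with pytest.raises(ValueError):
            SegWeightMask(weights=np.array([[1.5]]), eta=2.0)


# ---------------------------------------------------------- weighted L1
class TestWeightedL1:
    def test_zero_for_identical(self):
        img = np.random.default_rng(1).random((4, 4))
        assert float(weighted_l1(img, img)) == 0.0

    def test_hand_computed_mean_form(self):
        pred = np.array([[0.5, 1.0]])
        gt = np.array([[0.0, 0.5]])
        z = np.array([[1.0, 2.0]])
        assert float(weighted_l1(pred, gt, z)) == pytest.approx(0.75)

    def test_unit_weights_reduce_to_plain_l1(self, rng):
        pred, gt = rng.random((8, 8)), rng.random((8, 8))
        z = np.ones((8, 8))
        assert float(weighted_l1(pred, gt, z)) == pytest.approx(
            np.abs(pred - gt).mean(), rel=1e-12)

    @pytest.mark.parametrize("reduction", ["mean", "sum"])
    def test_matches_brute_force(self, rng, reduction):
        pred, gt = rng.random((8, 8)), rng.random((8, 8))
        z = np.where(rng.random((8, 8)) > 0.5, 2.0, 1.0)
        expected = brute_weighted_l1(pred, gt, z, reduction)
        assert float(weighted_l1(pred, gt, z, reduction=reduction)) == pytest.approx(
            expected, rel=1e-6)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            weighted_l1(np.zeros((2, 2)), np.zeros((2, 3)))


# ------------------------------------------------------- multi-scale LWM
class TestMultiscaleLwm:
    def test_zero_when_preds_equal_resized_gt(self, rng):
        gt = rng.random((8, 8))
        preds = [downscale_mean(gt, 4), downscale_mean(gt, 2)]
        assert float(multiscale_lwm_loss(preds, gt)) == pytest.approx(0.0, abs=1e-12)

    def test_single_scale_equals_weighted_l1(self, rng):
        gt = rng.random((8, 8))
        z = np.where(rng.random((8, 8)) > 0.5, 2.0, 1.0)
        pred = rng.random((4, 4))
        lwm = float(multiscale_lwm_loss([pred], gt, z))
        direct = float(weighted_l1(pred, downscale_mean(gt, 2), downscale_nearest(z, 2)))
        assert lwm == pytest.approx(direct, rel=1e-12)

    def test_two_scales_sum_of_hand_computed_terms(self, rng):
        gt = rng.random((8, 8))
        z = np.where(rng.random((8, 8)) > 0.5, 2.0, 1.0)
        p2, p4 = rng.random((4, 4)), rng.random((2, 2))
        expected = (
            brute_weighted_l1(p4, downscale_mean(gt, 4), downscale_nearest(z, 4), "mean")
            + brute_weighted_l1(p2, downscale_mean(gt, 2), downscale_nearest(z, 2), "mean")
        )
        got = float(multiscale_lwm_loss([p4, p2], gt, z))
        assert got == pytest.approx(expected, rel=1e-6)

    def test_non_power_of_two_scale_errors(self):
        with pytest.raises(ValueError):
            multiscale_lwm_loss([np.zeros((3, 3))], np.zeros((8, 8)))

    def test_nearest_downscale_preserves_weight_values(self, rng):
        z = np.where(rng.random((8, 8)) > 0.5, 2.0, 1.0)
        down = downscale_nearest(z, 2)
        assert set(np.unique(down)) <= {1.0, 2.0}


# ------------------------------------------------------ nuclei composite
class TestNucleiTotalLoss:
    @staticmethod
    def _output(image, seg_logits, scale_preds):
        return GeneratorOutput(image=Tensor(image), seg_logits=Tensor(seg_logits),
                               scale_preds=[Tensor(p) for p in scale_preds])

    def test_perfect_prediction_near_zero(self):
        gt = (np.random.default_rng(2).random((8, 8)) > 0.6).astype(float)
        out = self._output(gt, np.where(gt > 0.5, 60.0, -60.0), [downscale_mean(gt, 2)])
        total, comps = nuclei_total_loss(out, gt, gt)
        assert comps["l1_reg"] == 0.0
        assert comps["lwm"] == pytest.approx(0.0, abs=1e-12)
        assert comps["seg_bce"] == pytest.approx(0.0, abs=1e-12)
        assert float(total) == pytest.approx(0.0, abs=1e-9)

    def test_weight_zeroing_reduces_to_weighted_l1(self, rng):
        gt = rng.random((8, 8))
        mask = (rng.random((8, 8)) > 0.5).astype(float)
        pred = rng.random((8, 8))
        logits = rng.normal(size=(8, 8))
        out = self._output(pred, logits, [rng.random((4, 4))])
        cfg = LossConfig(alpha_lwm=0.0, alpha_seg=0.0)
        total, _ = nuclei_total_loss(out, gt, mask, cfg)
        prob = 1.0 / (1.0 + np.exp(-logits))
        z = brute_swm(prob, mask, 2.0, 0.5)
        assert float(total) == pytest.approx(brute_weighted_l1(pred, gt, z, "mean"), rel=1e-6)

    def test_components_recombine_with_stated_weights(self, rng):
        gt = rng.random((8, 8))
        mask = (rng.random((8, 8)) > 0.5).astype(float)
        out = self._output(rng.random((8, 8)), rng.normal(size=(8, 8)),
                           [rng.random((4, 4))])
        total, comps = nuclei_total_loss(out, gt, mask)
        assert float(total) == pytest.approx(
            comps["l1_reg"] + 0.1 * comps["lwm"] + 0.05 * comps["seg_bce"], rel=1e-9)


# ---------------------------------------------------------- gradient loss
class TestGradientLoss:
    def test_zero_for_identical(self, rng):
        img = rng.random((6, 6))
        assert float(gradient_loss(img, img)) == 0.0

    def test_invariant_to_constant_offset(self, rng):
        gt = rng.random((6, 6)) * 0.5
        assert float(gradient_loss(gt + 0.25, gt)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_sum_form(self):
        pred = np.zeros((2, 2))
        gt = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert float(gradient_loss(pred, gt, reduction="sum")) == pytest.approx(2.0)

    @pytest.mark.parametrize("reduction", ["mean", "sum"])
    def test_matches_brute_force(self, rng, reduction):
        pred, gt = rng.random((8, 8)), rng.random((8, 8))
        expected = brute_gradient_loss(pred, gt, reduction)
        assert float(gradient_loss(pred, gt, reduction=reduction)) == pytest.approx(
            expected, rel=1e-6)

    def test_too_small_image_errors(self):
        with pytest.raises(ValueError):
            gradient_loss(np.zeros((1, 5)), np.zeros((1, 5)))


# ------------------------------------------------------------ raLSGAN
class TestRalsgan:
    def test_constant_scores_give_two(self):
        for c in (-3.0, 0.0, 7.5):
            scores = np.full(5, c)
            assert float(ralsgan_generator_loss(scores, scores)) == pytest.approx(2.0)
            assert float(ralsgan_discriminator_loss(scores, scores)) == pytest.approx(2.0)

    def test_separated_scores_analytic_values(self):
        d_real, d_fake = np.array([1.0, 1.0]), np.array([0.0, 0.0])
        assert float(ralsgan_generator_loss(d_real, d_fake)) == pytest.approx(8.0)
        assert float(ralsgan_discriminator_loss(d_real, d_fake)) == pytest.approx(0.0)

    def test_asymmetric_in_real_fake_swap(self, rng):
        d_real, d_fake = rng.normal(size=6), rng.normal(size=6) + 1.0
        g_ab = float(ralsgan_generator_loss(d_real, d_fake))
        g_ba = float(ralsgan_generator_loss(d_fake, d_real))
        assert g_ab != pytest.approx(g_ba)

    def test_invariant_to_common_score_shift(self, rng):
        d_real, d_fake = rng.normal(size=6), rng.normal(size=6)
        base = float(ralsgan_discriminator_loss(d_real, d_fake))
        shifted = float(ralsgan_discriminator_loss(d_real + 5.0, d_fake + 5.0))
        assert shifted == pytest.approx(base, rel=1e-9)

    @pytest.mark.parametrize("generator", [True, False])
    def test_matches_brute_force(self, rng, generator):
        d_real, d_fake = rng.normal(size=(8, 8)), rng.normal(size=(8, 8))
        fn = ralsgan_generator_loss if generator else ralsgan_discriminator_loss
        assert float(fn(d_real, d_fake)) == pytest.approx(
            brute_ralsgan(d_real, d_fake, generator), rel=1e-6)

    def test_empty_scores_error(self):
        with pytest.raises(ValueError):
            ralsgan_generator_loss(np.array([]), np.array([1.0]))


# ------------------------------------------------------- lipid composite
class TestLipidTotalLoss:
    def test_perfect_prediction_leaves_trivial_gan_term(self, rng):
        gt = rng.random((8, 8))
        scores = np.full(4, 0.3)
        total, comps = lipid_total_loss(gt, gt, scores, scores)
        assert comps["l1"] == 0.0 and comps["grad"] == 0.0
        assert float(total) == pytest.approx(0.02)

    def test_weight_zeroing_reduces_to_l1(self, rng):
        pred, gt = rng.random((8, 8)), rng.random((8, 8))
        cfg = LossConfig(alpha_grad=0.0, alpha_adv=0.0)
        total, _ = lipid_total_loss(pred, gt, np.ones(3), np.zeros(3), cfg)
        assert float(total) == pytest.approx(np.abs(pred - gt).mean(), rel=1e-9)

    def test_components_recombine_with_stated_weights(self, rng):
        pred, gt = rng.random((8, 8)), rng.random((8, 8))
        d_real, d_fake = rng.normal(size=4), rng.normal(size=4)
        total, comps = lipid_total_loss(pred, gt, d_real, d_fake)
        assert float(total) == pytest.approx(
            1.0 * comps["l1"] + 5.0 * comps["grad"] + 0.01 * comps["adv"], rel=1e-9)


class TestLossConfig:
    def test_invalid_eta_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(eta=0.5)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(seg_threshold=1.0)


class TestSegmentationBce:
    def test_matches_direct_cross_entropy(self, rng):
        logits = rng.normal(size=(8, 8))
        target = (rng.random((8, 8)) > 0.5).astype(float)
        p = 1.0 / (1.0 + np.exp(-logits))
        expected = -(target * np.log(p) + (1 - target) * np.log(1 - p)).mean()
        assert float(segmentation_bce(logits, BinaryMask(target.astype(int)))) == \
            pytest.approx(expected, rel=1e-9)

    def test_stable_for_extreme_logits(self):
        val = float(segmentation_bce(np.array([[1000.0, -1000.0]]),
                                     np.array([[1, 0]])))
        assert np.isfinite(val) and val == pytest.approx(0.0, abs=1e-12)
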