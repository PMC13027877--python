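"""Hybrid loss closed forms, confusion arithmetic, metric identities and
curve AUCs against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltpnet import nn
from ltpnet.exceptions import InputError, ShapeError, UndefinedMetricError
from ltpnet.losses import LossWeights, bce_loss, dice_loss, hybrid_loss
from ltpnet.metrics import (
    ConfusionCounts,
    confusion,
    pr_roc,
    segmentation_metrics,
)
from oracles import roc_auc_pairwise


class TestHybridLoss:
    def test_perfect_prediction_near_zero(self, rng):
        gt = (rng.random((2, 1, 8, 8)) > 0.5).astype(float)
        loss = hybrid_loss(gt, gt)
        assert 0.0 <= loss.item() <= 1e-3

    def test_uniform_half_bce_is_ln2(self, rng):
        gt = (rng.random((1, 1, 10, 10)) > 0.3).astype(float)
        probs = np.full_like(gt, 0.5)
        assert bce_loss(probs, gt).item() == pytest.approx(np.log(2.0), abs=1e-12)

    def test_default_weights_sum_components(self, rng):
        probs = rng.random((1, 1, 6, 6))
        gt = (rng.random((1, 1, 6, 6)) > 0.5).astype(float)
        combined = hybrid_loss(probs, gt)  # defaults lambda1 = lambda2 = 1
        separate = bce_loss(probs, gt).item() + dice_loss(probs, gt).item()
        assert combined.item() == pytest.approx(separate, abs=1e-12)

    def test_loss_nonnegative_and_decreases_toward_gt(self, rng):
        gt = (rng.random((1, 1, 8, 8)) > 0.5).astype(float)
        start = rng.uniform(0.2, 0.8, gt.shape)
        prev = np.inf
        for t in np.linspace(0.0, 0.95, 8):
            probs = (1 - t) * start + t * gt
            val = hybrid_loss(probs, gt).item()
            assert 0.0 <= val < prev
            prev = val

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            hybrid_loss(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 5, 5)))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-1.0, 1.0)

    def test_differentiable(self, rng):
        probs = nn.Tensor(rng.uniform(0.1, 0.9, (1, 1, 4, 4)), requires_grad=True)
        gt = (rng.random((1, 1, 4, 4)) > 0.5).astype(float)
        hybrid_loss(probs, nn.Tensor(gt)).backward()
        assert probs.grad is not None and np.all(np.isfinite(probs.grad))


class TestConfusion:
    def test_perfect_prediction(self, rng):
        gt = (rng.random((2, 1, 5, 5)) > 0.5).astype(int)
        c = confusion(gt, gt)
        assert c.fp == 0 and c.fn == 0
        assert c.tp + c.tn == gt.size

    def test_complement_prediction(self, rng):
        gt = (rng.random((10,)) > 0.5).astype(int)
        c = confusion(1 - gt, gt)
        assert c.tp == 0 and c.tn == 0

    def test_hand_placed_counts(self):
        gt = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        c = confusion(pred, gt)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 1, 1, 5)

    def test_non_binary_rejected(self):
        with pytest.raises(InputError):
            confusion(np.array([0, 2, 1]), np.array([0, 1, 1]))

    def test_counts_total_invariant(self, rng):
        pred = (rng.random((3, 1, 6, 6)) > 0.4).astype(int)
        gt = (rng.random((3, 1, 6, 6)) > 0.6).astype(int)
        assert confusion(pred, gt).total == pred.size


class TestSegmentationMetrics:
    def test_hand_arithmetic(self):
        r = segmentation_metrics(ConfusionCounts(3, 1, 1, 5))
        assert r.acc == pytest.approx(0.8)
        assert r.sen == pytest.approx(0.75)
        assert r.spe == pytest.approx(0.8333, abs=1e-4)
        assert r.dsc == pytest.approx(0.75)
        assert r.miou == pytest.approx(0.6)

    def test_perfect_prediction_all_ones(self):
        r = segmentation_metrics(ConfusionCounts(10, 0, 0, 20))
        assert (r.miou, r.dsc, r.acc, r.spe, r.sen) == (1, 1, 1, 1, 1)

    @given(tp=st.integers(0, 10_000), fp=st.integers(0, 10_000),
           fn=st.integers(0, 10_000), tn=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_identity_miou_from_dsc(self, tp, fp, fn, tn):
        if tp + fn == 0 or tn + fp == 0:
            return
        r = segmentation_metrics(ConfusionCounts(tp, fp, fn, tn))
        assert r.miou == pytest.approx(r.dsc / (2.0 - r.dsc), abs=1e-12)

    def test_identity_consistent_with_published_pair(self):
        # a (DSC, IoU) pair printed as (96.12, 92.52) satisfies the
        # aggregated-confusion identity IoU = DSC / (2 - DSC)
        dsc = 0.9612
        assert 100 * dsc / (2 - dsc) == pytest.approx(92.52, abs=0.01)

    def test_empty_class_raises_named_error(self):
        with pytest.raises(UndefinedMetricError, match="sensitivity"):
            segmentation_metrics(ConfusionCounts(0, 3, 0, 5))
        with pytest.raises(UndefinedMetricError, match="specificity"):
            segmentation_metrics(ConfusionCounts(3, 0, 1, 0))


class TestCurves:
    def test_perfect_separation_auc_one(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0, 0])
        assert pr_roc(scores, labels).auc_roc == pytest.approx(1.0)

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10_000)
        labels = (rng.random(10_000) > 0.5).astype(int)
        assert pr_roc(scores, labels).auc_roc == pytest.approx(0.5, abs=0.02)

    def test_score_reversal_symmetry(self, rng):
        scores = rng.random(500)
        labels = (rng.random(500) > 0.6).astype(int)
        a = pr_roc(scores, labels).auc_roc
        b = pr_roc(-scores, labels).auc_roc
        assert a + b == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n,tie_fraction", [(50, 0.0), (200, 0.0), (150, 0.5)])
    def test_roc_auc_matches_pairwise_oracle(self, rng, n, tie_fraction):
        scores = rng.random(n)
        if tie_fraction:
            scores = np.round(scores, 1)  # force ties
        labels = (rng.random(n) > 0.5).astype(int)
        ours = pr_roc(scores, labels).auc_roc
        oracle = roc_auc_pairwise(scores, labels)
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            pr_roc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_threshold_tie_rule_constant_half(self):
        # the >= rule makes a constant-0.5 predictor call everything
        # positive at threshold 0.5: sen = 1, spe = 0
        probs = np.full(20, 0.5)
        gt = np.array([1] * 5 + [0] * 15)
        pred = (probs >= 0.5).astype(int)
        c = confusion(pred, gt)
        assert c.fn == 0 and c.tn == 0
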