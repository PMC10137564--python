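"""Evaluation metrics vs brute-force oracles and closed forms."""

import numpy as np
import pytest
from scipy import stats as sps

from ctrseg import io
from ctrseg.errors import DegenerateInputError
from ctrseg.metrics import (
    ConfusionCounts,
    agreement_report,
    bland_altman,
    confusion,
    diagnostic_performance,
    difference_stats,
    paired_t_test,
    regression_r2,
    roc_auc,
    seg_metrics,
)

from conftest import random_mask


def confusion_oracle(pred, ref):
    """Per-pixel Python loop, one-vs-rest per class."""
    tp = np.zeros(3, np.int64)
    fp = np.zeros(3, np.int64)
    fn = np.zeros(3, np.int64)
    tn = np.zeros(3, np.int64)
    for r in range(pred.shape[0]):
        for c in range(pred.shape[1]):
            p, g = pred[r, c], ref[r, c]
            for cls in range(3):
                if p == cls and g == cls:
                    tp[cls] += 1
                elif p == cls:
                    fp[cls] += 1
                elif g == cls:
                    fn[cls] += 1
                else:
                    tn[cls] += 1
    return tp, fp, fn, tn


def auc_oracle(scores, labels):
    """Pairwise counting: P(s+ > s-) + 0.5 P(s+ = s-)."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def counts(tp, fp, fn, total=1000, cls=io.HEART):
    """ConfusionCounts with the given tallies in one class."""
    z = np.zeros(3, np.int64)
    c = dict(tp=z.copy(), fp=z.copy(), fn=z.copy(), tn=z.copy())
    c["tp"][cls], c["fp"][cls], c["fn"][cls] = tp, fp, fn
    c["tn"][cls] = total - tp - fp - fn
    # give the other foreground class some pixels so averages exist
    other = io.LUNG if cls == io.HEART else io.HEART
    c["tp"][other], c["tn"][other] = 1, total - 1
    return ConfusionCounts(**c)


class TestConfusion:
    def test_perfect_prediction(self, rng):
        m = random_mask(rng)
        cc = confusion(m, m)
        assert (cc.fp == 0).all() and (cc.fn == 0).all()

    def test_all_background_vs_k_heart_pixels(self):
        ref = np.zeros((8, 8), np.uint8)
        ref[2:4, 2:5] = io.HEART
        cc = confusion(np.zeros((8, 8), np.uint8), ref)
        assert cc.fn[io.HEART] == 6

    def test_matches_per_pixel_loop(self, rng):
        for _ in range(25):
            pred = random_mask(rng, h=8, w=8)
            ref = random_mask(rng, h=8, w=8)
            cc = confusion(pred, ref)
            tp, fp, fn, tn = confusion_oracle(pred, ref)
            assert np.array_equal(cc.tp, tp) and np.array_equal(cc.fp, fp)
            assert np.array_equal(cc.fn, fn) and np.array_equal(cc.tn, tn)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((4, 4), np.uint8), np.zeros((5, 5), np.uint8))


class TestSegMetrics:
    def test_iou_dice_example(self):
        m = seg_metrics(counts(tp=8, fp=1, fn=1))
        assert m.iou_per_class[io.HEART] == pytest.approx(0.8)
        assert m.dice_per_class[io.HEART] == pytest.approx(2 * 0.8 / 1.8)

    def test_dice_from_ppv_tpr_formula(self):
        # PPV 0.9, TPR 0.8  ->  2*0.9*0.8/(0.9+0.8) = 0.8471
        m = seg_metrics(counts(tp=36, fp=4, fn=9))
        assert m.dice_per_class[io.HEART] == pytest.approx(1.44 / 1.7)

    def test_perfect_prediction_gives_unity(self, rng):
        m = random_mask(rng, ensure_all_classes=True)
        sm = seg_metrics(confusion(m, m))
        assert sm.miou == 1.0 and sm.adc == 1.0

    def test_dice_iou_identity_and_ordering(self, rng):
        for _ in range(50):
            cc = confusion(random_mask(rng, h=16, w=16),
                           random_mask(rng, h=16, w=16))
            sm = seg_metrics(cc, classes_to_average=(0, 1, 2))
            for c, iou in sm.iou_per_class.items():
                assert sm.dice_per_class[c] == pytest.approx(
                    2 * iou / (1 + iou), abs=1e-12)
            assert sm.miou <= sm.adc + 1e-15

    def test_absent_class_excluded_from_average(self):
        pred = np.zeros((6, 6), np.uint8)
        pred[0, 0] = io.LUNG
        ref = pred.copy()
        sm = seg_metrics(confusion(pred, ref))
        assert sm.class_set_averaged == (io.LUNG,)


class TestRegressionR2:
    def test_identity_and_affine_give_one(self):
        x = np.linspace(0.4, 0.6, 10)
        assert regression_r2(x, x) == pytest.approx(1.0)
        assert regression_r2(x, 2 * x + 5) == pytest.approx(1.0)

    def test_matches_brute_force_ols(self, rng):
        for _ in range(10):
            x = rng.normal(0.5, 0.05, 30)
            y = x + rng.normal(0, 0.02, 30)
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            expected = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
            assert regression_r2(x, y) == pytest.approx(expected)

    def test_constant_reference_rejected(self):
        with pytest.raises(DegenerateInputError):
            regression_r2([0.5, 0.5, 0.5], [0.4, 0.5, 0.6])


class TestDifferenceStats:
    def test_hand_example(self):
        mean, sd, n_ge = difference_stats([0.50, 0.52], [0.51, 0.51])
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)
        assert n_ge == 0

    def test_identical_inputs(self):
        assert difference_stats([0.4, 0.5], [0.4, 0.5]) == (0.0, 0.0, 0)

    def test_threshold_is_inclusive(self):
        _, _, n_ge = difference_stats([0.50, 0.50], [0.52, 0.515])
        assert n_ge == 1

    def test_matches_brute_force(self, rng):
        ref = rng.normal(0.5, 0.05, 40)
        test = ref + rng.normal(0, 0.02, 40)
        mean, sd, n_ge = difference_stats(ref, test)
        d = np.abs(test - ref)
        assert mean == pytest.approx(d.mean() * 100)
        assert sd == pytest.approx(d.std(ddof=1) * 100)
        assert n_ge == int((d >= 0.02).sum())


class TestBlandAltman:
    def test_constant_offset_collapses_limits(self):
        ref = np.array([0.4, 0.5, 0.6])
        ba = bland_altman(ref, ref + 0.01)
        assert ba.bias == pytest.approx(0.01)
        assert ba.lower_loa == pytest.approx(0.01)
        assert ba.upper_loa == pytest.approx(0.01)

    def test_identical_methods_all_zero(self):
        ba = bland_altman([0.4, 0.5], [0.4, 0.5])
        assert ba.bias == ba.lower_loa == ba.upper_loa == 0.0

    def test_limits_cover_95pct_of_normal_differences(self, rng):
        n = 1000
        ref = rng.normal(0.5, 0.05, n)
        test = ref + rng.normal(0.0, 0.01, n)
        ba = bland_altman(ref, test)
        inside = ((ba.diffs >= ba.lower_loa) & (ba.diffs <= ba.upper_loa)).mean()
        assert abs(inside - 0.95) < 0.015


class TestRocAuc:
    def test_perfect_separation(self):
        points, auc = roc_auc([0.6, 0.7, 0.3, 0.2], [True, True, False, False])
        assert auc == 1.0
        assert tuple(points[0]) == (0.0, 0.0) and tuple(points[-1]) == (1.0, 1.0)

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = rng.choice([0.3, 0.4, 0.5, 0.55, 0.6], size=n)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(auc_oracle(scores, labels), abs=1e-12)

    def test_roc_points_monotone(self, rng):
        scores = rng.normal(0.5, 0.1, 50)
        labels = rng.random(50) < 0.6
        points, _ = roc_auc(scores, labels)
        assert (np.diff(points[:, 0]) >= 0).all()
        assert (np.diff(points[:, 1]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_auc([0.4, 0.6], [True, True])

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            scores = np.round(rng.random(40), 2)
            labels = rng.random(40) < 0.5
            if labels.all() or not labels.any():
                continue
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(roc_auc_score(labels, scores),
                                        abs=1e-12)


class TestDiagnosticPerformance:
    def test_perfect_agreement(self):
        ref = [0.45, 0.55, 0.60, 0.48]
        rep = diagnostic_performance(ref, ref)
        assert rep.accuracy == rep.sensitivity == rep.specificity == 1.0

    def test_all_positive_predictions(self):
        rep = diagnostic_performance([0.9, 0.9, 0.9], [0.6, 0.4, 0.55])
        assert rep.sensitivity == 1.0
        assert rep.specificity == 0.0

    def test_matches_contingency_brute_force(self, rng):
        ref = rng.normal(0.5, 0.06, 60)
        test = ref + rng.normal(0, 0.02, 60)
        rep = diagnostic_performance(test, ref)
        truth, pred = ref > 0.5, test > 0.5
        tp = (pred & truth).sum()
        tn = (~pred & ~truth).sum()
        assert rep.accuracy == pytest.approx((tp + tn) / 60)
        assert rep.sensitivity == pytest.approx(tp / truth.sum())
        assert rep.specificity == pytest.approx(tn / (~truth).sum())


class TestPairedTTest:
    def test_hand_example_against_t_distribution(self):
        t, p = paired_t_test([1, 2, 3], [0, 0, 0])
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-4)     # 3.4641
        assert p == pytest.approx(2 * sps.t.sf(2 * np.sqrt(3), df=2), abs=1e-4)

    def test_null_p_values_are_uniform(self, rng):
        ps = []
        for _ in range(500):
            a = rng.normal(0, 1, 15)
            b = rng.normal(0, 1, 15)
            ps.append(paired_t_test(a, b)[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestAgreementReport:
    def test_fields_consistent(self, rng):
        ref = rng.normal(0.53, 0.05, 30)
        test = ref + rng.normal(0.002, 0.01, 30)
        rep = agreement_report(ref, test)
        assert rep.n == 30
        assert rep.bland_altman[0] == pytest.approx((test - ref).mean())
        assert 0 <= rep.n_bias_ge_2pct <= 30
        assert rep.r2 <= 1.0
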