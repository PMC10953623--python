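"""Confusion metrics, Dice, correlation, group comparisons and the
misclassification report."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import bruteforce_confusion

from ventra.evaluation import (ConfusionMatrix, UndefinedMetricError,
                               classification_metrics, confusion, dice,
                               group_compare, misclassification_report,
                               volume_correlation)
from ventra.io_model import GeometryError, LabelVolume, SchemaError


class TestConfusion:
    def test_all_correct(self):
        cm = confusion([1] * 5 + [0] * 5, [1] * 5 + [0] * 5)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (5, 0, 0, 5)

    def test_all_predicted_positive(self):
        cm = confusion([1, 1, 0, 0], [1, 1, 1, 1])
        assert cm.fn == 0 and cm.tn == 0
        assert cm.tp == 2 and cm.fp == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_labels_match_hand_loop(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 2, 40)
        p = rng.integers(0, 2, 40)
        cm = confusion(t, p)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == bruteforce_confusion(t, p)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.integers(0, 2, 30)
        p = rng.integers(0, 2, 30)
        perm = rng.permutation(30)
        cm1, cm2 = confusion(t, p), confusion(t[perm], p[perm])
        assert (cm1.tp, cm1.fn, cm1.fp, cm1.tn) == \
            (cm2.tp, cm2.fn, cm2.fp, cm2.tn)

    def test_length_mismatch(self):
        with pytest.raises(SchemaError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_published_validation_counts(self):
        """The bvFTD-vs-PPD confusion counts implied by the cohort sizes
        (14 and 36) and printed rates must reproduce the printed
        sensitivity/specificity/accuracy and likelihood ratio."""
        rep = classification_metrics(ConfusionMatrix(tp=10, fn=4, fp=4,
                                                     tn=32))
        assert round(rep.sensitivity * 100) == 71
        assert round(rep.specificity * 100) == 89
        assert round(rep.accuracy * 100) == 84
        assert rep.lr_pos == pytest.approx(6.43, abs=0.005)
        assert round(rep.fn_rate * 100) == 29
        assert round(rep.fp_rate * 100) == 11
        # the printed negative likelihood ratio (0.31) is a rounding
        # ambiguity: these counts give 0.32
        assert rep.lr_neg == pytest.approx(0.3214, abs=0.0005)

    def test_perfect_classifier_flags_infinite_lr(self):
        rep = classification_metrics(ConfusionMatrix(10, 0, 0, 10))
        assert rep.sensitivity == rep.specificity == rep.accuracy == 1.0
        assert math.isinf(rep.lr_pos) and rep.lr_pos_infinite

    def test_zero_sensitivity(self):
        rep = classification_metrics(ConfusionMatrix(0, 10, 0, 10))
        assert rep.sensitivity == 0.0
        assert rep.lr_neg == pytest.approx(1.0 / rep.specificity)

    def test_accuracy_identity_and_rate_complement(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            tp, fn, fp, tn = rng.integers(1, 30, 4)
            rep = classification_metrics(ConfusionMatrix(tp, fn, fp, tn))
            assert rep.accuracy == pytest.approx(
                (tp + tn) / (tp + fn + fp + tn))
            assert rep.fn_rate + rep.sensitivity == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            classification_metrics(ConfusionMatrix(0, 0, 5, 5))

    def test_formatted_report_prints_integer_percentages(self):
        rep = classification_metrics(ConfusionMatrix(10, 4, 4, 32))
        text = rep.formatted()
        assert "71%" in text and "89%" in text and "84%" in text
        assert "6.43" in text


def _cube(shift=0):
    m = np.zeros((8, 8, 8), dtype=np.int32)
    m[2 + shift:4 + shift, 2:4, 2:4] = 1
    return LabelVolume(m, np.eye(4))


class TestDice:
    def test_identical_masks(self):
        assert dice(_cube(), _cube()) == 1.0

    def test_disjoint_masks(self):
        assert dice(_cube(), _cube(4)) == 0.0

    def test_shifted_cube_half_overlap(self):
        assert dice(_cube(), _cube(1)) == pytest.approx(0.5)

    def test_symmetric(self):
        a, b = _cube(), _cube(1)
        assert dice(a, b) == dice(b, a)

    def test_both_empty_defined_as_one(self):
        e = LabelVolume(np.zeros((8, 8, 8), dtype=np.int32), np.eye(4))
        assert dice(e, e) == 1.0

    def test_grid_mismatch(self):
        e = LabelVolume(np.zeros((9, 9, 9), dtype=np.int32), np.eye(4))
        with pytest.raises(GeometryError):
            dice(_cube(), e)


class TestVolumeCorrelation:
    def test_proportional_is_one(self):
        a = [10.0, 20.0, 30.0, 40.0]
        assert volume_correlation(a, [2 * v for v in a]) == \
            pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        a = [10.0, 20.0, 30.0]
        assert volume_correlation(a, [-v for v in a]) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        a = np.array([12.0, 9.0, 30.0, 22.0, 17.0])
        b = np.array([14.0, 11.0, 27.0, 25.0, 15.0])
        r = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        assert volume_correlation(a, b) == pytest.approx(r)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedMetricError):
            volume_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGroupCompare:
    def test_identical_samples(self):
        t, p, pb = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_bonferroni_cap(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.1, 1, 20)
        _, p, pb = group_compare(a, b, n_comparisons=5)
        assert pb == min(1.0, 5 * p)
        _, p2, pb2 = group_compare(a, a + 0.001, n_comparisons=1000)
        assert pb2 == 1.0

    def test_bonferroni_never_below_raw(self):
        rng = np.random.default_rng(1)
        for m in (1, 3, 10):
            a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
            _, p, pb = group_compare(a, b, n_comparisons=m)
            assert pb >= p

    def test_power_at_reported_apr_contrast(self):
        """Two normal samples at the reported APR separation (1.26 vs
        0.97, sd 0.3, n = 30/group) must reach p < 0.05 in at least 80%
        of 100 seeded replicates."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.normal(1.26, 0.3, 30)
            b = rng.normal(0.97, 0.3, 30)
            _, p, _ = group_compare(a, b)
            if p < 0.05:
                hits += 1
        assert hits >= 80

    def test_degenerate_equal_constants_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t, p, pb = group_compare([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0


class TestMisclassificationReport:
    def _table(self, rng, n=40):
        age = np.r_[rng.normal(63, 8, n // 2), rng.normal(69, 10, n // 2)]
        apr = np.r_[rng.normal(1.3, 0.2, n // 2),
                    rng.normal(1.0, 0.2, n // 2)]
        return pd.DataFrame({"age": age, "apr": apr})

    def test_all_correct_predictions_yield_empty_report(self):
        rng = np.random.default_rng(0)
        df = self._table(rng)
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        with pytest.warns(UserWarning, match="skipped"):
            rep = misclassification_report(df, y, y)
        assert len(rep) == 0

    def test_directional_contrast_recovered(self):
        """When false negatives are generated older and with smaller APR
        than true positives, the report must show those directions."""
        rng = np.random.default_rng(1)
        n_tp, n_fn = 25, 15
        df = pd.DataFrame({
            "age": np.r_[rng.normal(63, 4, n_tp), rng.normal(72, 3, n_fn),
                         rng.normal(69, 5, 30)],
            "apr": np.r_[rng.normal(1.35, 0.1, n_tp),
                         rng.normal(1.0, 0.1, n_fn),
                         rng.normal(1.0, 0.15, 30)],
        })
        y = np.r_[np.ones(n_tp + n_fn, int), np.zeros(30, int)]
        pred = np.r_[np.ones(n_tp, int), np.zeros(n_fn, int),
                     np.zeros(30, int)]
        rep = misclassification_report(df, y, pred)
        tpfn = rep[rep.stratum == "TP_vs_FN"].set_index("feature")
        assert tpfn.loc["age", "mean_b"] > tpfn.loc["age", "mean_a"]
        assert tpfn.loc["apr", "mean_b"] < tpfn.loc["apr", "mean_a"]

    def test_stratum_sizes_match_confusion_counts(self):
        rng = np.random.default_rng(2)
        df = self._table(rng)
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        pred = y.copy()
        pred[:5] = 0   # 5 FN
        pred[20:28] = 1  # 8 FP
        cm = confusion(y, pred)
        rep = misclassification_report(df, y, pred)
        tpfn = rep[rep.stratum == "TP_vs_FN"].iloc[0]
        fptn = rep[rep.stratum == "FP_vs_TN"].iloc[0]
        assert tpfn.n_a == cm.tp and tpfn.n_b == cm.fn
        assert fptn.n_a == cm.fp and fptn.n_b == cm.tn
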