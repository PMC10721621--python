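"""Quantification and evaluation statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mam.quantify import (
    ConfusionCounts,
    PredictionResult,
    binarize_clips,
    classification_metrics,
    classify_fms_category,
    classify_group_by_frequency,
    cohort_balance_tests,
    concordance_kappa,
    fms_frequency,
    rank_clips_for_review,
    roc_auc,
    youden_threshold,
)


class TestBinarizeAndFrequency:
    def test_tie_at_half_counts_as_fms(self):
        np.testing.assert_array_equal(binarize_clips([0.5, 0.49]), [1, 0])

    def test_frequency_counts_proportion(self):
        calls = [1, 0, 0, 1, 1, 0, 0, 0, 1, 0]
        assert fms_frequency(calls) == pytest.approx(0.4)
        assert fms_frequency([1, 1]) == 1.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=30, deadline=None)
    def test_matches_elementwise_counting_oracle(self, alphas):
        calls = binarize_clips(alphas)
        assert fms_frequency(calls) == sum(a >= 0.5 for a in alphas) / len(alphas)

    def test_frequency_monotone_in_alphas(self, rng):
        alphas = rng.uniform(0, 1, 20)
        f0 = fms_frequency(binarize_clips(alphas))
        f1 = fms_frequency(binarize_clips(np.minimum(alphas + 0.2, 1.0)))
        assert f1 >= f0

    def test_alpha_range_validated(self):
        with pytest.raises(ValueError):
            binarize_clips([1.2])


class TestGroupAndCategoryCalls:
    def test_reported_group_medians_separate(self):
        # the published group medians fall on either side of any threshold
        # calibrated between them
        assert classify_group_by_frequency(0.553, 0.3) == "normal"
        assert classify_group_by_frequency(0.135, 0.3) == "risk"

    def test_reported_category_medians_separate_at_0603(self):
        assert classify_fms_category(0.738) == "continuous"
        assert classify_fms_category(0.455) == "intermittent"
        assert classify_fms_category(0.603) == "continuous"  # documented tie rule

    def test_youden_threshold_recovers_separation(self, rng):
        scores = np.concatenate([rng.uniform(0.6, 1.0, 30), rng.uniform(0.0, 0.4, 30)])
        labels = np.array([1] * 30 + [0] * 30)
        thr = youden_threshold(scores, labels)
        assert 0.4 < thr < 0.6
        # sweep agreement with a counting ROC oracle: J is maximal
        best = max(
            ((scores >= c) & (labels == 1)).sum() / 30
            + ((scores < c) & (labels == 0)).sum() / 30
            - 1
            for c in np.linspace(0, 1, 201)
        )
        pred = scores >= thr
        j = (pred & (labels == 1)).sum() / 30 + (~pred & (labels == 0)).sum() / 30 - 1
        assert j == pytest.approx(best, abs=1e-9)


class TestKappa:
    def test_perfect_agreement_is_one(self):
        assert concordance_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0

    def test_toy_table_hand_value(self):
        # 2x2 table a=4, b=1, c=1, d=4: p_o=0.8, p_e=0.5 -> kappa 0.6
        a = [1] * 4 + [1] + [0] + [0] * 4
        b = [1] * 4 + [0] + [1] + [0] * 4
        assert concordance_kappa(a, b) == pytest.approx(0.6)

    def test_chance_level_near_zero(self, rng):
        a = rng.integers(0, 2, 4000)
        b = rng.integers(0, 2, 4000)
        assert abs(concordance_kappa(a, b)) < 0.05

    def test_symmetric_in_raters(self, rng):
        a = rng.integers(0, 2, 50)
        b = rng.integers(0, 2, 50)
        assert concordance_kappa(a, b) == pytest.approx(concordance_kappa(b, a))

    def test_undefined_when_marginals_degenerate(self):
        assert math.isnan(concordance_kappa([1, 1, 1], [1, 1, 1]))

    def test_matches_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.metrics")
        for _ in range(5):
            a = rng.integers(0, 2, 30)
            b = rng.integers(0, 2, 30)
            if len(set(a.tolist() + b.tolist())) < 2:
                continue
            assert concordance_kappa(a, b) == pytest.approx(
                sklearn.cohen_kappa_score(a, b), abs=1e-12
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            concordance_kappa([1, 0], [1, 0, 1])


class TestClassificationMetrics:
    def test_toy_confusion_table(self):
        m = classification_metrics(ConfusionCounts(tp=3, fn=1, tn=5, fp=1))
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)
        assert m["ppv"] == pytest.approx(0.75)
        assert m["npv"] == pytest.approx(5 / 6)

    def test_undefined_marker_on_zero_denominator(self):
        m = classification_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=1))
        assert math.isnan(m["sensitivity"])

    @given(st.tuples(*[st.integers(0, 50)] * 4))
    @settings(max_examples=50, deadline=None)
    def test_accuracy_identity(self, counts):
        tp, fn, tn, fp = counts
        if tp + fn + tn + fp == 0:
            return
        m = classification_metrics(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp))
        p, n = tp + fn, tn + fp
        if p > 0 and n > 0:
            assert m["accuracy"] == pytest.approx(
                (m["sensitivity"] * p + m["specificity"] * n) / (p + n)
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fn=0, tn=1, fp=0)


class TestROC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        scores = rng.normal(size=40)
        scores[rng.integers(0, 40, 10)] = 0.0  # inject ties
        labels = rng.integers(0, 2, 40)
        if labels.sum() in (0, 40):
            labels[:2] = [0, 1]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc_auc(scores, labels) == pytest.approx(
            wins / (len(pos) * len(neg)), rel=1e-12
        )

    def test_score_negation_complements_auc(self, rng):
        scores = rng.normal(size=30)
        labels = np.array([1] * 10 + [0] * 20)
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_bootstrap_ci_brackets_point(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 40)])
        labels = np.array([1] * 40 + [0] * 40)
        point, (lo, hi) = roc_auc(scores, labels, ci=True, n_boot=200, seed=1)
        assert lo <= point <= hi
        assert 0.5 < point < 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])


class TestRankClips:
    def make_result(self, alphas):
        alphas = np.asarray(alphas, dtype=float)
        starts = np.arange(len(alphas)) * 150
        return PredictionResult(
            subject_id="s",
            start_frames=starts,
            alphas=alphas,
            fps=25.0,
            T=240,
            fms_frequency=float((alphas >= 0.5).mean()),
        )

    def test_top1_is_argmax(self):
        res = self.make_result([0.1, 0.9, 0.5])
        top = rank_clips_for_review(res, 1)
        assert top[0]["alpha"] == 0.9
        assert top[0]["start_s"] == 150 / 25.0
        assert top[0]["end_s"] == (150 + 240) / 25.0

    def test_k_larger_than_n_returns_all_sorted(self):
        res = self.make_result([0.3, 0.6, 0.2])
        top = rank_clips_for_review(res, 10)
        assert [c["alpha"] for c in top] == [0.6, 0.3, 0.2]

    def test_stable_tie_break_by_start(self):
        res = self.make_result([0.5, 0.7, 0.5])
        top = rank_clips_for_review(res, 3)
        assert [c["start_s"] for c in top] == [6.0, 0.0, 12.0]


class TestCohortBalance:
    def test_internal_sex_table_p_value(self):
        out = cohort_balance_tests(table=[[353, 338], [114, 101]])
        assert out["p"] == pytest.approx(0.676, abs=1e-3)

    def test_external_sex_table_p_value(self):
        out = cohort_balance_tests(table=[[87, 86], [27, 21]])
        assert out["p"] == pytest.approx(0.570, abs=1e-3)

    def test_uniform_table_not_significant(self):
        out = cohort_balance_tests(table=[[50, 50], [50, 50]])
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_normal_samples_use_t_test(self, rng):
        a = rng.normal(0, 1, 60)
        b = rng.normal(0.1, 1, 60)
        assert cohort_balance_tests(sample_a=a, sample_b=b)["test"] == "t-test"

    def test_skewed_samples_use_mann_whitney(self, rng):
        a = rng.exponential(1, 80)
        b = rng.exponential(1.2, 80)
        assert (
            cohort_balance_tests(sample_a=a, sample_b=b)["test"] == "Mann-Whitney"
        )

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            cohort_balance_tests(table=[[0, 0], [0, 0]])
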