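"""Metric formulas, ranking areas, and resampling protocols."""

import math

import numpy as np
import pytest

from profgram.classify import ClassifierSpec
from profgram.evaluate import (
    ConfusionCounts,
    Protocol,
    confusion,
    jackknife,
    kfold_cv,
    metrics,
    pr_auc,
    roc_auc,
)
from profgram.exceptions import InvalidInputError, UndefinedMetricError
from profgram.features import FeatureGroup, LabeledDataset
from profgram.synthetic import SyntheticConfig, generate_dataset


def concordance_oracle(scores, labels) -> float:
    """Brute-force auROC: concordant pos/neg pairs + half the ties, over all pairs."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for s_p in pos:
        for s_n in neg:
            if s_p > s_n:
                total += 1.0
            elif s_p == s_n:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestConfusion:
    @pytest.mark.parametrize(
        "labels,preds,expected",
        [
            ([1, 1, 0, 0], [1, 1, 0, 0], (2, 2, 0, 0)),
            ([1, 0], [0, 1], (0, 0, 1, 1)),
            ([1, 1, 1, 0], [1, 0, 1, 1], (2, 0, 1, 1)),
        ],
    )
    def test_small_tallies(self, labels, preds, expected):
        cc = confusion(labels, preds)
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == expected
        assert cc.total == len(labels)

    def test_matches_elementwise_tally_oracle(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 100)
        p = rng.integers(0, 2, 100)
        cc = confusion(y, p)
        tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
        tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
        fp = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
        fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (tp, tn, fp, fn)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_perfect_classifier(self):
        b = metrics(ConfusionCounts(50, 50, 0, 0))
        assert (b.accuracy, b.sensitivity, b.specificity, b.mcc) == (1, 1, 1, 1)
        assert not b.degenerate

    def test_perfectly_wrong_classifier(self):
        b = metrics(ConfusionCounts(0, 0, 50, 50))
        assert b.accuracy == 0 and b.mcc == -1

    def test_hand_evaluated_counts(self):
        # TP=80, TN=70, FP=30, FN=20: direct evaluation of the four formulas
        b = metrics(ConfusionCounts(80, 70, 30, 20))
        assert b.accuracy == pytest.approx(150 / 200)
        assert b.sensitivity == pytest.approx(80 / 100)
        assert b.specificity == pytest.approx(70 / 100)
        expected_mcc = (80 * 70 - 30 * 20) / math.sqrt(110 * 100 * 100 * 90)
        assert b.mcc == pytest.approx(expected_mcc, rel=1e-12)

    def test_zero_denominator_flagged(self):
        b = metrics(ConfusionCounts(0, 5, 0, 0))  # no positives at all
        assert b.sensitivity == 0.0 and b.mcc == 0.0 and b.degenerate

    def test_mcc_bounds_and_swap_invariance_on_random_counts(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(0, 50, 4)
            if tp + tn + fp + fn == 0:
                continue
            b = metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert -1.0 <= b.mcc <= 1.0
            swapped = metrics(ConfusionCounts(int(tn), int(tp), int(fn), int(fp)))
            assert b.mcc == pytest.approx(swapped.mcc, abs=1e-12)
            # accuracy decomposes over the class-conditional rates
            P, N = tp + fn, tn + fp
            if P and N:
                assert b.accuracy == pytest.approx(
                    (b.sensitivity * P + b.specificity * N) / (P + N)
                )

    def test_all_zero_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            metrics(ConfusionCounts(0, 0, 0, 0))


class TestRankingMetrics:
    def test_perfect_ranking(self):
        labels = [1, 1, 0, 0]
        assert roc_auc(labels, labels) == 1.0
        assert pr_auc(labels, labels) == 1.0

    def test_all_equal_scores_give_half(self):
        assert roc_auc([0.3] * 10, [1, 0] * 5) == pytest.approx(0.5)

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=200)
        scores[::7] = scores[0]  # inject ties
        labels = rng.integers(0, 2, 200)
        assert roc_auc(scores, labels) == pytest.approx(
            concordance_oracle(scores, labels), abs=1e-12
        )

    def test_score_negation_flips_auc(self):
        rng = np.random.default_rng(23)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        assert roc_auc(scores, labels) == pytest.approx(1 - roc_auc(-scores, labels))

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.2], [1, 1])


def toy_dataset(n=12, seed=0) -> LabeledDataset:
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 0], n // 2)
    X = rng.normal(size=(n, 20)) + 3.0 * y[:, None]
    return LabeledDataset([f"t{i}" for i in range(n)], X, y, FeatureGroup.MONOGRAM, "HMM")


class TestKFold:
    def test_every_instance_tested_exactly_once(self):
        ds = toy_dataset(n=4)
        report = kfold_cv(ds, ClassifierSpec(), k=2, seed=0)
        assert sorted(report.fold_assignments) == sorted(ds.instance_ids)
        assert report.pooled_counts.total == ds.n

    def test_same_seed_same_folds(self):
        ds = toy_dataset(n=20, seed=1)
        r1 = kfold_cv(ds, ClassifierSpec(), k=5, seed=7)
        r2 = kfold_cv(ds, ClassifierSpec(), k=5, seed=7)
        assert r1.fold_assignments == r2.fold_assignments
        assert r1.aggregate == r2.aggregate

    def test_stratification_and_k_bounds(self):
        ds = toy_dataset(n=8)
        with pytest.raises(InvalidInputError):
            kfold_cv(ds, ClassifierSpec(), k=5, seed=0)  # k > class size

    def test_pooled_counts_equal_fold_sum(self, separable_dataset):
        report = kfold_cv(separable_dataset, ClassifierSpec(), k=5, seed=1)
        assert report.pooled_counts.total == separable_dataset.n
        assert report.protocol is Protocol.KFOLD
        assert len(report.per_fold) == 5

    def test_signal_recovery_on_separable_synthetic_data(self, separable_dataset):
        report = kfold_cv(separable_dataset, ClassifierSpec(), k=5, seed=1)
        assert report.aggregate.accuracy >= 0.90


class TestJackknife:
    def test_three_instance_protocol(self):
        ds = toy_dataset(n=4)
        report = jackknife(ds, ClassifierSpec())
        assert len(report.per_fold) == ds.n
        assert sorted(report.fold_assignments.values()) == list(range(ds.n))

    def test_matches_manual_leave_one_out(self):
        """Pooled jack-knife predictions equal an explicit per-instance loop."""
        from profgram import classify

        ds = toy_dataset(n=10, seed=3)
        report = jackknife(ds, ClassifierSpec())
        manual = {}
        for i in range(ds.n):
            keep = [j for j in range(ds.n) if j != i]
            sub = LabeledDataset(
                [ds.instance_ids[j] for j in keep],
                ds.features[keep],
                ds.labels[keep],
                ds.feature_group,
                ds.origin,
            )
            model = classify.train(sub, ClassifierSpec())
            manual[ds.instance_ids[i]] = classify.predict(
                model, _single(ds, i)
            )[0].label
        pooled_acc = np.mean(
            [manual[i] == y for i, y in zip(ds.instance_ids, ds.labels)]
        )
        assert report.aggregate.accuracy == pytest.approx(pooled_acc)

    def test_small_n_rejected(self):
        ds = toy_dataset(n=4)
        ds2 = LabeledDataset(ds.instance_ids[:2], ds.features[:2], ds.labels[:2],
                             ds.feature_group, ds.origin)
        with pytest.raises(InvalidInputError):
            jackknife(ds2, ClassifierSpec())

    def test_recovery_on_separable_synthetic_data(self):
        ds = generate_dataset(SyntheticConfig(n_pos=30, n_neg=30, effect=0.8, seed=1))
        report = jackknife(ds, ClassifierSpec())
        assert report.aggregate.accuracy >= 0.90
        assert report.pooled_counts.total == 60


def _single(ds: LabeledDataset, i: int) -> LabeledDataset:
    return LabeledDataset(
        [ds.instance_ids[i]], ds.features[i : i + 1], ds.labels[i : i + 1],
        ds.feature_group, ds.origin,
    )
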