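"""Evaluation protocol: stratified CV, LOSO, confusion matrices, t-tests."""

import numpy as np
import pytest

from gaitpress.evaluate import (
    compare_folds,
    confusion_matrix,
    evaluate_pipeline,
    loso_evaluate,
    stratified_kfold,
)


class TestStratifiedKFold:
    def test_forty_balanced_samples_deal_one_per_class_per_fold(self):
        labels = np.repeat(["n", "i", "o", "f"], 10)
        fa = stratified_kfold(labels, k=10, seed=0)
        for f in range(10):
            sel = labels[fa.fold == f]
            assert sel.size == 4
            assert set(sel) == {"n", "i", "o", "f"}

    def test_proportions_within_one_sample_per_class(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["a", "b", "c"], p=[0.5, 0.3, 0.2], size=300)
        fa = stratified_kfold(labels, k=10, seed=1)
        for c in "abc":
            per_fold = [np.sum(labels[fa.fold == f] == c) for f in range(10)]
            assert max(per_fold) - min(per_fold) <= 1

    def test_k_of_one_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.repeat(["a", "b"], 10), k=1)

    def test_class_smaller_than_k_rejected(self):
        labels = np.array(["a"] * 20 + ["b"] * 5)
        with pytest.raises(ValueError):
            stratified_kfold(labels, k=10)

    def test_same_seed_identical(self):
        labels = np.repeat(["a", "b"], 30)
        a = stratified_kfold(labels, 10, seed=4)
        b = stratified_kfold(labels, 10, seed=4)
        assert np.array_equal(a.fold, b.fold)


class TestConfusionMatrix:
    ORDER = ("normal", "toe_in", "toe_out", "flat")

    def test_perfect_predictions_are_diagonal(self):
        y = np.array(["normal", "toe_in", "toe_out", "flat"] * 5)
        cm = confusion_matrix(y, y, self.ORDER)
        assert np.all(cm.counts == 5 * np.eye(4))

    def test_total_equals_sample_count(self, rng):
        a = rng.choice(self.ORDER, 100)
        p = rng.choice(self.ORDER, 100)
        assert confusion_matrix(a, p, self.ORDER).counts.sum() == 100

    def test_matches_pairwise_tally_oracle(self, rng):
        a = rng.choice(self.ORDER, 200)
        p = rng.choice(self.ORDER, 200)
        cm = confusion_matrix(a, p, self.ORDER).counts
        for i, ci in enumerate(self.ORDER):
            for j, cj in enumerate(self.ORDER):
                assert cm[i, j] == np.sum((a == ci) & (p == cj))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["normal"], ["limp"], self.ORDER)


def blobs_xy(rng, n=30, sep=6.0):
    order = ("normal", "toe_in", "toe_out", "flat")
    means = sep * np.eye(4)[:, :3]
    X = np.vstack([rng.normal(m, 0.5, (n, 3)) for m in means])
    y = np.repeat(order, n)
    return X, y


class TestEvaluatePipeline:
    def test_separable_data_perfect_diagonal_confusion(self, rng):
        X, y = blobs_xy(rng)
        res = evaluate_pipeline(None, ("svmlin", {}), X, y, k=5, seed=0,
                                batch_size=20)
        assert res.overall_accuracy_pct == 100.0
        assert np.all(res.confusion == np.diag(np.diag(res.confusion)))
        assert np.allclose(res.per_class_recall, 1.0)
        assert res.macro_precision_pct == 100.0

    def test_random_labels_near_chance(self, rng):
        X, _ = blobs_xy(rng, n=50)
        y = rng.choice(["normal", "toe_in", "toe_out", "flat"], size=len(X))
        res = evaluate_pipeline(None, ("svmlin", {}), X, y, k=5, seed=0,
                                batch_size=20)
        assert abs(res.overall_accuracy_pct - 25.0) < 10.0

    def test_confusion_row_sums_match_class_counts(self, rng):
        X, y = blobs_xy(rng, n=20)
        res = evaluate_pipeline(("lda", {}), ("svmlin", {}), X, y, k=5, seed=0,
                                batch_size=10)
        # averaged confusion: grand total equals mean per-fold test size
        assert res.confusion.sum() == pytest.approx(len(y) / 5)
        assert np.allclose(res.confusion.sum(axis=1), 20 / 5)

    def test_metric_layout_follows_canonical_class_order(self, rng):
        X, y = blobs_xy(rng, n=20)
        res = evaluate_pipeline(None, ("svmlin", {}), X, y, k=5, seed=0,
                                batch_size=10)
        assert res.class_order == ("normal", "toe_in", "toe_out", "flat")
        assert res.per_class_recall.shape == (4,)
        row = res.table_row("LDA + SVMlin")
        assert set(row) == {"Algorithm", "Recall", "Average precision (%)",
                            "Time cost (ms)"}

    def test_deterministic_under_seed(self, rng):
        X, y = blobs_xy(rng, n=20)
        a = evaluate_pipeline(("lda", {}), ("svmlin", {}), X, y, k=5, seed=3,
                              batch_size=10)
        b = evaluate_pipeline(("lda", {}), ("svmlin", {}), X, y, k=5, seed=3,
                              batch_size=10)
        assert np.array_equal(a.fold_accuracies, b.fold_accuracies)
        assert np.array_equal(a.confusion, b.confusion)

    def test_recall_precision_agree_with_direct_formulas(self, rng):
        from gaitpress.evaluate import _recall_precision

        a = rng.choice(["normal", "toe_in", "toe_out", "flat"], 150)
        p = rng.choice(["normal", "toe_in", "toe_out", "flat"], 150)
        cm = confusion_matrix(a, p).counts
        recall, precision = _recall_precision(cm)
        order = ("normal", "toe_in", "toe_out", "flat")
        for i, c in enumerate(order):
            tp = np.sum((a == c) & (p == c))
            assert recall[i] == pytest.approx(tp / np.sum(a == c))
            denom = np.sum(p == c)
            if denom:
                assert precision[i] == pytest.approx(tp / denom)


class TestLOSO:
    def test_identical_subjects_reach_perfect_accuracy(self, rng):
        X, y = blobs_xy(rng, n=20)
        subjects = np.tile(np.repeat(["s1", "s2"], 10), 4)
        per_subject, mean_acc, _ = loso_evaluate(None, ("svmlin", {}), X, y, subjects)
        assert len(per_subject) == 2
        assert mean_acc == 1.0

    def test_subject_confounded_data_drops_to_chance(self, rng):
        # each subject occupies its own disjoint feature support, so a model
        # trained on other subjects generalizes at chance level
        n, order = 15, ("normal", "toe_in", "toe_out", "flat")
        offsets = 3.0 * np.eye(5)[:4]
        X, y, subjects = [], [], []
        for s in range(8):
            center = np.array([30.0 * s, 0.0, 0.0, 0.0, 0.0])
            # the offset -> class mapping is rotated per subject, so the
            # geometry that predicts the label never transfers across subjects
            for k, c in enumerate(order):
                X.append(rng.normal(center + offsets[(k + s) % 4], 0.3, (n, 5)))
                y += [c] * n
                subjects += [f"s{s}"] * n
        X = np.vstack(X)
        y, subjects = np.array(y), np.array(subjects)
        # RBF kernel at the blob scale so the model *can* memorize the
        # per-subject geometry
        spec = ("svmrbf", {"gamma": 1.0})
        _, loso_acc, _ = loso_evaluate(None, spec, X, y, subjects)
        res_within = evaluate_pipeline(None, spec, X, y, k=5, seed=0,
                                       batch_size=10)
        assert res_within.overall_accuracy_pct > 90.0
        assert loso_acc < 0.5

    def test_single_subject_rejected(self, rng):
        X, y = blobs_xy(rng, n=5)
        with pytest.raises(ValueError):
            loso_evaluate(None, ("svmlin", {}), X, y, np.repeat("s1", len(y)))

    def test_round_skipped_with_warning_when_class_missing(self, rng):
        X, y = blobs_xy(rng, n=6)
        # "holder" carries the whole flat class; its round must be skipped,
        # while the r1/r2 rounds still see every class in training
        subjects = np.where(
            y == "flat", "holder", np.where(np.arange(len(y)) % 2 == 0, "r1", "r2")
        )
        with pytest.warns(UserWarning, match="skipped"):
            per_subject, _, _ = loso_evaluate(None, ("svmlin", {}), X, y, subjects)
        assert "holder" not in per_subject
        assert {"r1", "r2"} <= set(per_subject)


class TestCompareFolds:
    def test_identical_groups_give_t0_p1(self):
        res = compare_folds([0.9] * 5, [0.9] * 5)
        assert res.t == 0.0 and res.p == 1.0

    def test_separated_groups_highly_significant(self, rng):
        a = rng.normal(0.9, 0.01, 10)
        b = rng.normal(0.5, 0.01, 10)
        res = compare_folds(a, b)
        assert res.p < 0.001
        assert res.mean_a > res.mean_b

    def test_pooled_formulation_matches_hand_computed_example(self):
        # groups (1,2,3) vs (2,4,6): pooled t = -1.1339 (textbook arithmetic)
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        res = compare_folds(a, b, equal_var=True)
        sp2 = (2 * 1.0 + 2 * 4.0) / 4  # pooled variance
        expect_t = (2.0 - 4.0) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert res.t == pytest.approx(expect_t, rel=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            compare_folds([0.9], [0.8, 0.7])
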