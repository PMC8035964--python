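import numpy as np
import pytest
from sklearn.metrics import (
    f1_score,
    hamming_loss as sk_hamming,
    label_ranking_loss,
    roc_auc_score,
)

from bacloc.datatypes import GRAM_NEGATIVE, GRAM_POSITIVE
from bacloc.metrics import (
    example_metrics,
    hamming_loss_from_counts,
    kfold_split,
    label_metrics,
    label_metrics_from_counts,
    location_confusion,
    metrics_table,
    rank_loss,
    roc_auc,
)

from oracles import (
    mann_whitney_auc,
    naive_example_metrics,
    naive_label_metrics,
    naive_rank_loss,
)


def _random_case(rng, n=20, q=5):
    Y = (rng.random((n, q)) < 0.35).astype(int)
    Y[Y.sum(axis=1) == 0, rng.integers(0, q)] = 1
    P = (rng.random((n, q)) < 0.35).astype(int)
    S = rng.random((n, q))
    return Y, P, S


class TestExampleMetrics:
    def test_perfect_prediction(self):
        Y = np.array([[1, 0, 1], [0, 1, 0]])
        m = example_metrics(Y, Y)
        for key in ("accuracy_score", "precision", "recall", "f1", "subset_accuracy"):
            assert m[key] == 1.0
        assert m["hamming_loss"] == 0.0

    def test_hand_computed_two_instance_case(self):
        Y = np.array([[1, 0], [0, 1]])
        P = np.array([[1, 1], [0, 1]])
        m = example_metrics(Y, P)
        assert m["hamming_loss"] == pytest.approx(0.25)
        assert m["accuracy_score"] == pytest.approx(0.75)
        assert m["subset_accuracy"] == pytest.approx(0.5)

    def test_empty_prediction_convention(self):
        Y = np.array([[1, 1, 0]])
        P = np.zeros((1, 3), dtype=int)
        m = example_metrics(Y, P)
        assert m["precision"] == 0.0
        assert m["accuracy_score"] == 0.0  # union falls back to the true set

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            example_metrics(np.ones((2, 3)), np.ones((3, 3)))

    def test_agrees_with_sklearn_hamming(self):
        rng = np.random.default_rng(0)
        Y, P, _ = _random_case(rng, 50, 6)
        assert example_metrics(Y, P)["hamming_loss"] == pytest.approx(sk_hamming(Y, P))


class TestRankLoss:
    def test_perfect_and_tied_orderings(self):
        assert rank_loss([[1, 0, 0]], [[0.9, 0.2, 0.4]]) == 0.0
        assert rank_loss([[1, 0]], [[0.5, 0.5]]) == 0.5

    def test_degenerate_instances_excluded_but_counted(self):
        value, excluded = rank_loss(
            [[1, 1], [1, 0]], [[0.2, 0.1], [0.9, 0.1]], return_excluded=True
        )
        assert excluded == 1
        assert value == 0.0

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(1)
        Y = (rng.random((50, 4)) < 0.4).astype(int)
        S = np.round(rng.random((50, 4)), 1)  # coarse scores force ties
        assert rank_loss(Y, S) == pytest.approx(naive_rank_loss(Y, S), abs=1e-14)

    def test_matches_sklearn_on_tie_free_scores(self):
        rng = np.random.default_rng(2)
        Y = (rng.random((40, 5)) < 0.4).astype(int)
        mask = (Y.sum(axis=1) > 0) & (Y.sum(axis=1) < 5)
        Y, S = Y[mask], rng.random((int(mask.sum()), 5))
        assert rank_loss(Y, S) == pytest.approx(label_ranking_loss(Y, S))


class TestLabelMetrics:
    def test_consensus_counts_reproduce_printed_micro_recall(self):
        # Gram-negative consensus per-location counts pooled over CV
        tp = np.array([4132, 1388, 315, 393, 250, 8])
        fn = np.array([20, 27, 31, 29, 22, 2])
        fp = np.array([157, 238, 29, 72, 39, 0])
        m = label_metrics_from_counts(tp, fp, fn)
        assert m["micro_recall"] == pytest.approx(6486 / 6617)
        assert round(m["micro_recall"], 3) == 0.980

    def test_gram_positive_counts_reproduce_printed_macro_precision(self):
        tp = np.array([323, 1768, 282, 13, 4])
        fp = np.array([30, 61, 101, 3, 0])
        fn = np.array([26, 11, 8, 21, 0])
        m = label_metrics_from_counts(tp, fp, fn)
        assert round(m["macro_precision"], 3) == 0.886

    def test_degenerate_label_contributes_zero_with_warning(self):
        Y = np.array([[1, 0], [1, 0]])
        with pytest.warns(UserWarning, match="zero denominator"):
            m = label_metrics(Y, Y)
        assert m["macro_recall"] == pytest.approx(0.5)  # (1 + 0) / 2

    def test_micro_f1_identity(self):
        rng = np.random.default_rng(3)
        Y, P, _ = _random_case(rng, 60, 6)
        tp = ((Y == 1) & (P == 1)).sum()
        fp = ((Y == 0) & (P == 1)).sum()
        fn = ((Y == 1) & (P == 0)).sum()
        m = label_metrics(Y, P)
        assert m["micro_f1"] == pytest.approx(2 * tp / (2 * tp + fp + fn), abs=1e-12)

    def test_agrees_with_sklearn_averaging(self):
        rng = np.random.default_rng(4)
        Y = (rng.random((80, 5)) < 0.5).astype(int)  # all labels well-populated
        P = (rng.random((80, 5)) < 0.5).astype(int)
        m = label_metrics(Y, P)
        assert m["micro_f1"] == pytest.approx(f1_score(Y, P, average="micro"))
        assert m["macro_f1_per_label"] == pytest.approx(f1_score(Y, P, average="macro"))


class TestLocationConfusion:
    def test_correct_is_tp_plus_tn(self):
        rng = np.random.default_rng(5)
        Y, P, _ = _random_case(rng, 40, 6)
        table = location_confusion(Y, P, GRAM_NEGATIVE)
        assert (table["Correct"] == table["TP"] + table["TN"]).all()
        assert (table["Wrong"] == table["FP"] + table["FN"]).all()

    def test_rows_partition_the_dataset(self):
        rng = np.random.default_rng(6)
        Y, P, _ = _random_case(rng, 33, 5)
        table = location_confusion(Y, P, GRAM_POSITIVE)
        assert (table[["TP", "FP", "FN", "TN"]].sum(axis=1) == 33).all()

    def test_matches_elementwise_tally(self):
        rng = np.random.default_rng(7)
        Y, P, _ = _random_case(rng, 25, 6)
        table = location_confusion(Y, P, GRAM_NEGATIVE)
        for j, code in enumerate(GRAM_NEGATIVE.codes):
            tp = sum(1 for a, b in zip(Y[:, j], P[:, j]) if a == 1 and b == 1)
            row = table.iloc[j]
            assert row["TP"] == tp

    def test_hamming_equals_pooled_confusion_identity(self):
        rng = np.random.default_rng(8)
        Y, P, _ = _random_case(rng, 70, 6)
        table = location_confusion(Y, P, GRAM_NEGATIVE)
        pooled = hamming_loss_from_counts(
            table["FP"].to_numpy(), table["FN"].to_numpy(), 70, 6
        )
        assert example_metrics(Y, P)["hamming_loss"] == pytest.approx(pooled, abs=1e-12)


class TestRocAuc:
    def test_perfect_and_uninformative_scores(self):
        Y = np.array([[1, 0], [0, 1], [1, 0]])
        perfect = np.where(Y == 1, 0.9, 0.1)
        value, _, _ = roc_auc(Y, perfect)
        assert value == 1.0
        constant = np.full_like(perfect, 0.5)
        value, _, _ = roc_auc(Y, constant)
        assert value == 0.5

    def test_matches_mann_whitney_u(self):
        rng = np.random.default_rng(9)
        Y = (rng.random((6, 5)) < 0.4).astype(int)
        Y[0, 0], Y[1, 1] = 1, 0  # both classes present after flattening
        S = rng.random((6, 5))
        value, _, _ = roc_auc(Y, S)
        assert value == pytest.approx(mann_whitney_auc(Y.ravel(), S.ravel()), abs=1e-12)
        assert value == pytest.approx(roc_auc_score(Y.ravel(), S.ravel()))

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            roc_auc(np.ones((3, 2), dtype=int), np.random.rand(3, 2))


class TestKFold:
    def test_balanced_partition(self):
        folds = kfold_split(10, k=5, seed=0)
        sizes = np.bincount(folds.fold_of)
        assert (sizes == 2).all()
        assert sorted(np.concatenate([np.flatnonzero(folds.fold_of == f) for f in range(5)])) == list(range(10))

    def test_sizes_differ_by_at_most_one(self):
        folds = kfold_split(23, k=5, seed=1)
        sizes = np.bincount(folds.fold_of)
        assert sizes.max() - sizes.min() <= 1

    def test_seed_reproducibility_and_sensitivity(self):
        base = kfold_split(40, k=5, seed=0).fold_of
        np.testing.assert_array_equal(base, kfold_split(40, k=5, seed=0).fold_of)
        assert any(
            not np.array_equal(base, kfold_split(40, k=5, seed=s).fold_of)
            for s in range(1, 11)
        )

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            kfold_split(3, k=5)


class TestBruteForceSweep:
    def test_all_metrics_match_oracles_on_random_cases(self):
        """Every metric agrees with a from-scratch loop implementation
        across 200 random (truth, prediction, scores) triples."""
        rng = np.random.default_rng(123)
        for case in range(200):
            n = int(rng.integers(2, 25))
            q = int(rng.integers(2, 7))
            Y, P, S = _random_case(rng, n, q)
            ours_ex = example_metrics(Y, P)
            ref_ex = naive_example_metrics(Y.tolist(), P.tolist())
            for key, value in ref_ex.items():
                assert ours_ex[key] == pytest.approx(value, abs=1e-12), key
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ours_lb = label_metrics(Y, P)
            ref_lb = naive_label_metrics(Y.tolist(), P.tolist())
            for key, value in ref_lb.items():
                assert ours_lb[key] == pytest.approx(value, abs=1e-12), key
            assert rank_loss(Y, S) == pytest.approx(
                naive_rank_loss(Y.tolist(), S.tolist()), abs=1e-12
            )

    def test_all_metrics_within_unit_interval(self):
        rng = np.random.default_rng(321)
        import warnings

        for _ in range(20):
            Y, P, S = _random_case(rng, 30, 6)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                values = {**example_metrics(Y, P), **label_metrics(Y, P)}
            values["rank_loss"] = rank_loss(Y, S)
            for key, value in values.items():
                assert 0.0 <= value <= 1.0, key
            assert values["subset_accuracy"] <= values["accuracy_score"] + 1e-12


class TestCvRun:
    def test_every_protein_predicted_exactly_once(self, small_cv_result, small_dataset):
        preds = small_cv_result.predictions["go_ppv"]
        assert preds.ids == small_dataset.labels.ids
        # pooled predictions are real (at least one non-trivial row per fold)
        assert preds.predicted.sum() > 0

    def test_pooled_hamming_matches_confusion_identity(self, small_cv_result, small_dataset):
        n, q = small_dataset.labels.n, small_dataset.labels.universe.q
        for name, report in small_cv_result.reports.items():
            table = small_cv_result.confusions[name]
            pooled = hamming_loss_from_counts(
                table["FP"].to_numpy(), table["FN"].to_numpy(), n, q
            )
            assert report.hamming_loss == pytest.approx(pooled, abs=1e-12)

    def test_consensus_recall_dominates_members(self, small_cv_result):
        reports = small_cv_result.reports
        assert reports["consensus_pssm_go"].recall >= reports["pssm"].recall
        assert reports["consensus_pssm_go"].recall >= reports["go_ppv"].recall

    def test_table_has_thirteen_columns_in_layout_order(self, small_cv_result):
        table = small_cv_result.table()
        assert list(table.columns) == [
            "accuracy_score", "precision", "recall", "f1", "subset_accuracy",
            "hamming_loss", "rank_loss", "macro_precision", "macro_recall",
            "macro_f1", "micro_precision", "micro_recall", "micro_f1",
        ]
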