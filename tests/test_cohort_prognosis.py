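"""Stage-1 operations: normalization, median binarization, CV classifier,
copula augmentation and Lasso feature ranking."""

import numpy as np
import pandas as pd
import pytest

from oncodisco.cohort_prognosis import (
    augment_with_gan,
    binarize_outcome,
    merge_gene_lists,
    normalize_expression,
    rank_features_lasso,
    train_outcome_classifier,
)
from oncodisco.errors import ArgumentError, DataError
from oncodisco.synthetic_data import generate_cohort
from oncodisco.types import ExpressionMatrix, GeneRanking


def small_matrix():
    return ExpressionMatrix(
        pd.DataFrame(
            {"s1": [2.0, 4.0], "s2": [4.0, 4.0]}, index=["REF", "T"]
        )
    )


class TestNormalize:
    def test_hand_arithmetic(self):
        norm = normalize_expression(small_matrix(), "REF")
        assert norm.values.loc["T"].tolist() == [2.0, 1.0]
        assert norm.values.loc["REF"].tolist() == [1.0, 1.0]
        assert norm.normalized_to == "REF"

    def test_idempotent(self):
        once = normalize_expression(small_matrix(), "REF")
        twice = normalize_expression(once, "REF")
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_errors_name_offending_samples(self):
        matrix = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0, 2.0], "s2": [0.0, 3.0]}, index=["REF", "T"])
        )
        with pytest.raises(DataError, match="s2"):
            normalize_expression(matrix, "REF")
        with pytest.raises(DataError, match="MISSING"):
            normalize_expression(matrix, "MISSING")


def clinical_from_times(times):
    n = len(times)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "os_time": times,
            "os_event": [1] * n,
            "pfi_time": times,
            "pfi_event": [1] * n,
        }
    )


class TestBinarize:
    def test_even_cohort_median_split(self):
        labels = binarize_outcome(clinical_from_times([1, 2, 3, 4]), "OS")
        assert labels.median_used == 2.5
        assert labels.labels.tolist() == [0, 0, 1, 1]

    def test_patient_at_median_below_by_default(self):
        labels = binarize_outcome(clinical_from_times([1, 2, 3]), "OS")
        assert labels.labels.loc["P1"] == 0

    def test_tie_rule_above(self):
        labels = binarize_outcome(clinical_from_times([1, 2, 3]), "OS", tie_rule="above")
        assert labels.labels.loc["P1"] == 1

    def test_identical_times_degenerate(self):
        with pytest.raises(DataError):
            binarize_outcome(clinical_from_times([5, 5, 5, 5]), "OS")

    def test_classes_partition_cohort(self):
        clinical = generate_cohort(200, 20, 0, 0.0, seed=1).clinical
        labels = binarize_outcome(clinical, "PFI")
        assert len(labels.labels) == 200
        assert set(labels.labels.unique()) == {0, 1}


class TestOutcomeClassifier:
    def test_fold_count_and_probability_contract(self):
        cohort = generate_cohort(150, 30, 5, 2.0, seed=2)
        labels = binarize_outcome(cohort.clinical, "OS")
        model, report = train_outcome_classifier(cohort.expression, labels, folds=5, seed=2)
        assert report.n_folds == 5
        assert report.mean_auc == pytest.approx(np.mean(report.fold_aucs))
        probs = model.predict_proba(
            np.log1p(cohort.expression.values.T.to_numpy())
        )[:, 1]
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_stratification_error_when_class_too_small(self):
        cohort = generate_cohort(30, 10, 0, 0.0, seed=3)
        labels = binarize_outcome(cohort.clinical, "OS")
        # shrink one class below the fold count
        keep = labels.labels[labels.labels == 0].index[:3].union(
            labels.labels[labels.labels == 1].index
        )
        labels.labels = labels.labels.loc[keep]
        from oncodisco.errors import StratificationError

        with pytest.raises(StratificationError):
            train_outcome_classifier(cohort.expression, labels, folds=5, seed=3)


class TestAugmentation:
    @staticmethod
    def _table(n=120, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 5))
        y = (X[:, 0] + rng.normal(scale=0.5, size=n) > 0).astype(int)
        table = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
        table["label"] = y
        return table

    def test_zero_synthetic_is_identity(self):
        table = self._table()
        pd.testing.assert_frame_equal(augment_with_gan(table, 0, seed=1), table)

    def test_row_counts_and_flags(self):
        table = self._table()
        aug = augment_with_gan(table, 500, seed=1)
        assert len(aug) == 620
        assert aug["synthetic"].sum() == 500
        assert (~aug["synthetic"]).sum() == 120

    def test_synthetic_values_within_observed_range(self):
        table = self._table()
        aug = augment_with_gan(table, 1000, seed=2)
        synth = aug[aug["synthetic"]]
        for col in [f"f{i}" for i in range(5)]:
            lo, hi = table[col].min(), table[col].max()
            span = hi - lo
            assert synth[col].min() >= lo - 0.1 * span
            assert synth[col].max() <= hi + 0.1 * span

    def test_marginal_means_close(self):
        table = self._table(n=300, seed=4)
        aug = augment_with_gan(table, 3000, seed=4)
        synth = aug[aug["synthetic"]]
        for col in [f"f{i}" for i in range(5)]:
            pooled_se = table[col].std() * np.sqrt(1 / len(table) + 1 / len(synth))
            assert abs(synth[col].mean() - table[col].mean()) < 3 * pooled_se

    def test_label_distribution_preserved_as_categorical(self):
        table = self._table()
        aug = augment_with_gan(table, 400, seed=5)
        assert set(aug["label"].unique()) <= set(table["label"].unique())
        real_rate = table["label"].mean()
        synth_rate = aug.loc[aug["synthetic"], "label"].mean()
        assert abs(real_rate - synth_rate) < 0.05

    def test_errors(self):
        with pytest.raises(ArgumentError):
            augment_with_gan(self._table(n=20), 100, seed=0)
        with pytest.raises(ArgumentError):
            augment_with_gan(self._table(), 100, seed=0, backend="ctgan")


class TestLassoRanking:
    def test_recovers_planted_genes(self):
        cohort = generate_cohort(800, 100, 8, 2.0, seed=6)
        labels = binarize_outcome(cohort.clinical, "OS")
        ranking = rank_features_lasso(cohort.expression, labels, seed=6)
        assert len(set(ranking.top(16)) & cohort.planted_prognostic_genes) >= 6

    def test_constant_gene_never_ranked(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        X["const"] = 1.0
        y = pd.Series((X["a"] > 0).astype(int), index=X.index)
        ranking = rank_features_lasso(X, y, seed=7)
        assert "const" not in ranking.genes

    def test_permuted_labels_rank_below_signal(self):
        cohort = generate_cohort(600, 60, 8, 2.0, seed=8)
        labels = binarize_outcome(cohort.clinical, "OS")
        signal = rank_features_lasso(cohort.expression, labels, seed=8)
        rng = np.random.default_rng(8)
        permuted = labels.labels.copy()
        permuted[:] = rng.permutation(permuted.to_numpy())
        null = rank_features_lasso(cohort.expression, permuted, seed=8)
        tenth_signal = signal.entries[9][1]
        max_null = null.entries[0][1] if null.entries else 0.0
        assert max_null < tenth_signal


class TestMergeGeneLists:
    @staticmethod
    def _ranking(pairs):
        return GeneRanking(entries=pairs, method="lasso")

    def test_identical_lists_idempotent(self):
        r = self._ranking([("A", 3.0), ("B", 2.0), ("C", 1.0)])
        assert merge_gene_lists(r, r, 3) == ["A", "B", "C"]

    def test_disjoint_lists_union_cardinality(self):
        r1 = self._ranking([("A", 3.0), ("B", 2.0), ("C", 1.0)])
        r2 = self._ranking([("D", 3.0), ("E", 2.0), ("F", 1.0)])
        assert len(merge_gene_lists(r1, r2, 3)) == 6

    def test_ordering_by_best_rank_then_importance(self):
        # A and C both have best rank 1; C's summed importance is larger
        os_rank = self._ranking([("A", 3.0), ("B", 2.0), ("C", 1.0)])
        pfi_rank = self._ranking([("C", 4.0), ("D", 1.0)])
        merged = merge_gene_lists(os_rank, pfi_rank, 3)
        assert len(merged) == 4
        assert merged == ["C", "A", "B", "D"]

    def test_top_k_restricts_candidates(self):
        r1 = self._ranking([("A", 3.0), ("B", 2.0), ("C", 1.0)])
        r2 = self._ranking([("D", 5.0), ("E", 2.0)])
        assert set(merge_gene_lists(r1, r2, 1)) == {"A", "D"}
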