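"""Unit and property tests for the Cq preprocessing pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirmoo.preprocess import (
    LONG,
    SHORT,
    ExpressionMatrix,
    PreprocessError,
    SampleLabels,
    candidate_filter,
    dichotomize_survival,
    differential_expression,
    filter_missing,
    fold_change,
    knn_impute,
    quantile_normalize,
    smote_oversample,
)


def _mat(values, prefix="m"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
    )


def _labels(classes):
    return SampleLabels([f"s{j}" for j in range(len(classes))], np.array(classes, dtype=object))


class TestFilterMissing:
    def test_strict_threshold_on_counts(self, rng):
        values = rng.normal(27, 1, (4, 10))
        for i, n_missing in enumerate([0, 4, 5, 6]):
            values[i, :n_missing] = np.nan
        kept = filter_missing(_mat(values), 0.5)
        assert kept.mirna_ids == ["m0", "m1", "m2"]
        assert kept.sample_ids == [f"s{j}" for j in range(10)]

    def test_complete_matrix_unchanged(self, tiny_matrix):
        out = filter_missing(tiny_matrix, 0.5)
        assert out.mirna_ids == tiny_matrix.mirna_ids
        np.testing.assert_array_equal(out.values, tiny_matrix.values)

    def test_matches_per_row_count_oracle_and_idempotent(self, rng):
        values = rng.normal(27, 1, (50, 20))
        values[rng.random((50, 20)) < 0.4] = np.nan
        values[np.isnan(values).all(axis=1), 0] = 27.0
        mat = _mat(values)
        out = filter_missing(mat, 0.5)
        expected = [
            mat.mirna_ids[i]
            for i in range(50)
            if sum(np.isnan(values[i, j]) for j in range(20)) <= 10
        ]
        assert out.mirna_ids == expected
        again = filter_missing(out, 0.5)
        assert again.mirna_ids == out.mirna_ids

    def test_empty_result_raises(self):
        values = np.full((2, 4), np.nan)
        values[:, 0] = 25.0
        with pytest.raises(PreprocessError, match="no miRNAs survive"):
            filter_missing(_mat(values), 0.1)


class TestQuantileNormalize:
    def test_identical_samples_are_a_fixed_point(self):
        col = np.array([25.0, 30.0, 22.0, 28.0])
        mat = _mat(np.column_stack([col, col, col]))
        out = quantile_normalize(mat)
        np.testing.assert_allclose(out.values, mat.values)

    def test_hand_computed_3x2_reference(self):
        # sorted cols: (1,3,5) and (2,4,8) -> reference (1.5, 3.5, 6.5)
        mat = _mat([[3.0, 8.0], [1.0, 4.0], [5.0, 2.0]])
        out = quantile_normalize(mat)
        np.testing.assert_allclose(out.values, [[3.5, 6.5], [1.5, 3.5], [6.5, 1.5]])

    def test_sorted_columns_identical_and_idempotent(self, rng):
        mat = _mat(rng.normal(27, 2, (30, 6)))
        out = quantile_normalize(mat)
        ref = np.sort(out.values[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref)
        twice = quantile_normalize(out)
        np.testing.assert_allclose(twice.values, out.values, atol=1e-12)

    def test_ranks_preserved_within_sample(self, rng):
        mat = _mat(rng.normal(27, 2, (20, 4)))
        out = quantile_normalize(mat)
        for j in range(4):
            assert (np.argsort(mat.values[:, j]) == np.argsort(out.values[:, j])).all()

    def test_missing_entries_stay_missing(self, rng):
        values = rng.normal(27, 2, (10, 5))
        values[2, 3] = np.nan
        out = quantile_normalize(_mat(values))
        assert np.isnan(out.values[2, 3])
        assert np.isnan(out.values).sum() == 1

    def test_single_sample_rejected(self):
        with pytest.raises(PreprocessError):
            quantile_normalize(_mat([[1.0], [2.0]]))


def _brute_knn_impute(values, k):
    """Independent KNNimpute oracle: overlap-scaled Euclidean row distances,
    unweighted mean of the k nearest donor rows observed at the column."""
    n, p = values.shape
    out = values.copy()
    for i in range(n):
        for j in range(p):
            if not np.isnan(values[i, j]):
                continue
            dists = []
            for t in range(n):
                if t == i or np.isnan(values[t, j]):
                    continue
                common = [c for c in range(p)
                          if not np.isnan(values[i, c]) and not np.isnan(values[t, c])]
                if not common:
                    continue
                sq = sum((values[i, c] - values[t, c]) ** 2 for c in common)
                dists.append((np.sqrt(sq * p / len(common)), t))
            dists.sort()
            donors = [t for _, t in dists[:k]]
            out[i, j] = np.mean([values[t, j] for t in donors])
    return out


class TestKnnImpute:
    def test_complete_matrix_identity(self, tiny_matrix):
        out = knn_impute(tiny_matrix, k=2)
        np.testing.assert_array_equal(out.values, tiny_matrix.values)

    def test_duplicate_row_is_the_nearest_neighbour(self):
        values = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, np.nan], [9.0, 9.0, 9.0]])
        out = knn_impute(_mat(values), k=1)
        assert out.values[1, 2] == 3.0

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n, p = rng.integers(3, 9), rng.integers(3, 7)
        values = rng.normal(27, 2, (n, p))
        mask = rng.random((n, p)) < 0.2
        for i in np.flatnonzero(mask.all(axis=1)):
            mask[i, 0] = False
        for j in np.flatnonzero(mask.all(axis=0)):
            mask[0, j] = False
        values[mask] = np.nan
        k = int(rng.integers(1, 4))
        out = knn_impute(_mat(values), k=k)
        expected = _brute_knn_impute(values, k)
        np.testing.assert_allclose(out.values, expected, atol=1e-10)
        assert not np.isnan(out.values).any()

    def test_fully_missing_row_named_in_error(self):
        values = np.array([[1.0, 2.0], [np.nan, np.nan]])
        with pytest.raises(PreprocessError, match="m1"):
            knn_impute(_mat(values), k=1)


class TestDichotomize:
    def test_cutoff_boundary_and_below(self):
        labels = dichotomize_survival(["a", "b"], [23.9, 24.0])
        assert list(labels.classes) == [SHORT, LONG]

    def test_alive_at_followup_is_long(self):
        labels = dichotomize_survival(["a", "b"], [5.0, 30.0], alive_at_followup=[True, False])
        assert list(labels.classes) == [LONG, LONG]

    def test_negative_survival_rejected(self):
        with pytest.raises(PreprocessError):
            dichotomize_survival(["a"], [-1.0])


class TestSmote:
    @pytest.fixture
    def imbalanced(self, rng):
        values = rng.normal(27, 1, (10, 75))
        classes = np.array([SHORT] * 15 + [LONG] * 60, dtype=object)
        return _mat(values), _labels(classes)

    def test_minority_exactly_doubles(self, imbalanced):
        mat, labels = imbalanced
        out_mat, out_labels = smote_oversample(mat, labels, seed=0)
        assert (out_labels.classes == SHORT).sum() == 30
        assert (out_labels.classes == LONG).sum() == 60
        assert out_mat.n_samples == 90

    def test_synthetic_points_lie_on_parent_segments(self, imbalanced):
        mat, labels = imbalanced
        out_mat, out_labels = smote_oversample(mat, labels, seed=0)
        minority = mat.values[:, labels.class_indices(SHORT)]
        lo = minority.min(axis=1) - 1e-9
        hi = minority.max(axis=1) + 1e-9
        synth = out_mat.values[:, mat.n_samples:]
        assert ((synth >= lo[:, None]) & (synth <= hi[:, None])).all()

    def test_majority_samples_untouched(self, imbalanced):
        mat, labels = imbalanced
        out_mat, _ = smote_oversample(mat, labels, seed=0)
        np.testing.assert_array_equal(out_mat.values[:, : mat.n_samples], mat.values)

    def test_seed_determinism(self, imbalanced):
        mat, labels = imbalanced
        a, _ = smote_oversample(mat, labels, seed=7)
        b, _ = smote_oversample(mat, labels, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_singleton_minority_rejected(self, rng):
        mat = _mat(rng.normal(size=(3, 4)))
        labels = _labels([SHORT, LONG, LONG, LONG])
        with pytest.raises(PreprocessError):
            smote_oversample(mat, labels, seed=0)


class TestDifferentialExpression:
    def test_wilcoxon_matches_exact_rank_permutation(self):
        a, b = [1.1, 2.3, 3.9], [2.8, 4.5, 5.1]
        mat = _mat([a + b])
        labels = _labels([SHORT] * 3 + [LONG] * 3)
        p = differential_expression(mat, labels, method="wilcoxon").iloc[0]

        # exhaustive enumeration of all 3-of-6 rank assignments
        pooled = np.array(a + b)
        ranks = stats.rankdata(pooled)
        obs = ranks[:3].sum()
        centre = 3 * (len(pooled) + 1) / 2
        null = [sum(ranks[list(c)]) for c in itertools.combinations(range(6), 3)]
        extreme = sum(abs(w - centre) >= abs(obs - centre) - 1e-12 for w in null)
        assert p == pytest.approx(extreme / len(null), abs=1e-12)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(5)
        mat = _mat(rng.normal(27, 1, (200, 100)))
        labels = _labels([SHORT] * 50 + [LONG] * 50)
        p = differential_expression(mat, labels, method="ks")
        # exact small-sample KS p-values are discrete, so check calibration
        # pointwise: super-uniform tails and a centred mean
        for alpha in (0.05, 0.2, 0.5):
            tol = 3 * np.sqrt(alpha * (1 - alpha) / len(p))
            assert (p.values <= alpha).mean() <= alpha + tol
        assert 0.4 <= p.mean() <= 0.65

    def test_power_under_3_sd_shift(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(40):
            a = rng.normal(27, 1, 20)
            b = rng.normal(30, 1, 20)
            mat = _mat([np.concatenate([a, b])])
            labels = _labels([SHORT] * 20 + [LONG] * 20)
            hits += differential_expression(mat, labels, "ks").iloc[0] < 0.05
        assert hits / 40 > 0.95

    def test_sparse_class_yields_nan_not_dropped(self):
        values = np.array([[1.0, np.nan, np.nan, 2.0, 3.0, 4.0], [1, 2, 3, 4, 5, 6.0]])
        mat = _mat(values)
        labels = _labels([SHORT] * 3 + [LONG] * 3)
        p = differential_expression(mat, labels, "ks")
        assert np.isnan(p.iloc[0]) and not np.isnan(p.iloc[1])
        assert len(p) == 2


class TestFoldChange:
    def test_equal_means_give_unit_fc(self):
        mat = _mat([[5.0, 5.0, 5.0, 5.0]])
        labels = _labels([SHORT, SHORT, LONG, LONG])
        assert fold_change(mat, labels).iloc[0] == pytest.approx(1.0)

    def test_one_cycle_lower_in_short_doubles(self):
        mat = _mat([[24.0, 24.0, 25.0, 25.0]])
        labels = _labels([SHORT, SHORT, LONG, LONG])
        assert fold_change(mat, labels).iloc[0] == pytest.approx(2.0)

    def test_matches_direct_arithmetic(self, rng):
        values = rng.normal(27, 2, (5, 8))
        mat = _mat(values)
        labels = _labels([SHORT] * 3 + [LONG] * 5)
        fc = fold_change(mat, labels)
        for i in range(5):
            expected = 2.0 ** -(values[i, :3].mean() - values[i, 3:].mean())
            assert fc.iloc[i] == pytest.approx(expected, rel=1e-12)

    def test_direction_reciprocity(self, rng):
        mat = _mat(rng.normal(27, 2, (6, 10)))
        labels = _labels([SHORT] * 4 + [LONG] * 6)
        prod = fold_change(mat, labels) * fold_change(mat, labels, short_over_long=False)
        np.testing.assert_allclose(prod.values, 1.0, rtol=1e-12)


class TestCandidateFilter:
    @pytest.mark.parametrize(
        "fc, kept",
        [(1.6, True), (0.6, True), (1.0, False), (1.5, False), (2.0 / 3.0, False)],
    )
    def test_fold_change_rule_either_direction(self, fc, kept):
        fcs = pd.Series({"m": fc})
        assert (candidate_filter(None, fcs, fc_cut=1.5) == ["m"]) is kept

    def test_combined_and_switchable_filters(self):
        p = pd.Series({"a": 0.01, "b": 0.2, "c": 0.04})
        fc = pd.Series({"a": 1.2, "b": 2.0, "c": 1.8})
        assert candidate_filter(p, None) == ["a", "c"]
        assert candidate_filter(None, fc) == ["b", "c"]
        assert candidate_filter(p, fc) == ["c"]

    def test_nan_never_passes(self):
        p = pd.Series({"a": np.nan, "b": 0.01})
        assert candidate_filter(p, None) == ["b"]
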