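"""Unit and property tests for the SWISS score and its decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from swiss import (
    ClassAssignment,
    ExpressionMatrix,
    swiss_score,
    total_sum_of_squares,
    within_class_sum_of_squares,
)
from conftest import random_instance


def pairwise_sst(values: np.ndarray) -> float:
    """Independent oracle: N*SST = sum over unordered pairs of squared distance."""
    n = values.shape[1]
    total = 0.0
    for j in range(n):
        for l in range(j + 1, n):
            total += float(((values[:, j] - values[:, l]) ** 2).sum())
    return total / n


def brute_force_wiss(values: np.ndarray, class_idx: np.ndarray) -> float:
    """Independent oracle: per-class pairwise sum divided by class size."""
    total = 0.0
    for c in np.unique(class_idx):
        cols = values[:, class_idx == c]
        m = cols.shape[1]
        for j in range(m):
            for l in range(j + 1, m):
                total += float(((cols[:, j] - cols[:, l]) ** 2).sum()) / m
    return total


class TestTotalSumOfSquares:
    def test_toy_value(self, toy_matrix):
        assert total_sum_of_squares(toy_matrix) == 20.0

    def test_single_sample_is_zero(self):
        X = ExpressionMatrix(np.array([[3.0], [7.0]]), ("g1", "g2"), ("s1",))
        assert total_sum_of_squares(X) == 0.0

    def test_identical_samples_give_zero(self):
        X = ExpressionMatrix(np.tile([[1.0], [2.0]], (1, 5)), ("g1", "g2"), tuple("abcde"))
        assert total_sum_of_squares(X) == 0.0

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            X, _ = random_instance(rng)
            assert total_sum_of_squares(X) == pytest.approx(pairwise_sst(X.values), rel=1e-12)


class TestWithinClassSumOfSquares:
    def test_toy_value(self, toy_matrix, toy_labels):
        assert within_class_sum_of_squares(toy_matrix, toy_labels) == 4.0

    def test_each_sample_own_class_is_zero(self, toy_matrix):
        C = ClassAssignment.from_pairs((s, s) for s in toy_matrix.sample_ids)
        assert within_class_sum_of_squares(toy_matrix, C) == 0.0

    def test_single_class_equals_sst(self, toy_matrix):
        C = ClassAssignment.from_pairs((s, "all") for s in toy_matrix.sample_ids)
        assert within_class_sum_of_squares(toy_matrix, C) == total_sum_of_squares(toy_matrix)

    def test_unlabeled_sample_error_lists_ids(self, toy_matrix):
        C = ClassAssignment.from_pairs([("s1", "a"), ("s2", "a"), ("s3", "b")])
        with pytest.raises(ValueError, match="s4"):
            within_class_sum_of_squares(toy_matrix, C)

    def test_label_for_absent_sample_error_lists_ids(self, toy_matrix, toy_labels):
        C = ClassAssignment({**toy_labels.labels, "ghost": "a"})
        with pytest.raises(ValueError, match="ghost"):
            within_class_sum_of_squares(toy_matrix, C)


class TestSwissScore:
    def test_toy_value_exact(self, toy_matrix, toy_labels):
        assert swiss_score(toy_matrix, toy_labels).swiss == 0.2

    def test_single_class_gives_one(self, toy_matrix):
        C = ClassAssignment.from_pairs((s, "all") for s in toy_matrix.sample_ids)
        assert swiss_score(toy_matrix, C).swiss == 1.0

    def test_scale_invariance_toy(self, toy_matrix, toy_labels):
        scaled = ExpressionMatrix(7 * toy_matrix.values, toy_matrix.feature_ids, toy_matrix.sample_ids)
        assert swiss_score(scaled, toy_labels).swiss == 0.2

    def test_zero_variation_is_error(self):
        X = ExpressionMatrix(np.ones((2, 3)), ("g1", "g2"), ("s1", "s2", "s3"))
        C = ClassAssignment.from_pairs([("s1", "a"), ("s2", "a"), ("s3", "b")])
        with pytest.raises(ValueError, match="zero total variation"):
            swiss_score(X, C)

    def test_singleton_class_warns(self, toy_matrix):
        C = ClassAssignment.from_pairs([("s1", "a"), ("s2", "a"), ("s3", "a"), ("s4", "lone")])
        with pytest.warns(UserWarning, match="singleton"):
            swiss_score(toy_matrix, C)

    def test_label_order_irrelevant(self, toy_matrix, toy_labels):
        shuffled = ClassAssignment.from_pairs(
            [("s4", "b"), ("s2", "a"), ("s3", "b"), ("s1", "a")]
        )
        assert swiss_score(toy_matrix, shuffled).swiss == swiss_score(toy_matrix, toy_labels).swiss

    def test_contributions_sum_to_swiss(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            X, C = random_instance(rng, d=4, n=8, k=3)
            r = swiss_score(X, C)
            assert r.contributions.sum() == pytest.approx(r.swiss, rel=1e-12)
            assert (r.contributions >= 0).all()

    def test_anova_decomposition(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            X, C = random_instance(rng, d=4, n=8, k=3)
            r = swiss_score(X, C)
            idx = C.indices_for(X.sample_ids)
            sizes = np.bincount(idx, minlength=C.n_classes)
            between = sum(
                sizes[i] * float(((r.class_means[i] - r.overall_mean) ** 2).sum())
                for i in range(C.n_classes)
            )
            assert r.sst == pytest.approx(r.wiss + between, rel=1e-9)


# strategies: small complete matrices with a labeling using every class
@st.composite
def matrix_and_labels(draw):
    d = draw(st.integers(2, 6))
    n = draw(st.integers(3, 10))
    k = draw(st.integers(1, 3))
    values = draw(
        arrays(
            float, (d, n),
            elements=st.floats(-100, 100, allow_nan=False, allow_infinity=False, width=32),
        )
    )
    labels = draw(
        st.lists(st.integers(0, k - 1), min_size=n, max_size=n).filter(
            lambda ls: len(set(ls)) == k
        )
    )
    ids = tuple(f"s{j}" for j in range(n))
    X = ExpressionMatrix(values, tuple(f"g{i}" for i in range(d)), ids)
    C = ClassAssignment.from_pairs((ids[j], f"c{labels[j]}") for j in range(n))
    return X, C


@settings(max_examples=60, derandomize=True)
@given(matrix_and_labels())
def test_swiss_in_unit_interval_and_decomposes(case):
    X, C = case
    if total_sum_of_squares(X) == 0.0:
        with pytest.raises(ValueError):
            swiss_score(X, C)
        return
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        r = swiss_score(X, C)
    assert 0.0 <= r.swiss <= 1.0
    assert 0.0 <= r.wiss <= r.sst * (1 + 1e-12)
    idx = C.indices_for(X.sample_ids)
    assert r.wiss == pytest.approx(brute_force_wiss(X.values, idx), rel=1e-9, abs=1e-9)


@settings(max_examples=30, derandomize=True)
@given(matrix_and_labels(), st.floats(0.1, 50), st.floats(-20, 20))
def test_swiss_invariant_under_scaling_and_translation(case, scale, shift):
    X, C = case
    if total_sum_of_squares(X) == 0.0:
        return
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        base = swiss_score(X, C).swiss
        transformed = ExpressionMatrix(
            scale * X.values + shift, X.feature_ids, X.sample_ids
        )
        assert swiss_score(transformed, C).swiss == pytest.approx(base, rel=1e-9, abs=1e-12)


def test_swiss_invariant_under_rotation():
    from scipy.stats import ortho_group

    rng = np.random.default_rng(21)
    for _ in range(10):
        X, C = random_instance(rng, d=5, n=8, k=2)
        Q = ortho_group.rvs(5, random_state=rng)
        rotated = ExpressionMatrix(Q @ X.values, X.feature_ids, X.sample_ids)
        assert swiss_score(rotated, C).swiss == pytest.approx(swiss_score(X, C).swiss, rel=1e-9)


class TestValidation:
    def test_nan_entry_names_feature_and_sample(self):
        values = np.array([[1.0, 2.0], [np.nan, 4.0]])
        with pytest.raises(ValueError, match=r"g2.*s1"):
            ExpressionMatrix(values, ("g1", "g2"), ("s1", "s2"))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate feature"):
            ExpressionMatrix(np.ones((2, 2)), ("g", "g"), ("s1", "s2"))
        with pytest.raises(ValueError, match="duplicate sample"):
            ExpressionMatrix(np.ones((2, 2)), ("g1", "g2"), ("s", "s"))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(np.empty((0, 0)), (), ())

    def test_class_without_members_rejected(self, toy_labels):
        with pytest.raises(ValueError, match="classes"):
            ClassAssignment(toy_labels.labels, classes=("a", "b", "phantom"))
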