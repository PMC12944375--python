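import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfastox import (
    ToxClass,
    drop_duplicate_rows,
    filter_repeated_columns,
    pearson_correlation_matrix,
    stratified_split,
    zscore_apply,
    zscore_fit,
)
from pfastox.dataset_io import ValidationError


def labels_for(n_high, n_low):
    out = {f"h{i}": ToxClass.HIGH for i in range(n_high)}
    out.update({f"l{i}": ToxClass.LOW for i in range(n_low)})
    return out


class TestStratifiedSplit:
    def test_study_size_arithmetic(self):
        """195/112 at 70/30 gives 215 train / 92 test (58 high, 34 low)."""
        res = stratified_split(labels_for(195, 112), 0.3, seed=590729676119100)
        assert len(res.test_ids) == 92
        assert len(res.train_ids) == 215
        assert sum(i.startswith("h") for i in res.test_ids) == 58
        assert sum(i.startswith("l") for i in res.test_ids) == 34

    def test_balanced_half_split_is_exact(self):
        res = stratified_split(labels_for(5, 5), 0.5, seed=1)
        assert len(res.test_ids) == 5
        assert sum(i.startswith("h") for i in res.test_ids) in (2, 3)

    def test_largest_remainder_hand_case(self):
        """4 A / 3 B at 0.3: quotas floor(1.2)=1, floor(0.9)=0; the single
        leftover slot goes to B (remainder 0.9 > 0.2)."""
        labels = {f"a{i}": "A" for i in range(4)}
        labels.update({f"b{i}": "B" for i in range(3)})
        res = stratified_split(labels, 0.3, seed=3)
        assert len(res.test_ids) == 2
        assert sum(i.startswith("a") for i in res.test_ids) == 1
        assert sum(i.startswith("b") for i in res.test_ids) == 1

    def test_deterministic_and_partition(self):
        labels = labels_for(20, 13)
        a = stratified_split(labels, 0.3, seed=9)
        b = stratified_split(labels, 0.3, seed=9)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        assert set(a.train_ids) | set(a.test_ids) == set(labels)
        assert not set(a.train_ids) & set(a.test_ids)

    def test_singleton_class_rejected(self):
        with pytest.raises(ValidationError):
            stratified_split({"a": "A", "b": "B", "c": "B"}, 0.3, seed=0)

    @given(
        n_high=st.integers(5, 120),
        n_low=st.integers(5, 120),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_class_shares_within_one_compound(self, n_high, n_low, seed):
        """Per-class test counts stay within one compound of proportionality."""
        res = stratified_split(labels_for(n_high, n_low), 0.3, seed=seed)
        test_high = sum(i.startswith("h") for i in res.test_ids)
        test_low = sum(i.startswith("l") for i in res.test_ids)
        assert abs(test_high - 0.3 * n_high) <= 1
        assert abs(test_low - 0.3 * n_low) <= 1
        # total test size: round-half-up of N * fraction
        import math

        assert test_high + test_low == math.floor((n_high + n_low) * 0.3 + 0.5)


class TestFilterRepeatedColumns:
    def test_constant_distinct_and_borderline(self, matrix_factory):
        data = np.column_stack([
            np.ones(10),                      # constant: modal fraction 1.0
            np.arange(10.0),                  # all distinct: 0.1
            np.array([5.0] * 3 + list(range(10, 17))),  # modal fraction 0.3
        ])
        m = matrix_factory(data, cols=["const", "distinct", "tripled"])
        res = filter_repeated_columns(m, 0.2)
        assert res.dropped == ["const", "tripled"]
        assert res.kept == ["distinct"]
        assert res.modal_fraction["tripled"] == pytest.approx(0.3)

    def test_threshold_is_strict(self, matrix_factory):
        m = matrix_factory(np.array([[1.0], [1.0], [2.0], [3.0], [4.0]]))
        res = filter_repeated_columns(m, 0.4)  # modal fraction exactly 0.4
        assert res.kept == m.column_names

    def test_partition_of_columns(self, matrix_factory, rng):
        m = matrix_factory(rng.standard_normal((8, 5)))
        res = filter_repeated_columns(m)
        assert sorted(res.kept + res.dropped) == sorted(m.column_names)


class TestZScore:
    def test_simple_column(self, matrix_factory):
        m = matrix_factory([[1.0], [2.0], [3.0]])
        norm = zscore_fit(m)
        assert norm.mean.iloc[0] == pytest.approx(2.0)
        assert norm.sd.iloc[0] == pytest.approx(1.0)
        z = zscore_apply(norm, m)
        np.testing.assert_allclose(z.values.ravel(), [-1, 0, 1])

    def test_train_moments_and_test_at_mean(self, matrix_factory, rng):
        train = matrix_factory(rng.standard_normal((20, 5)) * 3 + 7)
        norm = zscore_fit(train)
        z = zscore_apply(norm, train)
        np.testing.assert_allclose(z.values.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(z.values.std(axis=0, ddof=1), 1, atol=1e-9)
        test = matrix_factory(norm.mean.to_numpy()[None, :], ids=["q"])
        np.testing.assert_allclose(zscore_apply(norm, test).values, 0, atol=1e-12)

    def test_zero_variance_directs_to_filter(self, matrix_factory):
        m = matrix_factory([[1.0, 2.0], [1.0, 3.0]])
        with pytest.raises(ValidationError, match="filter_repeated_columns"):
            zscore_fit(m)

    def test_json_round_trip(self, matrix_factory, rng, tmp_path):
        from pfastox.preprocess import Normalizer

        norm = zscore_fit(matrix_factory(rng.standard_normal((10, 3))))
        norm.to_json(tmp_path / "n.json")
        back = Normalizer.from_json(tmp_path / "n.json")
        pd.testing.assert_series_equal(norm.mean, back.mean, check_names=False)
        pd.testing.assert_series_equal(norm.sd, back.sd, check_names=False)


class TestDropDuplicateRows:
    def test_identical_pair_keeps_first(self, matrix_factory):
        m = matrix_factory([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0]])
        out, rep = drop_duplicate_rows(m)
        assert out.row_ids == ["c0", "c2"]
        assert rep.removed_ids == ["c1"]
        assert rep.kept_for == {"c1": "c0"}

    def test_no_duplicates_is_identity(self, matrix_factory, rng):
        m = matrix_factory(rng.standard_normal((6, 3)))
        out, rep = drop_duplicate_rows(m)
        assert out.row_ids == m.row_ids
        assert rep.removed_ids == []

    def test_two_duplicate_pairs(self, matrix_factory):
        rows = [[1, 1], [2, 2], [1, 1], [3, 3], [2, 2], [4, 4]]
        out, rep = drop_duplicate_rows(matrix_factory(rows))
        assert out.shape[0] == 4
        assert set(rep.removed_ids) == {"c2", "c4"}

    def test_conflicting_labels_warn(self, matrix_factory):
        m = matrix_factory([[1.0, 1.0], [1.0, 1.0]])
        _, rep = drop_duplicate_rows(
            m, {"c0": ToxClass.HIGH, "c1": ToxClass.LOW})
        assert rep.label_conflicts


class TestPearsonCorrelation:
    def test_duplicate_and_negated_columns(self, matrix_factory, rng):
        x = rng.standard_normal(8)
        m = matrix_factory(np.column_stack([x, x, -x]), cols=["a", "b", "c"])
        r = pearson_correlation_matrix(m)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        np.testing.assert_allclose(r.to_numpy(), r.to_numpy().T)
        np.testing.assert_allclose(np.diag(r.to_numpy()), 1.0)

    def test_five_point_hand_oracle(self, matrix_factory):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        m = matrix_factory(np.column_stack([x, y]), cols=["x", "y"])
        r = pearson_correlation_matrix(m)
        cov = ((x - x.mean()) * (y - y.mean())).sum() / 4
        expected = cov / (x.std(ddof=1) * y.std(ddof=1))
        assert r.loc["x", "y"] == pytest.approx(expected, abs=1e-12)

    def test_requires_three_rows_and_variance(self, matrix_factory):
        with pytest.raises(ValidationError):
            pearson_correlation_matrix(matrix_factory([[1.0, 2.0], [3.0, 4.0]]))
        with pytest.raises(ValidationError):
            pearson_correlation_matrix(
                matrix_factory([[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]]))
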