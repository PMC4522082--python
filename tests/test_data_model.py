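import numpy as np
import pytest

from omicsbias.data_model import (ExpressionDataset, cpm_normalize,
                                  label_counts, q3_normalize, read_expression,
                                  standardize_samples, write_expression)


class TestIO:
    def test_round_trip_preserves_everything(self, tiny_dataset, tmp_path):
        m, l = tmp_path / "m.tsv", tmp_path / "l.tsv"
        write_expression(tiny_dataset, m, l)
        back = read_expression(m, l)
        np.testing.assert_allclose(back.values, tiny_dataset.values)
        assert back.feature_ids == tiny_dataset.feature_ids
        assert back.sample_ids == tiny_dataset.sample_ids
        np.testing.assert_array_equal(back.labels, tiny_dataset.labels)

    def test_round_trip_full_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        ds = ExpressionDataset(values=rng.standard_normal((5, 4)),
                               labels=np.array([1, 1, -1, -1]))
        write_expression(ds, tmp_path / "m.tsv", tmp_path / "l.tsv")
        back = read_expression(tmp_path / "m.tsv", tmp_path / "l.tsv")
        np.testing.assert_array_equal(back.values, ds.values)

    def test_missing_label_errors(self, tiny_dataset, tmp_path):
        m, l = tmp_path / "m.tsv", tmp_path / "l.tsv"
        write_expression(tiny_dataset, m, l)
        l.write_text("s1\t+1\n")  # s2 dropped
        with pytest.raises(ValueError, match="missing a label"):
            read_expression(m, l)

    def test_unknown_label_token_errors(self, tiny_dataset, tmp_path):
        m, l = tmp_path / "m.tsv", tmp_path / "l.tsv"
        write_expression(tiny_dataset, m, l)
        l.write_text("s1\t+1\ns2\tcase\n")
        with pytest.raises(ValueError, match="unknown label token"):
            read_expression(m, l)

    def test_non_numeric_cell_errors(self, tmp_path):
        (tmp_path / "m.tsv").write_text("id\ts1\ts2\nfA\t1\tx\n")
        (tmp_path / "l.tsv").write_text("s1\t+1\ns2\t-1\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_expression(tmp_path / "m.tsv", tmp_path / "l.tsv")


class TestDatasetInvariants:
    def test_label_length_mismatch(self):
        with pytest.raises(ValueError, match="labels length"):
            ExpressionDataset(values=np.ones((2, 3)), labels=np.array([1, -1]))

    def test_labels_must_be_pm1(self):
        with pytest.raises(ValueError, match="-1 or \\+1"):
            ExpressionDataset(values=np.ones((2, 2)), labels=np.array([0, 1]))

    def test_counts_must_be_non_negative(self):
        with pytest.raises(ValueError, match="non-negative"):
            ExpressionDataset(values=np.array([[-1.0, 2.0]]),
                              labels=np.array([1, -1]),
                              distribution_tag="negative_binomial")


class TestStandardize:
    def test_simple_column(self):
        ds = ExpressionDataset(values=np.array([[1.0], [2.0], [3.0]]),
                               labels=np.array([1]))
        out = standardize_samples(ds)
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 0.0, 1.0])

    def test_zero_mean_unit_variance_all_columns(self):
        rng = np.random.default_rng(1)
        ds = ExpressionDataset(values=rng.gamma(2, 3, (50, 8)),
                               labels=np.array([1, -1] * 4))
        out = standardize_samples(ds)
        np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.values.var(axis=0, ddof=1), 1,
                                   atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        ds = ExpressionDataset(values=rng.standard_normal((30, 5)),
                               labels=np.array([1, 1, 1, -1, -1]))
        once = standardize_samples(ds)
        twice = standardize_samples(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_constant_column_errors_with_sample_id(self):
        ds = ExpressionDataset(values=np.array([[5.0, 1.0], [5.0, 2.0],
                                                [5.0, 3.0]]),
                               sample_ids=["bad", "ok"],
                               labels=np.array([1, -1]))
        with pytest.raises(ValueError, match="bad"):
            standardize_samples(ds)

    def test_feature_axis_switch(self):
        rng = np.random.default_rng(3)
        ds = ExpressionDataset(values=rng.standard_normal((6, 10)),
                               labels=np.array([1, -1] * 5))
        out = standardize_samples(ds, axis="features")
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.values.var(axis=1, ddof=1), 1,
                                   atol=1e-12)


class TestCountNormalization:
    def _counts(self, cols):
        arr = np.array(cols, dtype=float).T
        labels = np.array([1] * arr.shape[1])
        return ExpressionDataset(values=arr, labels=labels,
                                 distribution_tag="negative_binomial")

    def test_q3_unit_scale_unchanged(self):
        col = [0, 1000, 1000, 1000]  # 75th percentile exactly 1000
        assert np.percentile(col, 75) == 1000
        ds = self._counts([col])
        np.testing.assert_allclose(q3_normalize(ds).values[:, 0], col)

    def test_q3_halves_when_doubled(self):
        ds = self._counts([[0, 2000, 2000, 2000]])  # Q3 = 2000 -> s = 2
        np.testing.assert_allclose(q3_normalize(ds).values[:, 0],
                                   [0, 1000, 1000, 1000])

    def test_q3_zero_errors(self):
        ds = self._counts([[0, 0, 0, 0]])
        with pytest.raises(ValueError, match="75th percentile"):
            q3_normalize(ds)

    def test_cpm_values_and_conservation(self):
        ds = self._counts([[1, 1], [3, 1], [0, 500]])
        out = cpm_normalize(ds)
        np.testing.assert_allclose(out.values[:, 0], [500000, 500000])
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_cpm_zero_sum_errors(self):
        ds = self._counts([[0, 0]])
        with pytest.raises(ValueError, match="zero total count"):
            cpm_normalize(ds)


class TestLabelCounts:
    @pytest.mark.parametrize("n_pos,n_neg,maj_label,maj_count", [
        (34, 13, 1, 34),        # breast-cancer cohort counts
        (475, 68, 1, 475),      # kidney cohort counts
        (5, 5, 1, 5),           # tie resolves to +1
        (13, 34, -1, 34),
    ])
    def test_counts(self, n_pos, n_neg, maj_label, maj_count):
        labels = np.array([1] * n_pos + [-1] * n_neg)
        c = label_counts(labels)
        assert (c.n_positive, c.n_negative) == (n_pos, n_neg)
        assert c.majority_label == maj_label
        assert c.majority_count == maj_count

    def test_invalid_labels(self):
        with pytest.raises(ValueError):
            label_counts([0, 1])
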