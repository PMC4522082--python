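import math

import numpy as np
import pytest

from omicsbias.data_model import standardize_samples
from omicsbias.kernels import (KernelSpec, classify_gram, distance_summary,
                               gram, kernel_value, rbf2_bandwidth)

FAMILIES = ["linear", "rbf", "rbf2", "quad", "mlp"]


def spec_for(family):
    return KernelSpec(family, bandwidth_sq=2.0) \
        if family in ("rbf", "rbf2") else KernelSpec(family)


class TestKernelValue:
    def test_rbf_zero_distance_is_one(self):
        x = np.array([1.0, -2.0, 3.0])
        assert kernel_value(KernelSpec("rbf"), x, x) == 1.0

    def test_rbf_amplified_distance_vanishes(self):
        # ||x - x'||^2 = 100 with sigma^2 = 1 -> exp(-50) ~ 2e-22
        x = np.zeros(4)
        x2 = np.array([10.0, 0.0, 0.0, 0.0])
        val = kernel_value(KernelSpec("rbf", 1.0), x, x2)
        assert val == pytest.approx(math.exp(-50.0), rel=1e-12)
        assert val < 1e-21

    @pytest.mark.parametrize("family,expected", [
        ("linear", 11.0),   # (1,2).(3,4)
        ("quad", 144.0),    # (1 + 11)^2
    ])
    def test_dot_product_families(self, family, expected):
        assert kernel_value(KernelSpec(family), [1, 2], [3, 4]) == expected

    def test_mlp_at_unit_dot_is_zero(self):
        assert kernel_value(KernelSpec("mlp"), [1.0], [1.0]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            kernel_value(KernelSpec("linear"), [1, 2], [1, 2, 3])

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            KernelSpec("sigmoid")
        with pytest.raises(ValueError):
            KernelSpec("rbf", bandwidth_sq=-1.0)
        with pytest.raises(ValueError):
            KernelSpec("linear", bandwidth_sq=1.0)
        assert KernelSpec("rbf").bandwidth_sq == 1.0


class TestRbf2Bandwidth:
    def brute(self, X):
        # independent enumeration over all ordered pairs, incl. i = j
        m = X.shape[1]
        total = sum(np.sum((X[:, i] - X[:, j]) ** 2)
                    for i in range(m) for j in range(m))
        return total / (m - 1) ** 2

    def test_two_samples(self):
        X = np.array([[0.0, 2.0]])  # ||x1 - x2||^2 = 4
        assert rbf2_bandwidth(X) == pytest.approx(8.0)

    def test_equilateral_triangle(self):
        d = 2.0  # pairwise distance d, squared distance 4
        X = np.array([[0.0, d, d / 2],
                      [0.0, 0.0, d * math.sqrt(3) / 2]])
        assert rbf2_bandwidth(X) == pytest.approx(6 * d ** 2 / 4)
        assert rbf2_bandwidth(X) == pytest.approx(self.brute(X))

    def test_matches_enumeration_on_random_data(self):
        X = np.random.default_rng(0).standard_normal((7, 9))
        assert rbf2_bandwidth(X) == pytest.approx(self.brute(X), rel=1e-12)

    def test_identical_samples_error(self):
        with pytest.raises(ValueError, match="identical"):
            rbf2_bandwidth(np.ones((3, 4)))

    def test_single_sample_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            rbf2_bandwidth(np.ones((3, 1)))


class TestGram:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_matches_brute_force_pairwise_loop(self, family):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((6, 12))
        spec = spec_for(family)
        K = gram(spec, X)
        m = X.shape[1]
        expected = np.array([[kernel_value(spec, X[:, i], X[:, j])
                              for j in range(m)] for i in range(m)])
        np.testing.assert_allclose(K.values, expected, atol=1e-12)
        np.testing.assert_allclose(K.values, K.values.T, atol=1e-10)

    def test_rbf_diagonal_one_entries_in_unit_interval(self):
        X = np.random.default_rng(5).standard_normal((8, 10))
        K = gram(KernelSpec("rbf", 3.0), X)
        np.testing.assert_array_equal(np.diag(K.values), 1.0)
        assert np.all(K.values > 0) and np.all(K.values <= 1)

    def test_cross_kernel_block(self):
        rng = np.random.default_rng(6)
        A, B = rng.standard_normal((5, 3)), rng.standard_normal((5, 4))
        block = gram(KernelSpec("linear"), A, B)
        np.testing.assert_allclose(block, A.T @ B)
        with pytest.raises(ValueError, match="feature counts"):
            gram(KernelSpec("linear"), A, rng.standard_normal((4, 2)))

    def test_linear_two_samples(self):
        X = np.array([[1.0, 3.0], [2.0, 4.0]])
        K = gram(KernelSpec("linear"), X)
        np.testing.assert_allclose(K.values, [[5.0, 11.0], [11.0, 25.0]])


class TestClassifyGram:
    def test_exact_identity(self):
        assert classify_gram(np.eye(5)) == "identity_like"

    def test_all_ones_is_flat(self):
        assert classify_gram(np.ones((4, 4))) == "flat_like"

    def test_constant_zero_matrix_is_flat(self):
        # tanh(dot - 1) = 0 everywhere when all inner products are 1
        assert classify_gram(np.zeros((3, 3))) == "flat_like"

    def test_generic_linear_gram_is_normal(self):
        X = np.random.default_rng(7).standard_normal((10, 6))
        assert gram(KernelSpec("linear"), X).structure == "normal"

    def test_annotations_filled(self):
        K = gram(KernelSpec("rbf"), np.random.default_rng(8)
                 .standard_normal((5, 4)))
        assert K.max_offdiag >= 0 and K.min_entry > 0

    def test_non_square_errors(self):
        with pytest.raises(ValueError, match="square"):
            classify_gram(np.ones((2, 3)))


class TestDistanceSummary:
    def test_two_samples(self):
        X = np.array([[0.0, 3.0]])
        s = distance_summary(X)
        assert s.min_sq == s.max_sq == 9.0

    def test_orthogonal_standardized_samples(self):
        # standardized columns have squared norm p-1, so orthogonal
        # standardized samples sit at squared distance 2(p-1)
        p = 16
        rng = np.random.default_rng(9)
        # build exactly orthogonal zero-mean unit-variance columns
        a = rng.standard_normal(p)
        a -= a.mean()
        b = rng.standard_normal(p)
        b -= b.mean()
        b -= (a @ b) / (a @ a) * a  # a is zero-mean, so b stays zero-mean
        a /= a.std(ddof=1)
        b /= b.std(ddof=1)
        assert abs(a @ b) < 1e-8
        brute = float(np.sum((a - b) ** 2))
        s = distance_summary(np.column_stack([a, b]))
        assert s.min_sq == pytest.approx(2 * (p - 1), rel=1e-8)
        assert s.min_sq == pytest.approx(brute)

    def test_ordering_invariant(self):
        X = np.random.default_rng(10).standard_normal((12, 8))
        s = distance_summary(X)
        q1, q2, q3 = s.quartiles_sq
        assert s.min_sq <= q1 <= q2 <= q3 <= s.max_sq

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            distance_summary(np.ones((3, 1)))


class TestAmplifiedContract:
    def test_amplified_fixture_yields_identity_rbf(self, amplified_skew_dataset):
        Z = standardize_samples(amplified_skew_dataset)
        assert distance_summary(Z.values).min_sq >= 100.0
        K = gram(KernelSpec("rbf", 1.0), Z.values)
        assert K.structure == "identity_like"
        assert K.max_offdiag < 1e-20
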