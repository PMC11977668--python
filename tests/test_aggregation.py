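"""Unit and property tests for the pooling operators and probability transforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sparsemil.aggregation import (
    RegularizerWeights,
    attention_aggregate_embeddings,
    attention_aggregate_predictions,
    l0_penalty,
    l0_smooth_penalty,
    max_pool_embeddings,
    max_pool_predictions,
    mer_penalty,
    simplex_projection_oracle,
    softmax_transform,
    sparsemax_jacobian_vector,
    sparsemax_transform,
)

finite_vectors = arrays(
    np.float64, st.integers(1, 12),
    elements=st.floats(-20, 20, allow_nan=False, allow_infinity=False),
)


class TestSoftmax:
    @pytest.mark.parametrize("v, expected", [
        ([0.0, 0.0], [0.5, 0.5]),
        ([np.log(1.0), np.log(3.0)], [0.25, 0.75]),
        ([5.0], [1.0]),
    ])
    def test_closed_form(self, v, expected):
        np.testing.assert_allclose(softmax_transform(v), expected, atol=1e-12)

    @settings(deadline=None)
    @given(finite_vectors, st.floats(-50, 50))
    def test_shift_invariance_and_simplex(self, v, c):
        p = softmax_transform(v)
        assert np.all(p > 0)
        assert abs(p.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(softmax_transform(v + c), p, atol=1e-9)

    def test_overflow_safe(self):
        p = softmax_transform([1e4, 1e4 - 1.0])
        assert np.all(np.isfinite(p)) and abs(p.sum() - 1) < 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            softmax_transform([])


class TestSparsemax:
    def test_hand_case(self):
        res = sparsemax_transform([2.0, 0.0])
        np.testing.assert_array_equal(res.probabilities, [1.0, 0.0])
        assert res.threshold == 1.0
        assert res.support_size == 1

    def test_simplex_fixed_point(self):
        res = sparsemax_transform([0.5, 0.3, 0.2])
        np.testing.assert_allclose(res.probabilities, [0.5, 0.3, 0.2], atol=1e-12)
        assert abs(res.threshold) < 1e-12

    @pytest.mark.parametrize("L", [1, 2, 5, 11])
    def test_constant_gives_uniform(self, L):
        res = sparsemax_transform(np.full(L, 3.7))
        np.testing.assert_allclose(res.probabilities, np.full(L, 1.0 / L), atol=1e-12)
        assert res.support_size == L

    @pytest.mark.parametrize("t", [1.0, 1.5, 4.0, 30.0])
    def test_saturation_vs_softmax_positivity(self, t):
        # a gap >= 1 makes sparsemax exactly one-hot; softmax keeps every
        # instance strictly positive
        np.testing.assert_array_equal(
            sparsemax_transform([t, 0.0]).probabilities, [1.0, 0.0])
        p = softmax_transform([t, 0.0])
        assert p[0] < 1.0 and p[1] > 0.0

    @settings(deadline=None, max_examples=200)
    @given(finite_vectors)
    def test_matches_projection_oracle(self, v):
        res = sparsemax_transform(v)
        oracle = simplex_projection_oracle(v)
        np.testing.assert_allclose(res.probabilities, oracle, atol=1e-9)
        assert res.support_size == np.count_nonzero(res.probabilities)
        nz = res.probabilities > 0
        np.testing.assert_allclose(
            res.probabilities[nz], v[nz] - res.threshold, atol=1e-12)

    def test_jacobian_matches_finite_differences(self, rng):
        v = rng.normal(0, 2, 8)
        res = sparsemax_transform(v)
        g = rng.normal(0, 1, 8)
        dv = sparsemax_jacobian_vector(res, g)
        eps = 1e-7
        for i in range(8):
            e = np.zeros(8)
            e[i] = eps
            plus = sparsemax_transform(v + e).probabilities
            minus = sparsemax_transform(v - e).probabilities
            fd = g @ (plus - minus) / (2 * eps)
            assert abs(fd - dv[i]) < 1e-6


class TestOracle:
    def test_hand_cases(self):
        np.testing.assert_allclose(simplex_projection_oracle([2.0, 0.0]), [1.0, 0.0])
        np.testing.assert_allclose(
            simplex_projection_oracle(np.full(4, 9.0)), np.full(4, 0.25))

    def test_large_vector_rejected(self):
        with pytest.raises(ValueError):
            simplex_projection_oracle(np.zeros(21))


class TestPenalties:
    @pytest.mark.parametrize("p, lam, expected", [
        ([0.0, 0.0, 0.0], 5.0, 0.0),
        ([0.7, 0.3, 0.0, 0.0], 0.01, 0.02),
        ([0.2, 0.8], 0.0, 0.0),
    ])
    def test_l0_examples(self, p, lam, expected):
        assert l0_penalty(p, lam) == pytest.approx(expected, abs=1e-15)

    def test_l0_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            l0_penalty([0.5, 0.5], -0.1)

    def test_l0_smooth_approaches_count(self):
        p = np.array([0.6, 0.4, 0.0])
        value, grad = l0_smooth_penalty(p, 1.0, sigma=1e-4)
        assert value == pytest.approx(2.0, abs=1e-6)
        assert grad.shape == p.shape

    @pytest.mark.parametrize("p, lam, sign, expected", [
        ([1.0, 0.0, 0.0], 3.0, +1, 0.0),                       # one-hot
        ([0.5, 0.5], 1.0, +1, 2 * 0.5 * np.log(0.5)),          # -0.693147
        ([0.25] * 4, 0.0, +1, 0.0),
        ([0.5, 0.5], 1.0, -1, -2 * 0.5 * np.log(0.5)),
    ])
    def test_mer_examples(self, p, lam, sign, expected):
        assert mer_penalty(p, lam, sign) == pytest.approx(expected, abs=1e-12)

    def test_mer_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            mer_penalty([0.5, 0.6], 1.0)

    @settings(deadline=None)
    @given(finite_vectors)
    def test_mer_bounded_and_zero_iff_onehot(self, v):
        p = softmax_transform(v)
        value = mer_penalty(p, 1.0, +1)
        assert abs(value) <= np.log(p.size) + 1e-9
        one_hot = np.zeros(p.size)
        one_hot[0] = 1.0
        assert mer_penalty(one_hot, 1.0) == 0.0
        if p.size > 1:  # softmax output is never one-hot
            assert value < 0

    def test_regularizer_weights_validation(self):
        with pytest.raises(ValueError):
            RegularizerWeights(lambda_l0=-1.0)
        with pytest.raises(ValueError):
            RegularizerWeights(mer_sign=0)


class TestPooling:
    def test_max_pool_embeddings(self):
        np.testing.assert_array_equal(
            max_pool_embeddings([[1.0, 0.0], [0.0, 2.0]]), [1.0, 2.0])
        np.testing.assert_array_equal(
            max_pool_embeddings([[3.0, -1.0]]), [3.0, -1.0])

    def test_max_pool_predictions(self):
        assert max_pool_predictions([0.2, 0.9, 0.1]) == 0.9
        assert max_pool_predictions([0.4]) == 0.4

    def test_attention_aggregate_embeddings(self):
        H = np.array([[0.0, 0.0], [2.0, 4.0]])
        np.testing.assert_allclose(
            attention_aggregate_embeddings(H, [0.5, 0.5]), [1.0, 2.0])
        np.testing.assert_allclose(
            attention_aggregate_embeddings(H, [0.0, 1.0]), H[1])

    def test_attention_aggregate_predictions(self):
        assert attention_aggregate_predictions([0.2, 0.8], [0.5, 0.5]) == pytest.approx(0.5)
        assert attention_aggregate_predictions([0.2, 0.8], [1.0, 0.0]) == pytest.approx(0.2)

    @settings(deadline=None, max_examples=50)
    @given(st.data())
    def test_permutation_invariance_and_bounds(self, data):
        L = data.draw(st.integers(1, 10))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        H = rng.normal(0, 1, (L, 4))
        scores = rng.uniform(0, 1, L)
        a = softmax_transform(rng.normal(0, 1, L))
        perm = rng.permutation(L)
        np.testing.assert_allclose(
            max_pool_embeddings(H), max_pool_embeddings(H[perm]), atol=1e-12)
        np.testing.assert_allclose(
            attention_aggregate_embeddings(H, a),
            attention_aggregate_embeddings(H[perm], a[perm]), atol=1e-9)
        agg = attention_aggregate_predictions(scores, a)
        assert scores.min() - 1e-12 <= agg <= scores.max() + 1e-12

    def test_zero_weight_instances_ignored(self, rng):
        H = rng.normal(0, 1, (4, 3))
        a = np.array([0.6, 0.4, 0.0, 0.0])
        H2 = H.copy()
        H2[2:] = 999.0
        np.testing.assert_allclose(
            attention_aggregate_embeddings(H, a),
            attention_aggregate_embeddings(H2, a), atol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attention_aggregate_predictions([0.1, 0.2], [1.0])
        with pytest.raises(ValueError):
            max_pool_embeddings(np.empty((0, 3)))
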