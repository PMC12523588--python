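"""AHP weighting: eigenvector priorities, consistency, group aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mcdaval as m
from mcdaval.ahp import (
    RANDOM_INDEX,
    SAATY_LEVELS,
    aggregate_judgments,
    authority_coefficient,
    consistency,
    panel_authoritative,
    principal_weights,
    row_geometric_mean_weights,
)

from conftest import random_reciprocal_matrix

DOMAIN_WEIGHTS_31 = (0.3855, 0.2885, 0.0965, 0.0824, 0.0784, 0.0688)


class TestPrincipalWeights:
    def test_consistent_3x3(self):
        mat = m.PairwiseComparisonMatrix([[1, 2, 4], [0.5, 1, 2], [0.25, 0.5, 1]])
        w, lam = principal_weights(mat)
        np.testing.assert_allclose(w, [4 / 7, 2 / 7, 1 / 7], atol=1e-10)
        assert lam == pytest.approx(3.0, abs=1e-9)

    @pytest.mark.parametrize("n", [2, 4, 7])
    def test_all_ones_gives_uniform(self, n):
        mat = m.PairwiseComparisonMatrix(np.ones((n, n)))
        w, lam = principal_weights(mat)
        np.testing.assert_allclose(w, np.full(n, 1 / n), atol=1e-12)
        assert lam == pytest.approx(n, abs=1e-9)

    def test_recovers_elicited_domain_weights(self):
        # a consistent matrix built from the six elicited domain weights
        # returns that vector, safety largest
        w_true = np.array(DOMAIN_WEIGHTS_31)
        w_true = w_true / w_true.sum()
        mat = m.PairwiseComparisonMatrix.consistent_from_weights(w_true)
        w, lam = principal_weights(mat)
        np.testing.assert_allclose(w, w_true, atol=1e-8)
        assert np.argmax(w) == 0  # safety
        assert lam == pytest.approx(6.0, abs=1e-8)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.05, max_value=1.0), min_size=2, max_size=10)
    )
    def test_eigenvector_recovery_property(self, raw):
        w_true = np.array(raw) / np.sum(raw)
        mat = m.PairwiseComparisonMatrix.consistent_from_weights(w_true)
        w, _ = principal_weights(mat)
        np.testing.assert_allclose(w, w_true, atol=1e-8)

    def test_scale_invariance(self):
        # doubling one item's underlying weight rescales consistently;
        # the recovered vector is the renormalized scaled truth
        w_true = np.array([0.5, 0.3, 0.2])
        scaled = w_true * np.array([2.0, 1.0, 1.0])
        mat = m.PairwiseComparisonMatrix.consistent_from_weights(scaled)
        w, _ = principal_weights(mat)
        np.testing.assert_allclose(w, scaled / scaled.sum(), atol=1e-10)

    def test_matches_dense_eigensolver(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(3, 8))
            mat = random_reciprocal_matrix(rng, n)
            _, lam = principal_weights(mat)
            lam_np = np.max(np.real(np.linalg.eigvals(mat.values)))
            assert lam == pytest.approx(lam_np, abs=1e-8)

    def test_agrees_with_row_geometric_mean_on_consistent(self):
        mat = m.PairwiseComparisonMatrix.consistent_from_weights([0.6, 0.25, 0.1, 0.05])
        w_eig, _ = principal_weights(mat)
        np.testing.assert_allclose(w_eig, row_geometric_mean_weights(mat), atol=1e-9)


class TestMatrixValidation:
    def test_rejects_nonreciprocal_naming_cell(self):
        with pytest.raises(m.ValidationError, match=r"\(0, 1\)"):
            m.PairwiseComparisonMatrix([[1, 2, 1], [1, 1, 1], [1, 1, 1]])

    def test_rejects_out_of_scale(self):
        with pytest.raises(m.ValidationError, match="Saaty scale"):
            m.PairwiseComparisonMatrix([[1, 12], [1 / 12, 1]])

    def test_permissive_scale_warns(self):
        with pytest.warns(UserWarning, match="Saaty"):
            m.PairwiseComparisonMatrix([[1, 12], [1 / 12, 1]], permissive_scale=True)

    def test_rejects_bad_diagonal(self):
        with pytest.raises(m.ValidationError, match="diagonal"):
            m.PairwiseComparisonMatrix([[2, 2], [0.5, 1]])

    def test_from_upper_fills_reciprocals(self):
        mat = m.PairwiseComparisonMatrix.from_upper({(0, 1): 3, (0, 2): 5, (1, 2): 2}, 3)
        assert mat.values[1, 0] == pytest.approx(1 / 3)
        assert mat.values[2, 0] == pytest.approx(1 / 5)

    def test_from_upper_rejects_incomplete(self):
        with pytest.raises(m.ValidationError, match="missing"):
            m.PairwiseComparisonMatrix.from_upper({(0, 1): 3}, 3)


class TestConsistency:
    def test_consistent_matrix_cr_zero(self):
        mat = m.PairwiseComparisonMatrix.consistent_from_weights([0.5, 0.3, 0.2])
        rep = consistency(mat)
        assert rep.consistency_index == pytest.approx(0.0, abs=1e-9)
        assert rep.consistency_ratio == pytest.approx(0.0, abs=1e-9)
        assert rep.acceptable

    def test_inconsistent_3x3_against_char_poly_oracle(self):
        # independent oracle: lambda_max as the largest root of the cubic
        # characteristic polynomial, coefficients from trace / principal
        # minors / determinant arithmetic
        a = np.array([[1, 2, 0.5], [0.5, 1, 4], [2, 0.25, 1]])
        mat = m.PairwiseComparisonMatrix(a)
        rep = consistency(mat)
        tr = a[0, 0] + a[1, 1] + a[2, 2]
        minors = (
            (a[1, 1] * a[2, 2] - a[1, 2] * a[2, 1])
            + (a[0, 0] * a[2, 2] - a[0, 2] * a[2, 0])
            + (a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0])
        )
        det = (
            a[0, 0] * (a[1, 1] * a[2, 2] - a[1, 2] * a[2, 1])
            - a[0, 1] * (a[1, 0] * a[2, 2] - a[1, 2] * a[2, 0])
            + a[0, 2] * (a[1, 0] * a[2, 1] - a[1, 1] * a[2, 0])
        )
        roots = np.roots([1.0, -tr, minors, -det])
        lam_oracle = max(r.real for r in roots if abs(r.imag) < 1e-9)
        assert rep.lambda_max == pytest.approx(lam_oracle, abs=1e-9)
        assert rep.consistency_ratio == pytest.approx(
            (lam_oracle - 3) / 2 / RANDOM_INDEX[3], abs=1e-9
        )
        assert not rep.acceptable  # heavily inconsistent judgments

    def test_2x2_always_consistent(self):
        rep = consistency(m.PairwiseComparisonMatrix([[1, 7], [1 / 7, 1]]))
        assert rep.consistency_ratio == 0.0
        assert rep.acceptable

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_cr_monotone_in_perturbation(self, n):
        rng = np.random.default_rng(n)
        w = rng.uniform(0.1, 1.0, n)
        base = m.PairwiseComparisonMatrix.consistent_from_weights(w / w.sum())
        last_cr = consistency(base).consistency_ratio
        assert last_cr == pytest.approx(0.0, abs=1e-9)
        for phi in (1.5, 2.0, 3.0, 5.0):
            a = base.values.copy()
            a[0, 1] *= phi
            a[1, 0] = 1.0 / a[0, 1]
            cr = consistency(
                m.PairwiseComparisonMatrix(a, permissive_scale=True)
            ).consistency_ratio
            assert cr > last_cr
            last_cr = cr

    def test_lambda_max_at_least_n(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            mat = random_reciprocal_matrix(rng, int(rng.integers(3, 7)))
            rep = consistency(mat)
            assert rep.lambda_max >= rep.n - 1e-9

    def test_order_outside_ri_table_rejected(self):
        mat = m.PairwiseComparisonMatrix(np.ones((16, 16)))
        with pytest.raises(m.ConfigurationError, match="random index"):
            consistency(mat)


class TestAggregation:
    def test_identical_matrices_idempotent(self):
        mat = m.PairwiseComparisonMatrix([[1, 3], [1 / 3, 1]])
        agg = aggregate_judgments([mat] * 5)
        np.testing.assert_allclose(agg.values, mat.values, atol=1e-12)

    def test_unweighted_geometric_mean(self):
        m1 = m.PairwiseComparisonMatrix([[1, 2], [0.5, 1]])
        m2 = m.PairwiseComparisonMatrix([[1, 8], [0.125, 1]])
        agg = aggregate_judgments([m1, m2])
        assert agg.values[0, 1] == pytest.approx(4.0, abs=1e-12)

    def test_authority_weighted_geometric_mean(self):
        # Cr weights 0.9 and 0.3 -> exponents 0.75 and 0.25:
        # 2^0.75 * 8^0.25 = 2^0.75 * 2^0.75 = 2^1.5
        m1 = m.PairwiseComparisonMatrix([[1, 2], [0.5, 1]])
        m2 = m.PairwiseComparisonMatrix([[1, 8], [0.125, 1]])
        agg = aggregate_judgments([m1, m2], expert_weights=[0.9, 0.3])
        assert agg.values[0, 1] == pytest.approx(2**1.5, abs=1e-12)

    def test_reciprocity_exact_after_aggregation(self):
        rng = np.random.default_rng(3)
        mats = [random_reciprocal_matrix(rng, 5) for _ in range(9)]
        agg = aggregate_judgments(mats)
        # reciprocity holds exactly by construction: the lower triangle is
        # the literal float reciprocal of the upper triangle
        for i in range(5):
            for j in range(i + 1, 5):
                assert agg.values[j, i] == 1.0 / agg.values[i, j]

    def test_empty_and_mismatched_rejected(self):
        with pytest.raises(m.ValidationError):
            aggregate_judgments([])
        with pytest.raises(m.ValidationError, match="orders differ"):
            aggregate_judgments(
                [
                    m.PairwiseComparisonMatrix(np.ones((2, 2))),
                    m.PairwiseComparisonMatrix(np.ones((3, 3))),
                ]
            )


class TestAuthority:
    @pytest.mark.parametrize(
        "ca, cs, expected", [(0.9, 0.8, 0.85), (1.0, 1.0, 1.0), (0.0, 0.5, 0.25)]
    )
    def test_cr_is_mean(self, ca, cs, expected):
        assert authority_coefficient(ca, cs) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(m.ValidationError):
            authority_coefficient(1.2, 0.5)

    def test_panel_authoritative_flag(self):
        experts = [m.ExpertProfile(f"e{i}", 0.9, 0.85) for i in range(17)]
        assert panel_authoritative(experts)
        experts.append(m.ExpertProfile("junior", 0.5, 0.5))
        assert not panel_authoritative(experts)


def test_saaty_levels_cover_scale():
    assert min(SAATY_LEVELS) == pytest.approx(1 / 9)
    assert max(SAATY_LEVELS) == 9
    assert 1.0 in SAATY_LEVELS
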