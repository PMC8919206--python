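import numpy as np
import pandas as pd
import pytest

from oracles import (naive_genorm_iterative, naive_pair_variation,
                     naive_v_profile)
from refstab.cq import CqMatrix
from refstab.genorm import (
    genorm_pair_variation, genorm_rank, normalization_factor,
    pairwise_variation_profile, to_relative_quantities,
)


class TestRelativeQuantities:
    def test_one_cycle_is_one_halving(self):
        m = CqMatrix(pd.DataFrame([[20.0, 21.0, 22.0], [20.0, 20.0, 20.0],
                                   [25.0, 24.0, 23.0]],
                                  index=["A", "B", "C"]))
        q = to_relative_quantities(m, 2.0)
        assert list(q.q.loc["A"]) == pytest.approx([1.0, 0.5, 0.25])

    def test_constant_row_all_ones(self):
        m = CqMatrix(pd.DataFrame([[20.0] * 4, [25.0] * 4, [30.0] * 4]))
        q = to_relative_quantities(m)
        assert np.allclose(q.q.to_numpy(), 1.0)

    def test_measured_factor(self):
        m = CqMatrix(pd.DataFrame([[20.0, 21.0], [18.0, 19.0], [30.0, 31.0]],
                                  index=["A", "B", "C"]))
        q = to_relative_quantities(m, {"A": 1.948, "B": 2.0, "C": 2.0})
        assert q.q.loc["A"].to_numpy() == pytest.approx([1.0, 1.0 / 1.948])

    def test_all_q_in_unit_interval_with_max_at_one(self, random_matrix_factory):
        q = to_relative_quantities(random_matrix_factory(seed=3), 2.0)
        arr = q.q.to_numpy()
        assert (arr > 0).all() and (arr <= 1.0).all()
        assert np.allclose(arr.max(axis=1), 1.0)

    def test_factor_below_one_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            to_relative_quantities(toy_matrix, 0.9)


class TestPairVariation:
    def test_constant_offset_pair_is_zero(self):
        m = CqMatrix(pd.DataFrame([[20.0, 21.0, 22.0], [23.0, 24.0, 25.0],
                                   [20.0, 25.0, 21.0]], index=["A", "B", "C"]))
        q = to_relative_quantities(m)
        assert genorm_pair_variation(q, "A", "B") == pytest.approx(0.0, abs=1e-12)

    def test_toy_values(self, toy_matrix):
        q = to_relative_quantities(toy_matrix)
        assert genorm_pair_variation(q, "A", "B") == pytest.approx(0.08165, abs=1e-5)
        assert genorm_pair_variation(q, "A", "C") == pytest.approx(0.64550, abs=1e-5)
        assert genorm_pair_variation(q, "B", "C") == pytest.approx(0.56862, abs=1e-5)

    def test_sample_permutation_invariant(self, toy_matrix):
        q = to_relative_quantities(toy_matrix)
        perm = CqMatrix(toy_matrix.values[["s3", "s1", "s4", "s2"]])
        qp = to_relative_quantities(perm)
        assert genorm_pair_variation(q, "A", "C") == pytest.approx(
            genorm_pair_variation(qp, "A", "C"), abs=1e-14)

    def test_same_gene_rejected(self, toy_matrix):
        q = to_relative_quantities(toy_matrix)
        with pytest.raises(ValueError):
            genorm_pair_variation(q, "A", "A")


class TestGenormRank:
    def test_toy_iterative_exclusion(self, toy_matrix):
        res = genorm_rank(to_relative_quantities(toy_matrix))
        assert res.m_values["C"] == pytest.approx(0.60706, abs=1e-5)
        assert res.m_values["A"] == pytest.approx(0.08165, abs=1e-5)
        assert res.m_values["A"] == res.m_values["B"]
        assert list(res.ranks[["A", "B", "C"]]) == [1, 1, 3]
        assert res.exclusion_order["C"] == 1

    def test_top_two_always_tie(self, random_matrix_factory):
        for seed in range(5):
            res = genorm_rank(to_relative_quantities(
                random_matrix_factory(n_genes=6, n_samples=10, seed=seed)))
            top = res.m_values[res.ranks == 1]
            assert len(top) >= 2
            assert top.nunique() == 1

    def test_matches_naive_iterative_oracle(self, random_matrix_factory):
        for seed in range(10):
            q = to_relative_quantities(random_matrix_factory(seed=seed))
            res = genorm_rank(q)
            expected, _ = naive_genorm_iterative(q.q)
            assert np.allclose(res.m_values.to_numpy(), expected.to_numpy(),
                               atol=1e-10)

    def test_loading_shift_invariance(self, random_matrix_factory):
        m = random_matrix_factory(seed=11)
        shift = np.random.default_rng(1).normal(0, 2, m.n_samples)
        shifted = CqMatrix(m.values + shift)
        r1 = genorm_rank(to_relative_quantities(m))
        r2 = genorm_rank(to_relative_quantities(shifted))
        assert np.allclose(r1.m_values.to_numpy(), r2.m_values.to_numpy(),
                           atol=1e-12)

    def test_per_gene_offset_invariance(self, random_matrix_factory):
        m = random_matrix_factory(seed=12)
        offs = np.random.default_rng(2).normal(0, 3, m.n_genes)
        shifted = CqMatrix(m.values.add(offs, axis=0))
        r1 = genorm_rank(to_relative_quantities(m))
        r2 = genorm_rank(to_relative_quantities(shifted))
        assert np.allclose(r1.m_values.to_numpy(), r2.m_values.to_numpy(),
                           atol=1e-12)

    def test_two_genes_rejected(self):
        m = CqMatrix(pd.DataFrame([[20.0, 21.0, 22.0], [25.0, 24.0, 26.0]]))
        with pytest.raises(ValueError):
            genorm_rank(to_relative_quantities(m))


class TestNormalizationFactor:
    def test_single_gene_is_its_q(self, toy_matrix):
        q = to_relative_quantities(toy_matrix)
        nf = normalization_factor(q, ["A"])
        assert np.allclose(nf.nf.to_numpy(), q.q.loc["A"].to_numpy())

    def test_reciprocal_pair_gives_constant(self):
        qdf = pd.DataFrame([[1.0, 0.5, 0.25], [0.25, 0.5, 1.0]],
                           index=["A", "B"], columns=["s1", "s2", "s3"])
        from refstab.genorm import RelativeQuantityMatrix
        q = RelativeQuantityMatrix(qdf, pd.Series(2.0, index=["A", "B"]))
        nf = normalization_factor(q, ["A", "B"])
        assert np.allclose(nf.nf.to_numpy(), 0.5)

    def test_top_pair_matches_brute_force(self, toy_matrix):
        q = to_relative_quantities(toy_matrix)
        nf = normalization_factor(q, ["A", "B"])
        expected = np.sqrt(q.q.loc["A"].to_numpy() * q.q.loc["B"].to_numpy())
        assert np.allclose(nf.nf.to_numpy(), expected, atol=1e-14)


class TestPairwiseVariationProfile:
    def test_scalar_multiple_genes_give_zero_profile(self):
        base = np.array([20.0, 21.0, 22.5, 19.0, 23.0])
        m = CqMatrix(pd.DataFrame([base, base + 2, base + 4, base - 1],
                                  index=list("ABCD")))
        q = to_relative_quantities(m)
        prof = pairwise_variation_profile(q)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in prof.v_values.values())
        assert prof.recommended_n == 2

    def test_matches_naive_oracle(self, random_matrix_factory):
        q = to_relative_quantities(random_matrix_factory(n_genes=6, n_samples=12,
                                                         seed=21))
        ranking = genorm_rank(q)
        prof = pairwise_variation_profile(q, ranking)
        expected = naive_v_profile(q.q, ranking.stability_order)
        assert set(prof.v_values) == set(expected) == {2, 3, 4, 5}
        for n in expected:
            assert prof.v_values[n] == pytest.approx(expected[n], abs=1e-12)

    def test_recommended_n_none_when_all_above_threshold(self, random_matrix_factory):
        q = to_relative_quantities(random_matrix_factory(seed=5))
        prof = pairwise_variation_profile(q, threshold=1e-9)
        assert prof.recommended_n is None
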