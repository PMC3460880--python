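"""Closed-form and permutation null models for overlap significance."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleioscan.overlap import OverlapResult
from pleioscan.significance import (
    OverlapTest,
    WeightedPool,
    build_weighted_pool,
    hypergeom_pvalue,
    monte_carlo_pvalue,
    score_all_overlaps,
    weighted_permutation_pvalue,
    weighted_sample_memberships,
)


def exact_hypergeom_tail(k, N, n1, n2):
    """Independent enumeration oracle: sum the hypergeometric pmf directly."""
    total = 0.0
    for x in range(k, min(n1, n2) + 1):
        total += (
            math.comb(n1, x) * math.comb(N - n1, n2 - x) / math.comb(N, n2)
        )
    return total


class TestClosedForm:
    @pytest.mark.parametrize(
        "sizes,k,expected",
        [
            ((85, 101, 105, 141), 1, 0.002),  # BP/CAD/CKD/Lipids 4-way
            ((219, 105, 137), 2, 0.015),  # Obesity/CKD/T2D
            ((101, 219, 137), 1, 0.165),  # CAD/Obesity/T2D
        ],
    )
    def test_multiway_values_at_catalog_list_sizes(self, sizes, k, expected):
        p = hypergeom_pvalue(OverlapTest(sizes, 4105, k))
        assert round(p, 3) == expected

    def test_two_way_cad_lipids_overlap_is_extreme(self):
        assert hypergeom_pvalue(OverlapTest((101, 141), 4105, 14)) < 0.001

    def test_k_zero_tail_is_one(self):
        assert hypergeom_pvalue(OverlapTest((10, 20, 30), 100, 0)) == 1.0

    def test_k_above_min_size_rejected(self):
        with pytest.raises(ValueError):
            OverlapTest((5, 50), 100, 6)

    @given(
        n1=st.integers(1, 40),
        n2=st.integers(1, 40),
        N=st.integers(50, 500),
        frac=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_two_way_matches_enumeration_oracle(self, n1, n2, N, frac):
        k = max(1, round(frac * min(n1, n2)))
        p = hypergeom_pvalue(OverlapTest((n1, n2), N, k))
        assert p == pytest.approx(exact_hypergeom_tail(k, N, n1, n2), rel=1e-9)

    def test_monotone_decreasing_in_k(self):
        ps = [hypergeom_pvalue(OverlapTest((30, 40, 50), 400, k)) for k in range(6)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_monotone_increasing_in_list_size(self):
        ps = [hypergeom_pvalue(OverlapTest((n, 40, 50), 400, 2)) for n in (10, 20, 30)]
        assert ps == sorted(ps)

    def test_monte_carlo_agrees_on_small_instance(self):
        test = OverlapTest((20, 30), 100, 8)
        exact = hypergeom_pvalue(test)
        mc, se = monte_carlo_pvalue(test, draws=20_000, rng=5)
        assert abs(mc - exact) < 3 * se


class TestWeightedPool:
    def _rows(self, tuples):
        return pd.DataFrame(tuples, columns=["gene", "snp_id", "phenotype"])

    def test_three_snps_one_phenotype_weight_three(self):
        pool = build_weighted_pool(
            self._rows([("G", "rs1", "BP"), ("G", "rs2", "BP"), ("G", "rs3", "BP")])
        )
        assert pool.weights["G"] == 3

    def test_one_snp_two_phenotypes_weight_two(self):
        pool = build_weighted_pool(self._rows([("G", "rs1", "BP"), ("G", "rs1", "CKD")]))
        assert pool.weights["G"] == 2

    def test_duplicate_appearances_not_double_counted(self):
        pool = build_weighted_pool(
            self._rows([("G", "rs1", "BP"), ("G", "rs1", "BP"), ("H", "rs2", "BP")])
        )
        assert pool.weights == {"G": 1, "H": 1}

    def test_weights_below_one_rejected(self):
        with pytest.raises(ValueError):
            WeightedPool({"G": 0})


class TestWeightedSampling:
    def test_sample_size_and_shape(self):
        rng = np.random.default_rng(0)
        mem = weighted_sample_memberships(rng, np.ones(30), 7, 50)
        assert mem.shape == (50, 30)
        assert (mem.sum(axis=1) == 7).all()

    def test_size_exceeding_pool_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            weighted_sample_memberships(rng, np.ones(5), 6, 1)

    def test_weight_proportional_first_order_inclusion(self):
        """A gene with double weight is included more often (n=1 draws make
        inclusion probability exactly proportional to weight)."""
        rng = np.random.default_rng(1)
        w = np.array([2.0] + [1.0] * 9)  # total 11
        mem = weighted_sample_memberships(rng, w, 1, 40_000)
        freq = mem.mean(axis=0)
        assert freq[0] == pytest.approx(2 / 11, abs=0.01)
        assert freq[1:].mean() == pytest.approx(1 / 11, abs=0.005)


class TestPermutationPvalue:
    POOL = WeightedPool({f"g{i}": 1 for i in range(60)})

    def test_k_zero_gives_one(self):
        assert weighted_permutation_pvalue(self.POOL, (10, 10), 0, replicates=200) == 1.0

    def test_never_below_add_one_floor(self):
        p = weighted_permutation_pvalue(self.POOL, (5, 5), 5, replicates=500, seed=3)
        assert p >= 1 / 501

    def test_reproducible_given_seed(self):
        args = (self.POOL, (10, 12), 3)
        a = weighted_permutation_pvalue(*args, replicates=1000, seed=11)
        b = weighted_permutation_pvalue(*args, replicates=1000, seed=11)
        assert a == b

    def test_uniform_weights_match_hypergeometric_tail(self):
        """With uniform weights and m=2 the permutation null *is* the
        hypergeometric null, up to binomial resampling error."""
        N, n1, n2, k, R = 80, 15, 20, 7, 4000
        pool = WeightedPool({f"g{i}": 1 for i in range(N)})
        exact = exact_hypergeom_tail(k, N, n1, n2)
        p = weighted_permutation_pvalue(pool, (n1, n2), k, replicates=R, seed=7)
        se = math.sqrt(exact * (1 - exact) / R)
        assert abs(p - exact) < 3 * se + 1 / (R + 1)

    def test_concentrated_weight_inflates_null_intersections(self):
        """Extra weight on one gene present in every list makes large
        intersections more likely under the null, so p grows."""
        N, sizes, k, R = 50, (8, 8, 8), 2, 3000
        uniform = WeightedPool({f"g{i}": 1 for i in range(N)})
        skewed = WeightedPool({f"g{i}": (25 if i == 0 else 1) for i in range(N)})
        p_u = weighted_permutation_pvalue(uniform, sizes, k, replicates=R, seed=13)
        p_w = weighted_permutation_pvalue(skewed, sizes, k, replicates=R, seed=13)
        assert p_w >= p_u

    def test_list_size_exceeding_pool_rejected(self):
        with pytest.raises(ValueError):
            weighted_permutation_pvalue(self.POOL, (61, 5), 1, replicates=10)


class TestScoreAllOverlaps:
    def _overlap(self, phen, sizes, genes, N=200):
        return OverlapResult(
            phenotypes=phen, shared_genes=genes, list_sizes=sizes, pool_size=N
        )

    def test_empty_input_empty_output(self):
        assert score_all_overlaps([], None) == []

    def test_deterministic_given_seed(self):
        pool = WeightedPool({f"g{i}": 1 for i in range(200)})
        ovs = [
            self._overlap(("BP", "CAD"), (20, 30), {"g1", "g2"}),
            self._overlap(("BP", "CAD", "CKD"), (20, 30, 25), {"g1"}),
        ]
        r1 = score_all_overlaps(ovs, pool, replicates=500, seed=9)
        r2 = score_all_overlaps(ovs, pool, replicates=500, seed=9)
        assert [x.permutation_p for x in r1] == [x.permutation_p for x in r2]

    def test_substreams_stable_under_added_combination(self):
        """Scoring an extra combination must not perturb existing ones."""
        pool = WeightedPool({f"g{i}": 1 for i in range(200)})
        a = self._overlap(("BP", "CAD"), (20, 30), {"g1"})
        b = self._overlap(("T2D", "CKD"), (25, 25), {"g2"})
        alone = score_all_overlaps([a], pool, replicates=500, seed=9)
        together = score_all_overlaps([a, b], pool, replicates=500, seed=9)
        assert alone[0].permutation_p == together[0].permutation_p

    def test_both_pvalues_populated(self):
        pool = WeightedPool({f"g{i}": 1 for i in range(200)})
        res = score_all_overlaps(
            [self._overlap(("BP", "CAD"), (20, 30), {"g1"})], pool, replicates=300
        )[0]
        assert 0 < res.hypergeom_p <= 1
        assert 0 < res.permutation_p <= 1
        assert res.replicates == 300
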