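import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from samgsr import (ConnectivityWeights, InputError, estimate_s0,
                    permutation_pvalue, sam_statistics, samgs_score)
from tests.conftest import make_dataset


class TestEstimateS0:
    @pytest.mark.parametrize("s, expected", [
        ([1, 2, 3], 2.0),
        ([0, 0, 0], 1e-6),
        ([0.1, 0.4, 0.2, 0.9], 0.3),
        ([0, 0, 5.0], 5.0),  # zeros excluded from the median
    ])
    def test_examples(self, s, expected):
        assert estimate_s0(np.array(s, float)) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            estimate_s0(np.array([]))


class TestSamStatistics:
    def test_identical_group_means_give_zero(self):
        ds = make_dataset([[1.0, 2.0, 1.0, 2.0]], ["d", "d", "c", "c"])
        st_ = sam_statistics(ds, "d", "c", s0=0.5)
        assert st_.d[0] == 0.0

    def test_label_swap_negates_d(self, planted_dataset):
        a = sam_statistics(planted_dataset, "d", "c", s0=0.5)
        b = sam_statistics(planted_dataset, "c", "d", s0=0.5)
        np.testing.assert_allclose(a.d, -b.d)

    def test_hand_pooled_sd_case(self):
        # case (2,2), control (0,0): zero within-group variance, d = 2/s0
        ds = make_dataset([[2.0, 2.0, 0.0, 0.0]], ["d", "d", "c", "c"])
        st_ = sam_statistics(ds, "d", "c", s0=0.5)
        assert st_.s[0] == 0.0
        assert st_.d[0] == pytest.approx(4.0)

    def test_pooled_sd_formula(self):
        # hand evaluation: case (1,3), control (0,0), nd=nc=2
        ds = make_dataset([[1.0, 3.0, 0.0, 0.0]], ["d", "d", "c", "c"])
        st_ = sam_statistics(ds, "d", "c", s0=0.5)
        s_expected = math.sqrt((1 / 2 + 1 / 2) * (2.0 + 0.0) / 2)
        assert st_.s[0] == pytest.approx(s_expected)
        assert st_.d[0] == pytest.approx(2.0 / (s_expected + 0.5))

    def test_small_class_rejected(self):
        ds = make_dataset([[1.0, 2.0, 3.0]], ["d", "c", "c"])
        with pytest.raises(InputError):
            sam_statistics(ds, "d", "c")

    def test_unknown_label_rejected(self, planted_dataset):
        with pytest.raises(InputError):
            sam_statistics(planted_dataset, "d", "nope")

    def test_weighted_effective_statistic(self, planted_dataset):
        w = ConnectivityWeights(planted_dataset.gene_ids,
                                np.arange(1, 31, dtype=float))
        st_ = sam_statistics(planted_dataset, "d", "c", weights=w)
        np.testing.assert_allclose(st_.d_effective,
                                   np.arange(1, 31) * st_.d)

    def test_unweighted_effective_equals_d(self, planted_dataset):
        st_ = sam_statistics(planted_dataset, "d", "c")
        np.testing.assert_array_equal(st_.d_effective, st_.d)


class TestSamgsScore:
    def test_examples(self, planted_dataset):
        st_ = sam_statistics(planted_dataset, "d", "c", s0=0.5)
        st_.d_effective = np.array([3.0] + [0.0] * 29)
        assert samgs_score(st_, ["g1"]) == pytest.approx(9.0)
        st_.d_effective = np.array([1.0, -2.0, 2.0] + [0.0] * 27)
        assert samgs_score(st_, ["g1", "g2", "g3"]) == pytest.approx(9.0)

    def test_uniform_weight_homogeneity(self, planted_dataset):
        members = planted_dataset.gene_ids[:5]
        base = samgs_score(sam_statistics(planted_dataset, "d", "c", s0=0.5),
                           members)
        w = ConnectivityWeights.uniform(planted_dataset.gene_ids, 3.0)
        scaled = samgs_score(
            sam_statistics(planted_dataset, "d", "c", s0=0.5, weights=w),
            members)
        assert scaled == pytest.approx(9.0 * base)

    def test_empty_members_rejected(self, planted_dataset):
        with pytest.raises(InputError):
            samgs_score(sam_statistics(planted_dataset, "d", "c"), [])


def naive_exact_pvalue(values, n_case, members_idx, s0):
    """Independent oracle: enumerate every case-assignment with plain loops."""
    n = values.shape[1]

    def score(case):
        ctrl = [j for j in range(n) if j not in case]
        total = 0.0
        for i in members_idx:
            xd = [values[i][j] for j in case]
            xc = [values[i][j] for j in ctrl]
            md, mc = sum(xd) / len(xd), sum(xc) / len(xc)
            ss = sum((x - md) ** 2 for x in xd) + sum((x - mc) ** 2 for x in xc)
            s = math.sqrt((1 / len(xd) + 1 / len(xc)) * ss / (n - 2))
            total += ((md - mc) / (s + s0)) ** 2
        return total

    observed = score(set(range(n_case)))  # true cases are the first columns
    assigns = [set(c) for c in combinations(range(n), n_case)]
    count = sum(1 for a in assigns if score(a) >= observed - 1e-12)
    return count / len(assigns)


class TestPermutationPvalue:
    def test_constant_matrix_gives_p_one(self):
        ds = make_dataset(np.zeros((3, 8)), ["d"] * 4 + ["c"] * 4)
        res = permutation_pvalue(ds, "d", "c", ["g1", "g2"], B=50, seed=1)
        assert res.p_value == 1.0

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        values = rng.standard_normal((3, 4))
        values[0, :2] += 1.5
        ds = make_dataset(values, ["d", "d", "c", "c"])
        for members in (["g1"], ["g1", "g2"], ["g1", "g2", "g3"]):
            res = permutation_pvalue(ds, "d", "c", members, s0=0.5, exact=True)
            idx = [int(m[1:]) - 1 for m in members]
            expected = naive_exact_pvalue(values, 2, idx, 0.5)
            assert res.p_value == pytest.approx(expected, abs=1e-12)
            assert res.B == 6  # C(4, 2) label assignments

    def test_add_one_lower_bound(self, planted_dataset):
        res = permutation_pvalue(planted_dataset, "d", "c", ["g3"], B=19, seed=0)
        assert res.p_value >= 1 / 20

    def test_label_swap_invariance(self, planted_dataset):
        members = planted_dataset.gene_ids[:5]
        a = permutation_pvalue(planted_dataset, "d", "c", members, B=99, seed=7)
        b = permutation_pvalue(planted_dataset, "c", "d", members, B=99, seed=7)
        assert a.p_value == b.p_value
        assert a.observed_score == pytest.approx(b.observed_score)

    def test_uniform_weight_pvalues_identical(self, planted_dataset):
        members = planted_dataset.gene_ids[:5]
        w = ConnectivityWeights.uniform(planted_dataset.gene_ids, 4.0)
        a = permutation_pvalue(planted_dataset, "d", "c", members, B=99, seed=3)
        b = permutation_pvalue(planted_dataset, "d", "c", members, weights=w,
                               B=99, seed=3)
        assert a.p_value == b.p_value

    def test_gene_order_invariance(self, planted_dataset):
        members = planted_dataset.gene_ids[:5]
        perm = np.random.default_rng(0).permutation(planted_dataset.n_genes)
        shuffled = planted_dataset.subset_genes(
            [planted_dataset.gene_ids[i] for i in perm])
        a = permutation_pvalue(planted_dataset, "d", "c", members, B=49, seed=2)
        b = permutation_pvalue(shuffled, "d", "c", members, B=49, seed=2)
        assert a.p_value == b.p_value

    def test_deterministic_given_seed(self, planted_dataset):
        members = planted_dataset.gene_ids[:4]
        a = permutation_pvalue(planted_dataset, "d", "c", members, B=49, seed=9)
        b = permutation_pvalue(planted_dataset, "d", "c", members, B=49, seed=9)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null_scores, b.null_scores)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(1, 2**31 - 2))
    def test_pvalue_bounds_property(self, seed):
        rng = np.random.default_rng(seed % 10_000)
        ds = make_dataset(rng.standard_normal((4, 10)),
                          ["d"] * 5 + ["c"] * 5)
        res = permutation_pvalue(ds, "d", "c", ["g1", "g2"], B=20, seed=seed)
        assert 1 / 21 <= res.p_value <= 1.0
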