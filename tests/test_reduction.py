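import math
from itertools import combinations

import numpy as np
import pytest

from samgsr import (ConnectivityWeights, GeneSetCollection, reduce_gene_set,
                    sam_statistics, select_significant_sets)
from tests.conftest import make_dataset


@pytest.fixture(scope="module")
def two_signal_dataset():
    """10 genes x 12 samples; g1, g2 carry a +3 shift in the case group."""
    rng = np.random.default_rng(11)
    values = rng.standard_normal((10, 12))
    values[0, :6] += 3.0
    values[1, :6] += 3.0
    return make_dataset(values, ["d"] * 6 + ["c"] * 6)


def naive_exact_residual_pvalues(ds, members, s0):
    """Oracle: for every k, exact enumeration p-value of the residual subset,
    computed with plain loops, independent of the package's permutation code."""
    n = ds.n_samples
    values = ds.values
    case = set(j for j, l in enumerate(ds.labels) if l == "d")

    def d_stat(i, case_set):
        ctrl = [j for j in range(n) if j not in case_set]
        xd = [values[i][j] for j in case_set]
        xc = [values[i][j] for j in ctrl]
        md, mc = sum(xd) / len(xd), sum(xc) / len(xc)
        ss = sum((x - md) ** 2 for x in xd) + sum((x - mc) ** 2 for x in xc)
        s = math.sqrt((1 / len(xd) + 1 / len(xc)) * ss / (n - 2))
        return (md - mc) / (s + s0)

    idx = {g: i for i, g in enumerate(ds.gene_ids)}
    ranked = sorted(members, key=lambda g: (-abs(d_stat(idx[g], case)), g))
    assigns = [set(c) for c in combinations(range(n), len(case))]
    pvals = []
    for k in range(1, len(ranked)):
        residual = [idx[g] for g in ranked[k:]]

        def score(case_set):
            return sum(d_stat(i, case_set) ** 2 for i in residual)

        observed = score(case)
        count = sum(1 for a in assigns if score(a) >= observed - 1e-9)
        pvals.append(count / len(assigns))
    return ranked, pvals


class TestReduceGeneSet:
    def test_ck_zero_keeps_only_top_gene(self, two_signal_dataset):
        ds = two_signal_dataset
        stats = sam_statistics(ds, "d", "c")
        trace = reduce_gene_set(ds, "d", "c", ds.gene_ids, stats, c_k=0.0,
                                B=50, seed=1)
        assert trace.stop_k == 1
        assert trace.core == [trace.ranked_genes[0]]

    def test_ck_one_keeps_entire_set(self, two_signal_dataset):
        ds = two_signal_dataset
        stats = sam_statistics(ds, "d", "c")
        trace = reduce_gene_set(ds, "d", "c", ds.gene_ids, stats, c_k=1.0,
                                B=50, seed=1)
        assert trace.stop_k == len(ds.gene_ids)
        assert trace.core == trace.ranked_genes

    def test_singleton_set(self, two_signal_dataset):
        ds = two_signal_dataset
        stats = sam_statistics(ds, "d", "c")
        trace = reduce_gene_set(ds, "d", "c", ["g1"], stats, c_k=0.05,
                                B=50, seed=1)
        assert trace.core == ["g1"]
        assert trace.residual_pvalues == []

    def test_stop_matches_brute_force_oracle(self, two_signal_dataset):
        """Two strongly shifted genes among eight noise genes: the residual
        loses significance exactly after both signal genes are removed."""
        ds = two_signal_dataset
        stats = sam_statistics(ds, "d", "c")
        ranked_oracle, pvals_oracle = naive_exact_residual_pvalues(
            ds, list(ds.gene_ids), stats.s0)
        stop_oracle = next(
            (k for k, p in enumerate(pvals_oracle, start=1) if p > 0.05),
            len(ranked_oracle))
        assert stop_oracle == 2  # oracle confirms the planted design
        trace = reduce_gene_set(ds, "d", "c", list(ds.gene_ids), stats,
                                c_k=0.05, B=400, seed=3)
        assert trace.ranked_genes == ranked_oracle
        assert trace.stop_k == stop_oracle
        assert set(trace.core) == {"g1", "g2"}

    def test_core_size_monotone_in_ck(self, two_signal_dataset):
        ds = two_signal_dataset
        stats = sam_statistics(ds, "d", "c")
        sizes = []
        for ck in (0.0, 0.01, 0.05, 0.2, 0.5, 1.0):
            trace = reduce_gene_set(ds, "d", "c", list(ds.gene_ids), stats,
                                    c_k=ck, B=100, seed=5)
            sizes.append(trace.stop_k)
        assert sizes == sorted(sizes)

    def test_residual_pvalues_within_bounds(self, two_signal_dataset):
        ds = two_signal_dataset
        stats = sam_statistics(ds, "d", "c")
        B = 60
        trace = reduce_gene_set(ds, "d", "c", list(ds.gene_ids), stats,
                                c_k=0.5, B=B, seed=2)
        assert all(1 / (B + 1) <= p <= 1.0 for p in trace.residual_pvalues)

    def test_uniform_weights_reproduce_unweighted_trace(self, two_signal_dataset):
        ds = two_signal_dataset
        stats_u = sam_statistics(ds, "d", "c")
        w = ConnectivityWeights.uniform(ds.gene_ids, 2.0)
        stats_w = sam_statistics(ds, "d", "c", weights=w)
        tr_u = reduce_gene_set(ds, "d", "c", list(ds.gene_ids), stats_u,
                               c_k=0.1, B=100, seed=4)
        tr_w = reduce_gene_set(ds, "d", "c", list(ds.gene_ids), stats_w,
                               c_k=0.1, B=100, seed=4, weights=w)
        assert tr_u.ranked_genes == tr_w.ranked_genes
        assert tr_u.stop_k == tr_w.stop_k
        assert tr_u.residual_pvalues == tr_w.residual_pvalues

    def test_raising_weight_never_lowers_rank(self, two_signal_dataset):
        ds = two_signal_dataset
        base = np.ones(ds.n_genes)
        w1 = ConnectivityWeights(ds.gene_ids, base.copy())
        boosted = base.copy()
        boosted[5] = 10.0  # boost g6
        w2 = ConnectivityWeights(ds.gene_ids, boosted)
        from samgsr.reduction import rank_members
        r1 = rank_members(sam_statistics(ds, "d", "c", weights=w1),
                          list(ds.gene_ids))
        r2 = rank_members(sam_statistics(ds, "d", "c", weights=w2),
                          list(ds.gene_ids))
        assert r2.index("g6") <= r1.index("g6")


class TestSelectSignificantSets:
    def test_planted_signal_set_selected(self, planted_dataset, planted_sets):
        selected, table = select_significant_sets(
            planted_dataset, "d", "c", planted_sets, alpha=0.05, B=200, seed=1)
        assert "SIG" in selected

    def test_alpha_one_selects_everything(self, planted_dataset, planted_sets):
        selected, _ = select_significant_sets(
            planted_dataset, "d", "c", planted_sets, alpha=1.0, B=50, seed=1)
        assert set(selected) == set(planted_sets.names)

    def test_pvalue_table_complete(self, planted_dataset, planted_sets):
        _, table = select_significant_sets(
            planted_dataset, "d", "c", planted_sets, alpha=0.05, B=50, seed=1)
        assert list(table["set"]) == planted_sets.usable_names
        assert table["p_value"].between(0, 1).all()
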