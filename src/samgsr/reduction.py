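"""Core-subset extraction: rank genes inside a significant set and keep the
leading genes while the residual subset still carries signal.

Within a significant set the genes are ordered by decreasing |d_effective|.
For k = 1, 2, ... the set splits into the reduced subset R_k (first k genes)
and the residual Rbar_k (the rest); the residual's permutation p-value is
computed and the iteration stops the first time it exceeds the threshold
c_k. The core is R_k at that stop; if the residual never loses significance
the core is the entire set. c_k thus controls sparsity: c_k = 0 keeps only
the top gene, c_k = 1 keeps everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .io import ExpressionDataset, GeneSetCollection
from .network import ConnectivityWeights
from .stats import SamStatistics, permutation_pvalue

__all__ = ["ReductionTrace", "reduce_gene_set", "select_significant_sets"]


@dataclass
class ReductionTrace:
    """Per-set record of the reduction loop.

    ``residual_pvalues[k-1]`` is the permutation p-value of the residual
    after removing the top k genes; the loop stopped at ``stop_k`` and the
    core is the first ``stop_k`` ranked genes.
    """

    set_name: str
    ranked_genes: list[str]
    residual_pvalues: list[float]
    stop_k: int
    c_k: float
    d_effective: list[float] = field(default_factory=list)
    d: list[float] = field(default_factory=list)

    @property
    def core(self) -> list[str]:
        return self.ranked_genes[: self.stop_k]

    def to_frame(self) -> pd.DataFrame:
        m = len(self.ranked_genes)
        pvals = list(self.residual_pvalues) + [np.nan] * (m - len(self.residual_pvalues))
        return pd.DataFrame({
            "rank": np.arange(1, m + 1),
            "gene": self.ranked_genes,
            "d": self.d if self.d else [np.nan] * m,
            "d_effective": self.d_effective if self.d_effective else [np.nan] * m,
            "residual_p": pvals,
            "in_core": [i < self.stop_k for i in range(m)],
        })

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def rank_members(stats: SamStatistics, members) -> list[str]:
    """Members sorted by decreasing |d_effective|, ties broken by gene ID."""
    idx = stats.indices(members)
    mag = np.abs(stats.d_effective[idx])
    order = sorted(range(len(members)), key=lambda i: (-mag[i], members[i]))
    return [members[i] for i in order]


def reduce_gene_set(ds: ExpressionDataset, case_label: str, control_label: str,
                    members, stats: SamStatistics, c_k: float, B: int,
                    seed: int, set_name: str = "",
                    weights: ConnectivityWeights | None = None) -> ReductionTrace:
    """Extract the core subset of one significant gene set.

    ``stats`` must come from the same dataset/contrast (its s0 and
    d_effective drive the ranking and the residual tests). A singleton set's
    core is its single gene, with no residual test.
    """
    members = list(members)
    if not members:
        raise InputError("cannot reduce an empty gene set")
    if not 0.0 <= c_k <= 1.0:
        raise InputError("c_k must be in [0, 1]")
    ranked = rank_members(stats, members)
    idx = stats.indices(ranked)
    d_eff = [float(x) for x in stats.d_effective[idx]]
    d_raw = [float(x) for x in stats.d[idx]]
    if len(ranked) == 1:
        return ReductionTrace(set_name, ranked, [], 1, c_k, d_eff, d_raw)
    pvals = _residual_sequence(ds, case_label, control_label, ranked, stats,
                               weights, B, seed, set_name, stop_above=c_k)
    stop_k = next((k for k, p in enumerate(pvals, start=1) if p > c_k),
                  len(ranked))
    return ReductionTrace(set_name, ranked, pvals, stop_k, c_k, d_eff, d_raw)


def _residual_sequence(ds, case_label, control_label, ranked, stats, weights,
                       B, seed, set_name, stop_above):
    """Residual p-values with per-k derived seeds, stopping once one exceeds
    ``stop_above`` (computing further values cannot change any stop index at
    or below that threshold)."""
    from .stats import derive_rng  # local import to keep module surface tidy

    pvals: list[float] = []
    for k in range(1, len(ranked)):
        sub_seed = int(derive_rng(seed, set_name, k).integers(0, 2**31 - 1))
        res = permutation_pvalue(ds, case_label, control_label, ranked[k:],
                                 weights=weights, B=B, seed=sub_seed, s0=stats.s0)
        pvals.append(res.p_value)
        if res.p_value > stop_above:
            break
    return pvals


def select_significant_sets(ds: ExpressionDataset, case_label: str,
                            control_label: str, gsc: GeneSetCollection,
                            weights: ConnectivityWeights | None = None,
                            alpha: float = 0.05, B: int = 1000,
                            seed: int = 0) -> tuple[list[str], pd.DataFrame]:
    """Stage-1 screen: permutation p-value per usable set, keep p <= alpha.

    Returns the selected set names and the full p-value table (columns
    set, size, score, p_value). Unusable (empty-after-intersection) sets are
    excluded from testing.
    """
    if not 0.0 < alpha <= 1.0:
        raise InputError("alpha must be in (0, 1]")
    from .stats import derive_rng

    rows = []
    for name in gsc.usable_names:
        members = gsc.sets[name]
        sub_seed = int(derive_rng(seed, "stage1", name).integers(0, 2**31 - 1))
        res = permutation_pvalue(ds, case_label, control_label, members,
                                 weights=weights, B=B, seed=sub_seed)
        rows.append({"set": name, "size": len(members),
                     "score": res.observed_score, "p_value": res.p_value})
    table = pd.DataFrame(rows, columns=["set", "size", "score", "p_value"])
    selected = [r["set"] for r in rows if r["p_value"] <= alpha]
    return selected, table
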