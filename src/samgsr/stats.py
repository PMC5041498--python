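"""SAM statistics, (weighted) gene-set scores, and permutation significance.

The moderated per-gene statistic is

    d_i = (xbar_case(i) - xbar_ctrl(i)) / (s(i) + s0)

with s(i) the two-group pooled standard deviation

    s(i) = sqrt[ (1/n_d + 1/n_c) * (SS_case + SS_ctrl) / (n_d + n_c - 2) ]

and s0 a small positive constant damping the statistic for genes with tiny
variability. A gene set's score is the sum of squared (optionally
connectivity-weighted) statistics over its members, and its significance is
estimated by permuting the phenotype labels while preserving class sizes.

s0 is, by default, the median of the positive pooled standard deviations over
the analyzed gene universe, computed once from the observed labeling and held
fixed across permutations so that observed and null scores share the same
damping.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .errors import InputError
from .io import ExpressionDataset
from .network import ConnectivityWeights

__all__ = [
    "SamStatistics",
    "PermutationResult",
    "estimate_s0",
    "sam_statistics",
    "samgs_score",
    "permutation_pvalue",
    "derive_rng",
]

_S0_FLOOR = 1e-6


def derive_rng(seed: int, *tokens) -> np.random.Generator:
    """Deterministic child RNG from a master seed plus context tokens.

    Tokens (set names, iteration indices, ...) are hashed so that distinct
    analysis steps draw independent, reproducible permutation streams.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class SamStatistics:
    """Per-gene SAM statistics for one case/control contrast.

    ``d_effective`` is w_i * d_i when connectivity weights were supplied and
    exactly ``d`` otherwise; ranking and set scores always use it.
    """

    gene_ids: list[str]
    d: np.ndarray
    s: np.ndarray
    s0: float
    weighted: bool
    d_effective: np.ndarray
    weights: np.ndarray | None = None
    case_label: str | None = None
    control_label: str | None = None

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def indices(self, genes) -> np.ndarray:
        try:
            return np.array([self._index[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise InputError(f"gene {exc.args[0]!r} not in statistics") from None


@dataclass
class PermutationResult:
    """Observed set score, its permutation null, and the add-one p-value."""

    observed_score: float
    null_scores: np.ndarray
    p_value: float
    B: int
    seed: int
    exact: bool = False


def estimate_s0(s: np.ndarray) -> float:
    """Median of the positive pooled standard deviations.

    Falls back to a fixed small constant when every gene has zero pooled
    variance (a degenerate matrix, but the statistic stays defined).
    """
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise InputError("cannot estimate s0 from an empty sd vector")
    if np.any(s < 0):
        raise InputError("standard deviations must be nonnegative")
    positive = s[s > 0]
    if positive.size == 0:
        return _S0_FLOOR
    return float(np.median(positive))


def _pooled_stats(X: np.ndarray, case_mask: np.ndarray):
    """Group-mean difference and pooled sd for every row of X."""
    nd = int(case_mask.sum())
    nc = int((~case_mask).sum())
    Xd, Xc = X[:, case_mask], X[:, ~case_mask]
    md, mc = Xd.mean(axis=1), Xc.mean(axis=1)
    ss = ((Xd - md[:, None]) ** 2).sum(axis=1) + ((Xc - mc[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / nd + 1.0 / nc) * ss / (nd + nc - 2))
    return md - mc, s


def sam_statistics(ds: ExpressionDataset, case_label: str, control_label: str,
                   s0: float | str = "auto",
                   weights: ConnectivityWeights | None = None) -> SamStatistics:
    """SAM statistic d_i for every gene in the dataset.

    The difference is case minus control; ``s0="auto"`` estimates the damping
    constant as the median pooled sd over all genes. When ``weights`` are
    given, ``d_effective = w_i * d_i`` (the weighted SAM statistic).
    """
    case_mask = ds.label_mask(case_label)
    ctrl_mask = ds.label_mask(control_label)
    if case_mask.sum() < 2 or ctrl_mask.sum() < 2:
        raise InputError("each class needs at least 2 samples")
    keep = case_mask | ctrl_mask
    X = ds.values[:, keep]
    diff, s = _pooled_stats(X, case_mask[keep])
    s0_val = estimate_s0(s) if s0 == "auto" else float(s0)
    if s0_val <= 0:
        raise InputError("s0 must be positive")
    d = diff / (s + s0_val)
    if weights is not None:
        w = weights.for_genes(ds.gene_ids)
        d_eff = w * d
        return SamStatistics(list(ds.gene_ids), d, s, s0_val, True, d_eff, w,
                             case_label, control_label)
    return SamStatistics(list(ds.gene_ids), d, s, s0_val, False, d.copy(), None,
                         case_label, control_label)


def samgs_score(stats: SamStatistics, members) -> float:
    """Gene-set score: sum over members of the squared (effective) statistic."""
    members = list(members)
    if not members:
        raise InputError("gene-set members must be non-empty")
    idx = stats.indices(members)
    return float(np.sum(stats.d_effective[idx] ** 2))


def _null_scores_batch(X: np.ndarray, case_masks: np.ndarray, s0: float,
                       w2: np.ndarray) -> np.ndarray:
    """Set scores for a batch of permuted case masks (rows of case_masks).

    Uses sufficient statistics: per-permutation group sums of x and x^2 give
    the pooled sd without looping over genes or permutations.
    """
    n = X.shape[1]
    nd = int(case_masks[0].sum())
    nc = n - nd
    M = case_masks.T.astype(float)                    # n x B
    X2 = X * X
    tot1 = X.sum(axis=1, keepdims=True)               # m x 1
    tot2 = X2.sum(axis=1, keepdims=True)
    s1d = X @ M                                       # m x B case sums
    s2d = X2 @ M
    md = s1d / nd
    mc = (tot1 - s1d) / nc
    ssd = s2d - nd * md ** 2
    ssc = (tot2 - s2d) - nc * mc ** 2
    ss = np.maximum(ssd + ssc, 0.0)
    s = np.sqrt((1.0 / nd + 1.0 / nc) * ss / (n - 2))
    d = (md - mc) / (s + s0)
    return (w2[:, None] * d * d).sum(axis=0)


def _all_case_masks(n: int, nd: int) -> np.ndarray:
    masks = np.zeros((0, n), dtype=bool)
    rows = [np.isin(np.arange(n), combo) for combo in combinations(range(n), nd)]
    return np.array(rows, dtype=bool) if rows else masks


def permutation_pvalue(ds: ExpressionDataset, case_label: str, control_label: str,
                       members, weights: ConnectivityWeights | None = None,
                       B: int = 1000, seed: int = 0, s0: float | str = "auto",
                       exact: bool = False) -> PermutationResult:
    """Permutation p-value of a gene set's (weighted) score.

    Labels are shuffled preserving class sizes; the statistic is recomputed
    with the observed s0 held fixed. The default estimator is the add-one
    p = (1 + #{null >= observed}) / (B + 1) over B uniformly drawn
    permutations. With ``exact=True`` every distinct case-assignment is
    enumerated instead and p = #{score >= observed} / total (the identity
    assignment is part of the null, so p >= 1/total); B is ignored.
    """
    if not exact and B < 1:
        raise InputError("B must be >= 1")
    members = list(members)
    stats = sam_statistics(ds, case_label, control_label, s0=s0, weights=weights)
    observed = samgs_score(stats, members)

    case_mask = ds.label_mask(case_label)
    ctrl_mask = ds.label_mask(control_label)
    keep = case_mask | ctrl_mask
    X = ds.values[np.ix_(stats.indices(members), keep)]
    n = int(keep.sum())
    nd = int(case_mask.sum())
    if stats.weighted:
        w2 = stats.weights[stats.indices(members)] ** 2
    else:
        w2 = np.ones(len(members))

    # ties between null and observed scores count as >=; the tolerance is
    # relative so that rescaling all weights cannot flip a tie
    tol = 1e-9 * max(1.0, abs(observed))

    if exact:
        total = comb(n, nd)
        if total > 200_000:
            raise InputError(
                f"exact enumeration of {total} label assignments is infeasible; "
                "use the sampled permutation test")
        masks = _all_case_masks(n, nd)
        null = _null_scores_batch(X, masks, stats.s0, w2)
        p = float(np.count_nonzero(null >= observed - tol) / total)
        return PermutationResult(observed, null, p, total, seed, exact=True)

    rng = derive_rng(seed)
    order = np.argsort(rng.random((B, n)), axis=1)
    masks = order < nd
    null = _null_scores_batch(X, masks, stats.s0, w2)
    p = float((1 + np.count_nonzero(null >= observed - tol)) / (B + 1))
    return PermutationResult(observed, null, p, B, seed, exact=False)
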