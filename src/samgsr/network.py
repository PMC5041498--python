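"""Connectivity weights from a gene-interaction network.

For the G analyzed genes, an implicit symmetric adjacency A with unit
self-loops (a_ii = 1) defines each gene's connectivity weight

    w_i = sum_j a_ij = 1 + sum of scores of edges incident to i,

where a_ij is 1 for a binary interaction or the interaction's confidence
score in (0, 1]. The self-loop guarantees w_i >= 1, so isolated genes keep a
non-zero weight. Only edges with both endpoints inside the analysis universe
contribute; the dense G x G matrix is never materialized, only the row sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError
from .io import EdgeList, GeneSetCollection

__all__ = ["ConnectivityWeights", "build_weights", "membership_connectivity_correlation"]

_TRANSFORMS = ("identity", "log2p1", "rank")


@dataclass
class ConnectivityWeights:
    """Per-gene connectivity weight over an ordered gene universe.

    ``transform`` records what was applied after the raw 1 + degree / 1 +
    score-sum computation ("identity" means the literal row sum).
    """

    gene_ids: list[str]
    weights: np.ndarray
    transform: str = "identity"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.gene_ids),):
            raise InputError("one weight per gene is required")
        if np.any(self.weights <= 0):
            raise InputError("connectivity weights must be positive")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def for_genes(self, genes: Sequence[str]) -> np.ndarray:
        """Weight vector aligned to ``genes`` (error on unknown gene)."""
        try:
            idx = [self._index[g] for g in genes]
        except KeyError as exc:
            raise InputError(f"gene {exc.args[0]!r} has no connectivity weight") from None
        return self.weights[idx]

    @classmethod
    def uniform(cls, gene_ids: Sequence[str], value: float = 1.0) -> "ConnectivityWeights":
        return cls(list(gene_ids), np.full(len(gene_ids), float(value)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "weight": self.weights})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_weights(edges: EdgeList, universe: Sequence[str],
                  transform: str = "identity") -> ConnectivityWeights:
    """Compute w_i = 1 + sum of incident edge scores within ``universe``.

    In binary mode (all scores 1) with the identity transform this is exactly
    1 + degree(i). Edges touching genes outside the universe are ignored:
    the weights describe connectivity among the analyzed genes only.
    """
    if not len(universe):
        raise InputError("universe must be non-empty")
    if transform not in _TRANSFORMS:
        raise InputError(f"transform must be one of {_TRANSFORMS}, got {transform!r}")
    index = {g: i for i, g in enumerate(universe)}
    w = np.ones(len(universe), dtype=float)  # a_ii = 1
    for a, b, score in edges.edges:
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            continue
        w[ia] += score
        w[ib] += score
    if transform == "log2p1":
        w = np.log2(1.0 + w)
    elif transform == "rank":
        w = sps.rankdata(w)
    return ConnectivityWeights(list(universe), w, transform=transform)


def membership_connectivity_correlation(gsc: GeneSetCollection,
                                        w: ConnectivityWeights) -> float:
    """Spearman correlation between set-membership counts and weights.

    For each universe gene, correlates the number of gene sets it belongs to
    with its connectivity weight (with binary identity weights the latter is
    1 + the number of connected genes). Returns NaN when either vector is
    constant, where the rank correlation is undefined.
    """
    counts = gsc.membership_counts()
    weights = w.for_genes(list(counts.index))
    if len(counts) < 2 or counts.nunique() == 1 or len(np.unique(weights)) == 1:
        return float("nan")
    rho, _ = sps.spearmanr(counts.to_numpy(), weights)
    return float(rho)
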