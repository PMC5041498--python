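"""Evaluation metrics for probabilistic class predictions and for the
stability of repeated gene selections.

For n samples in K classes with true-class indicator Y_ik and predicted
probability p_ik:

  error rate   misclassified fraction; for K = 2 a sample is called the case
               class when its case confidence passes the 0.5 cutoff (a
               confidence of exactly 0.5 also calls the case class), for
               K > 2 by argmax.
  GBS          generalized Brier score, (1/2n) sum_i sum_k (Y_ik - p_ik)^2,
               scaled to [0, 1]; 0 is perfect.
  BCM          belief confusion metric, the mean over classes of the average
               confidence assigned to the true class; 1 is perfect.
  AUPR         macro average over classes of the area under the
               precision-recall curve built by ranking samples on their
               class-k confidence (step-wise average precision).
  Rand         mean pairwise Jaccard similarity between the gene (or set)
               lists of repeated runs — a selection-stability measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["PredictionTable", "MetricsReport", "error_rate", "gbs", "bcm",
           "aupr", "rand_index", "evaluate"]


@dataclass
class PredictionTable:
    """True classes plus a samples x classes probability matrix.

    ``probs`` rows must sum to 1; ``positive_class`` names the case class
    used by the two-class 0.5 cutoff (defaults to the first column).
    """

    probs: pd.DataFrame
    y_true: list[str]
    positive_class: str | None = None

    def __post_init__(self) -> None:
        self.y_true = [str(y) for y in self.y_true]
        if len(self.y_true) != len(self.probs):
            raise InputError("one true class per prediction row is required")
        p = self.probs.to_numpy(dtype=float)
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise InputError("probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise InputError("probability rows must sum to 1")
        unknown = set(self.y_true) - set(map(str, self.probs.columns))
        if unknown:
            raise InputError(f"true classes missing from columns: {sorted(unknown)}")
        if self.positive_class is None:
            self.positive_class = str(self.probs.columns[0])

    @property
    def classes(self) -> list[str]:
        return [str(c) for c in self.probs.columns]

    @property
    def n(self) -> int:
        return len(self.probs)


@dataclass
class MetricsReport:
    error_rate: float
    gbs: float
    bcm: float
    aupr: float
    rand_gene: float | None = None
    rand_geneset: float | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"error_rate": self.error_rate, "gbs": self.gbs,
             "bcm": self.bcm, "aupr": self.aupr}
        if self.rand_gene is not None:
            d["rand_gene"] = self.rand_gene
        if self.rand_geneset is not None:
            d["rand_geneset"] = self.rand_geneset
        return pd.DataFrame([d])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _indicator(pt: PredictionTable) -> np.ndarray:
    classes = pt.classes
    return np.array([[1.0 if y == c else 0.0 for c in classes]
                     for y in pt.y_true])


def error_rate(pt: PredictionTable, cutoff: float = 0.5) -> float:
    """Misclassified fraction (0.5-cutoff rule for K = 2, argmax otherwise)."""
    if len(pt.classes) == 2:
        p_pos = pt.probs[pt.positive_class].to_numpy(dtype=float)
        other = next(c for c in pt.classes if c != pt.positive_class)
        pred = np.where(p_pos >= cutoff, pt.positive_class, other)
    else:
        p = pt.probs.to_numpy(dtype=float)
        pred = np.array(pt.classes)[p.argmax(axis=1)]
    truth = np.array(pt.y_true)
    return float(np.mean(pred != truth))


def gbs(pt: PredictionTable) -> float:
    """Generalized Brier score scaled to [0, 1] (lower is better)."""
    Y = _indicator(pt)
    P = pt.probs.to_numpy(dtype=float)
    return float(((Y - P) ** 2).sum() / (2 * pt.n))


def bcm(pt: PredictionTable) -> float:
    """Mean over classes of the average confidence on the true class."""
    truth = np.array(pt.y_true)
    out = 0.0
    for c in pt.classes:
        members = truth == c
        if not members.any():
            raise InputError(f"class {c!r} has no true members; BCM undefined")
        out += float(pt.probs[c].to_numpy(dtype=float)[members].mean())
    return out / len(pt.classes)


def _average_precision(is_positive: np.ndarray) -> float:
    """Step-wise average precision of a ranked 0/1 relevance vector."""
    positives = is_positive.cumsum()
    ranks = np.arange(1, len(is_positive) + 1)
    precision = positives / ranks
    n_pos = int(is_positive.sum())
    return float(precision[is_positive.astype(bool)].sum() / n_pos)


def aupr(pt: PredictionTable) -> float:
    """Macro-averaged area under per-class precision-recall curves.

    Samples are ranked by class-k confidence, descending; ties break by
    sample-ID order (ascending), which makes the value deterministic.
    """
    truth = np.array(pt.y_true)
    ids = np.array([str(i) for i in pt.probs.index])
    total = 0.0
    for c in pt.classes:
        members = truth == c
        if not members.any():
            raise InputError(f"class {c!r} has no true members; AUPR undefined")
        conf = pt.probs[c].to_numpy(dtype=float)
        order = sorted(range(pt.n), key=lambda i: (-conf[i], ids[i]))
        total += _average_precision(members[order])
    return total / len(pt.classes)


def rand_index(lists) -> float:
    """Mean pairwise Jaccard similarity of identifier lists across runs.

    Two empty lists count as identical (similarity 1); an empty list against
    a non-empty one contributes 0.
    """
    sets = [set(l) for l in lists]
    k = len(sets)
    if k < 2:
        raise InputError("rand_index needs at least 2 lists")
    total = 0.0
    for i in range(k - 1):
        for j in range(i + 1, k):
            a, b = sets[i], sets[j]
            if not a and not b:
                total += 1.0
            elif not a or not b:
                total += 0.0
            else:
                total += len(a & b) / len(a | b)
    return 2.0 * total / (k * (k - 1))


def evaluate(pt: PredictionTable, gene_lists=None, set_lists=None) -> MetricsReport:
    """All predictive metrics, plus stability Rand indices when lists given."""
    return MetricsReport(
        error_rate=error_rate(pt), gbs=gbs(pt), bcm=bcm(pt), aupr=aupr(pt),
        rand_gene=rand_index(gene_lists) if gene_lists is not None else None,
        rand_geneset=rand_index(set_lists) if set_lists is not None else None,
    )
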