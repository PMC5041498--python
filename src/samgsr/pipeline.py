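"""End-to-end gene selection and evaluation.

Running the method means: screen gene sets for significance, reduce each
significant set to its core, take the deduplicated union of cores as the
selected genes, and fit a probabilistic classifier on them. The sparsity
threshold c_k is tuned by stratified k-fold cross-validation of the
misclassification rate; multi-class problems are handled by composing
independent binary tasks into product probabilities.

Everything is deterministic given the master seed: stage-1 tests, the per-k
reduction permutations, the fold assignment, and the classifier fit all draw
from seeds derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import DegenerateAnalysisError, InputError
from .io import ExpressionDataset, GeneSetCollection
from .network import ConnectivityWeights
from .reduction import ReductionTrace, _residual_sequence, rank_members, \
    select_significant_sets
from .stats import derive_rng, sam_statistics

__all__ = [
    "SelectionResult",
    "CvResult",
    "ProbabilisticClassifier",
    "DEFAULT_CK_GRID",
    "run_selection",
    "tune_ck",
    "fit_classifier",
    "compose_multiclass",
]

DEFAULT_CK_GRID = (0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.5)


@dataclass
class SelectionResult:
    """Outcome of one (weighted-)SAMGSR run: sets, traces, gene union."""

    selected_sets: pd.DataFrame          # columns set, size, score, p_value
    traces: dict[str, ReductionTrace]
    genes: list[str]                     # deduplicated union of trace cores
    c_k: float
    weighted: bool
    alpha: float = 0.05

    @property
    def empty(self) -> bool:
        return len(self.genes) == 0


@dataclass
class CvResult:
    """Cross-validated tuning of c_k over a candidate grid."""

    grid: list[float]
    fold_errors: pd.DataFrame            # rows folds, columns c_k values
    mean_error: pd.Series                # per c_k
    best_ck: float
    per_fold_gene_lists: list[list[str]]
    per_fold_set_lists: list[list[str]]


@dataclass
class ProbabilisticClassifier:
    """Binary linear decision function with calibrated probabilities.

    Default is a linear max-margin fit whose decision margin is mapped to a
    case-class probability by a 1-D logistic (Platt) calibration, so
    probabilities are monotone in the margin; ``kind="logistic"`` fits a
    regularized logistic model directly.
    """

    genes: list[str]
    case_label: str
    control_label: str
    coefficients: np.ndarray
    intercept: float
    kind: str = "svm"
    _margin_model: object = field(default=None, repr=False)
    _calibrator: object = field(default=None, repr=False)

    def decision_margin(self, ds: ExpressionDataset) -> np.ndarray:
        X = ds.subset_genes(self.genes).values.T
        return X @ self.coefficients + self.intercept

    def predict_proba(self, ds: ExpressionDataset) -> pd.DataFrame:
        """Per-sample probabilities, columns [case_label, control_label]."""
        margin = self.decision_margin(ds)
        if self._calibrator is not None:
            p_case = self._calibrator.predict_proba(margin.reshape(-1, 1))[:, 1]
        else:
            p_case = 1.0 / (1.0 + np.exp(-margin))
        return pd.DataFrame(
            {self.case_label: p_case, self.control_label: 1.0 - p_case},
            index=ds.sample_ids)


def fit_classifier(ds: ExpressionDataset, genes, case_label: str,
                   control_label: str, seed: int = 0,
                   kind: str = "svm", C: float = 1.0) -> ProbabilisticClassifier:
    """Fit the downstream classifier on the selected genes.

    The selection stage produces a gene list but no coefficients, so a
    separate model supplies them. Raises if the gene list is empty (the
    caller decides how to handle an empty selection).
    """
    genes = list(genes)
    if not genes:
        raise InputError("selection is empty: no genes to fit a classifier on")
    sub = ds.subset_genes(genes)
    y = np.array([1 if l == case_label else 0 for l in sub.labels])
    if y.sum() == 0 or y.sum() == len(y):
        raise DegenerateAnalysisError("both classes must be present to fit")
    X = sub.values.T
    if kind == "svm":
        base = SVC(kernel="linear", C=C, random_state=int(seed) & 0x7FFFFFFF)
        base.fit(X, y)
        coef = base.coef_.ravel().copy()
        intercept = float(base.intercept_[0])
        margin = X @ coef + intercept
        calib = LogisticRegression(C=1.0)
        calib.fit(margin.reshape(-1, 1), y)
        return ProbabilisticClassifier(genes, case_label, control_label, coef,
                                       intercept, kind, base, calib)
    if kind == "logistic":
        model = LogisticRegression(C=C, max_iter=1000)
        model.fit(X, y)
        return ProbabilisticClassifier(
            genes, case_label, control_label, model.coef_.ravel().copy(),
            float(model.intercept_[0]), kind, model, None)
    raise InputError(f"unknown classifier kind {kind!r}")


def _two_class_labels(ds: ExpressionDataset, case_label: str | None,
                      control_label: str | None) -> tuple[str, str]:
    classes = ds.classes
    if case_label is None or control_label is None:
        if len(classes) != 2:
            raise InputError(
                f"dataset has classes {classes}; specify case/control labels")
        control_label, case_label = classes  # lexicographically later = case
        if case_label < control_label:
            case_label, control_label = control_label, case_label
    return case_label, control_label


def run_selection(ds: ExpressionDataset, gsc: GeneSetCollection,
                  weights: ConnectivityWeights | None = None,
                  c_k: float = 0.05, alpha: float = 0.05, B: int = 1000,
                  seed: int = 0, case_label: str | None = None,
                  control_label: str | None = None) -> SelectionResult:
    """Stage-1 set screen, per-set reduction, union of cores."""
    result = _run_selection_grid(ds, gsc, weights, [c_k], alpha, B, seed,
                                 case_label, control_label)
    return result[float(c_k)]


def _run_selection_grid(ds, gsc, weights, grid, alpha, B, seed,
                        case_label=None, control_label=None
                        ) -> dict[float, SelectionResult]:
    """Selection at every c_k in ``grid`` sharing stage 1 and the residual
    p-value sequences (which do not depend on c_k: each k has its own derived
    seed)."""
    grid = sorted(float(c) for c in grid)
    if not grid:
        raise InputError("c_k grid must be non-empty")
    for c in grid:
        if not 0.0 <= c <= 1.0:
            raise InputError("c_k values must lie in [0, 1]")
    case_label, control_label = _two_class_labels(ds, case_label, control_label)
    stats = sam_statistics(ds, case_label, control_label, weights=weights)
    selected, table = select_significant_sets(
        ds, case_label, control_label, gsc, weights=weights, alpha=alpha,
        B=B, seed=seed)
    c_max = grid[-1]
    sequences: dict[str, tuple[list[str], list[float], list[float]]] = {}
    for name in selected:
        ranked = rank_members(stats, gsc.sets[name])
        idx = stats.indices(ranked)
        d_eff = [float(x) for x in stats.d_effective[idx]]
        d_raw = [float(x) for x in stats.d[idx]]
        if len(ranked) == 1:
            sequences[name] = (ranked, [], d_eff, d_raw)
            continue
        pvals = _residual_sequence(ds, case_label, control_label, ranked,
                                   stats, weights, B, seed, name,
                                   stop_above=c_max)
        sequences[name] = (ranked, pvals, d_eff, d_raw)

    out: dict[float, SelectionResult] = {}
    sel_table = table[table["set"].isin(selected)].reset_index(drop=True)
    for c in grid:
        traces: dict[str, ReductionTrace] = {}
        union: list[str] = []
        seen: set[str] = set()
        for name in selected:
            ranked, pvals, d_eff, d_raw = sequences[name]
            if len(ranked) == 1:
                stop_k = 1
            else:
                stop_k = next((k for k, p in enumerate(pvals, start=1) if p > c),
                              len(ranked))
            tr = ReductionTrace(name, ranked, pvals[:stop_k], stop_k, c,
                                d_eff, d_raw)
            traces[name] = tr
            for g in tr.core:
                if g not in seen:
                    seen.add(g)
                    union.append(g)
        out[c] = SelectionResult(sel_table.copy(), traces, union, c,
                                 weights is not None, alpha)
    return out


def tune_ck(ds: ExpressionDataset, gsc: GeneSetCollection,
            weights: ConnectivityWeights | None = None,
            grid=DEFAULT_CK_GRID, folds: int = 10, alpha: float = 0.05,
            B: int = 1000, seed: int = 0, case_label: str | None = None,
            control_label: str | None = None,
            classifier: str = "svm") -> CvResult:
    """Choose c_k by stratified k-fold CV of the 0.5-cutoff error rate.

    Per fold: selection on the training folds at every grid value, classifier
    fit, misclassification on the held-out fold. Ties in mean error go to the
    smaller c_k (the sparser model). A fold whose selection is empty predicts
    the training majority class. Per-fold gene/set lists at the winning c_k
    are recorded for stability (Rand-index) reporting.
    """
    if folds < 2:
        raise InputError("folds must be >= 2")
    grid = sorted(float(c) for c in grid)
    case_label, control_label = _two_class_labels(ds, case_label, control_label)
    y = np.array([1 if l == case_label else 0 for l in ds.labels])
    if min((y == 1).sum(), (y == 0).sum()) < folds:
        raise DegenerateAnalysisError(
            "a class has fewer samples than folds; use fewer folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(derive_rng(seed, "cv").integers(2**31 - 1)))
    errors = np.zeros((folds, len(grid)))
    fold_genes: list[dict[float, list[str]]] = []
    fold_sets: list[dict[float, list[str]]] = []
    for f, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        train, test = ds.subset_samples(tr_idx), ds.subset_samples(te_idx)
        fold_seed = int(derive_rng(seed, "fold", f).integers(2**31 - 1))
        results = _run_selection_grid(train, gsc, weights, grid, alpha, B,
                                      fold_seed, case_label, control_label)
        genes_at, sets_at = {}, {}
        for ci, c in enumerate(grid):
            sel = results[c]
            genes_at[c] = list(sel.genes)
            sets_at[c] = list(sel.selected_sets["set"])
            if sel.empty:
                # majority-class fallback
                maj = case_label if (np.array(train.labels) == case_label).sum() \
                    >= (np.array(train.labels) == control_label).sum() else control_label
                pred = np.full(test.n_samples, maj == case_label)
            else:
                clf = fit_classifier(train, sel.genes, case_label,
                                     control_label, seed=fold_seed,
                                     kind=classifier)
                p_case = clf.predict_proba(test)[case_label].to_numpy()
                pred = p_case >= 0.5
            truth = np.array([l == case_label for l in test.labels])
            errors[f, ci] = float(np.mean(pred != truth))
        fold_genes.append(genes_at)
        fold_sets.append(sets_at)
    fold_df = pd.DataFrame(errors, columns=grid,
                           index=[f"fold{f+1}" for f in range(folds)])
    mean_error = fold_df.mean(axis=0)
    best_ck = float(min(grid, key=lambda c: (mean_error[c], c)))
    return CvResult(grid, fold_df, mean_error, best_ck,
                    [fg[best_ck] for fg in fold_genes],
                    [fs[best_ck] for fs in fold_sets])


def compose_multiclass(task_probs: dict[str, pd.DataFrame],
                       class_map: dict[str, tuple]) -> pd.DataFrame:
    """Product probabilities for composite classes from independent binary tasks.

    ``task_probs[t]`` is a samples x task-classes probability table;
    ``class_map`` sends each composite class to one class per task, e.g.
    {"AC-I": ("AC", "I"), ...}. Each composite probability is the product of
    its factors, so if every task table's rows sum to 1 and the map covers
    the full factor product, composite rows sum to 1.
    """
    if not task_probs:
        raise InputError("need at least one task probability table")
    tables = list(task_probs.values())
    index = tables[0].index
    for t in tables[1:]:
        if not index.equals(t.index):
            missing = index.symmetric_difference(t.index).tolist()
            raise InputError(f"task tables disagree on samples: {missing}")
    tasks = list(task_probs)
    out = {}
    for comp, factors in class_map.items():
        if len(factors) != len(tasks):
            raise InputError(
                f"composite {comp!r} must name one class per task ({tasks})")
        prob = np.ones(len(index))
        for task, factor in zip(tasks, factors):
            if factor not in task_probs[task].columns:
                raise InputError(f"class {factor!r} not in task {task!r} table")
            prob = prob * task_probs[task][factor].to_numpy()
        out[comp] = prob
    return pd.DataFrame(out, index=index)
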