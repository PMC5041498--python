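"""Synthetic benchmark generator and replicate harness.

The generator emulates a two-class transcriptomic study driven by two causal
genes embedded in a gene-set collection and an interaction network:

* expression is iid standard normal per gene and sample (or resampled and
  standardized from a user-supplied real matrix);
* the phenotype comes from the logit u = 0.37 * x_weak - 0.86 * x_strong,
  either thresholded at 0 (default) or drawn Bernoulli(sigmoid(u));
* ~1000 genes are split into 5 gene sets, both causal genes sitting in the
  first set;
* the network gives the weak-effect gene many partners (default 30) and the
  strong-effect gene few (default 3), with background degrees drawn from a
  right-skewed (geometric) distribution — the configuration in which
  connectivity weighting should rescue the weak, highly connected gene.

``run_replicates`` repeats generate/select/fit/evaluate and reports selection
frequencies of the causal genes plus test-set metrics, one row per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError
from .io import EdgeList, ExpressionDataset, GeneSetCollection
from .metrics import PredictionTable, aupr, bcm, error_rate, gbs
from .network import build_weights
from .pipeline import DEFAULT_CK_GRID, fit_classifier, run_selection, tune_ck
from .stats import derive_rng

__all__ = ["SimulationConfig", "generate_dataset", "run_replicates",
           "summarize_replicates"]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark (defaults above)."""

    n_train: int = 60
    n_test: int = 60
    gene_set_sizes: tuple[int, ...] = (200, 200, 200, 200, 200)
    weak_gene: str = "HDAC1"     # subtle effect, high connectivity
    strong_gene: str = "GNAS"    # strong effect, low connectivity
    beta_weak: float = 0.37
    beta_strong: float = -0.86
    weak_degree: int = 30
    strong_degree: int = 3
    background_degree_mean: float = 1.5
    expression_model: str = "iid_standard_normal"   # or "resampled_real_matrix"
    source_matrix: np.ndarray | None = None
    label_rule: str = "threshold"                    # or "bernoulli"
    case_label: str = "case"
    control_label: str = "control"
    set_overlap: int = 0
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return sum(self.gene_set_sizes)


def _gene_ids(cfg: SimulationConfig) -> list[str]:
    n_background = cfg.n_genes - 2
    ids = [f"G{i:04d}" for i in range(1, n_background + 1)]
    return [cfg.weak_gene, cfg.strong_gene] + ids


def _make_sets(cfg: SimulationConfig, genes: list[str]) -> GeneSetCollection:
    """Split the universe into the configured set sizes.

    The two causal genes always land in the first set. ``set_overlap`` > 0
    additionally copies that many genes of each set into the next one.
    """
    sets: dict[str, list[str]] = {}
    start = 0
    for i, size in enumerate(cfg.gene_set_sizes):
        members = genes[start:start + size]
        start += size
        sets[f"SET{i + 1}"] = members
    if cfg.set_overlap > 0:
        names = list(sets)
        for i in range(len(names) - 1):
            sets[names[i + 1]] = sets[names[i]][-cfg.set_overlap:] + sets[names[i + 1]]
    for g in (cfg.weak_gene, cfg.strong_gene):
        if not any(g in m for m in sets.values()):
            raise InputError(f"causal gene {g!r} assigned to no gene set")
    return GeneSetCollection(sets, genes)


def _make_network(cfg: SimulationConfig, genes: list[str],
                  rng: np.random.Generator) -> EdgeList:
    """Chung-Lu random graph with per-gene target degrees.

    Background targets are geometric (right-skewed, mostly 0-3 partners);
    the causal genes get their configured targets.
    """
    targets = rng.geometric(1.0 / (1.0 + cfg.background_degree_mean),
                            size=len(genes)) - 1
    targets = targets.astype(float)
    targets[genes.index(cfg.weak_gene)] = cfg.weak_degree
    targets[genes.index(cfg.strong_gene)] = cfg.strong_degree
    graph = nx.expected_degree_graph(targets, seed=int(rng.integers(2**31 - 1)),
                                     selfloops=False)
    edges = [(genes[a], genes[b], 1.0) for a, b in graph.edges()]
    return EdgeList(edges)


def _expression(cfg: SimulationConfig, n_samples: int,
                rng: np.random.Generator) -> np.ndarray:
    if cfg.expression_model == "iid_standard_normal":
        return rng.standard_normal((cfg.n_genes, n_samples))
    if cfg.expression_model == "resampled_real_matrix":
        if cfg.source_matrix is None:
            raise InputError("resampled_real_matrix needs a source_matrix")
        src = np.asarray(cfg.source_matrix, dtype=float)
        if src.shape[0] < cfg.n_genes:
            raise InputError("source matrix has fewer genes than requested")
        rows = rng.choice(src.shape[0], size=cfg.n_genes, replace=False)
        cols = rng.choice(src.shape[1], size=n_samples, replace=True)
        X = src[np.ix_(rows, cols)]
        X = X - X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        return X / sd
    raise InputError(f"unknown expression model {cfg.expression_model!r}")


def _labels(cfg: SimulationConfig, X: np.ndarray, genes: list[str],
            rng: np.random.Generator) -> list[str]:
    u = (cfg.beta_weak * X[genes.index(cfg.weak_gene)]
         + cfg.beta_strong * X[genes.index(cfg.strong_gene)])
    if cfg.label_rule == "threshold":
        case = u > 0
    elif cfg.label_rule == "bernoulli":
        case = rng.random(len(u)) < 1.0 / (1.0 + np.exp(-u))
    else:
        raise InputError(f"unknown label rule {cfg.label_rule!r}")
    return [cfg.case_label if c else cfg.control_label for c in case]


def generate_dataset(cfg: SimulationConfig):
    """Build one replicate: (train, test, gene sets, edges, causal gene IDs)."""
    genes = _gene_ids(cfg)
    rng = derive_rng(cfg.seed, "simulate")
    gsc = _make_sets(cfg, genes)
    edges = _make_network(cfg, genes, rng)
    Xtr = _expression(cfg, cfg.n_train, rng)
    Xte = _expression(cfg, cfg.n_test, rng)
    train = ExpressionDataset(genes, [f"tr{j+1}" for j in range(cfg.n_train)],
                              Xtr, _labels(cfg, Xtr, genes, rng))
    test = ExpressionDataset(genes, [f"te{j+1}" for j in range(cfg.n_test)],
                             Xte, _labels(cfg, Xte, genes, rng))
    return train, test, gsc, edges, (cfg.weak_gene, cfg.strong_gene)


def run_replicates(cfg: SimulationConfig, n_reps: int, method: str = "samgsr",
                   alpha: float = 0.05, B: int = 100,
                   grid=DEFAULT_CK_GRID, folds: int = 10,
                   tune: bool = True, c_k: float = 0.05,
                   classifier: str = "svm") -> pd.DataFrame:
    """Repeat generate -> (tune) -> select -> fit -> evaluate.

    ``method`` is "samgsr" (unweighted) or "weighted". Per-replicate seeds
    derive from ``cfg.seed``, so the two methods can be run on identical,
    paired datasets by calling this twice with the same config. Returns one
    row per replicate with the selected genes, model size, best c_k and
    test-set metrics.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    if method not in ("samgsr", "weighted"):
        raise InputError("method must be 'samgsr' or 'weighted'")
    rows = []
    for rep in range(n_reps):
        rep_seed = int(derive_rng(cfg.seed, "replicate", rep).integers(2**31 - 1))
        rep_cfg = replace(cfg, seed=rep_seed)
        train, test, gsc, edges, truth = generate_dataset(rep_cfg)
        weights = build_weights(edges, train.gene_ids) \
            if method == "weighted" else None
        if tune:
            cv = tune_ck(train, gsc, weights=weights, grid=grid, folds=folds,
                         alpha=alpha, B=B, seed=rep_seed,
                         case_label=cfg.case_label,
                         control_label=cfg.control_label,
                         classifier=classifier)
            best_ck = cv.best_ck
        else:
            best_ck = float(c_k)
        sel = run_selection(train, gsc, weights=weights, c_k=best_ck,
                            alpha=alpha, B=B, seed=rep_seed,
                            case_label=cfg.case_label,
                            control_label=cfg.control_label)
        row = {"rep": rep, "seed": rep_seed, "method": method,
               "best_ck": best_ck, "n_genes": len(sel.genes),
               "genes": ";".join(sel.genes),
               "weak_selected": cfg.weak_gene in sel.genes,
               "strong_selected": cfg.strong_gene in sel.genes}
        if sel.empty:
            row.update({"test_error": np.nan, "gbs": np.nan,
                        "bcm": np.nan, "aupr": np.nan})
        else:
            clf = fit_classifier(train, sel.genes, cfg.case_label,
                                 cfg.control_label, seed=rep_seed,
                                 kind=classifier)
            pt = PredictionTable(clf.predict_proba(test), test.labels,
                                 positive_class=cfg.case_label)
            row.update({"test_error": error_rate(pt), "gbs": gbs(pt),
                        "bcm": bcm(pt), "aupr": aupr(pt)})
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_replicates(table: pd.DataFrame, cfg: SimulationConfig) -> pd.DataFrame:
    """One summary row per method: mean model size, causal-gene selection
    frequencies (%), mean test error (%) and mean GBS/BCM/AUPR."""
    out = []
    for method, sub in table.groupby("method"):
        out.append({
            "method": method,
            "size": float(sub["n_genes"].mean()),
            f"{cfg.weak_gene} (%)": 100.0 * float(sub["weak_selected"].mean()),
            f"{cfg.strong_gene} (%)": 100.0 * float(sub["strong_selected"].mean()),
            "error (%)": 100.0 * float(sub["test_error"].mean()),
            "GBS": float(sub["gbs"].mean()),
            "BCM": float(sub["bcm"].mean()),
            "AUPR": float(sub["aupr"].mean()),
        })
    return pd.DataFrame(out)
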