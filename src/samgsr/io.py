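"""Dataset containers and readers/writers for the formats the tool touches.

Expression matrices are delimited text with gene IDs in the first column and
sample IDs in the header; labels are a two-column (sample_id, class) table;
gene sets use the MSigDB GMT dialect; interaction networks are two-column
(binary) or three-column (scored) edge lists.

Gene-ID matching everywhere is exact, case-sensitive string equality; alias
resolution and probe collapsing are preprocessing concerns and are not done
here.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "GeneSetCollection",
    "EdgeList",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class ExpressionDataset:
    """A genes x samples matrix of log-scale expression with class labels.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in ``sample_ids[j]``;
    ``labels[j]`` is that sample's class. Gene IDs must be unique (duplicate
    rows are an input error, collapsing is out of scope) and all values finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InputError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.labels) != len(self.sample_ids):
            raise InputError("one label per sample is required")
        dups = [g for g, c in Counter(self.gene_ids).items() if c > 1]
        if dups:
            raise InputError(f"duplicate gene IDs: {sorted(dups)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InputError("duplicate sample IDs")
        if not np.all(np.isfinite(self.values)):
            raise InputError("expression values must all be finite")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def gene_indices(self, genes: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._gene_index[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise InputError(f"unknown gene ID: {exc.args[0]!r}") from None

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        idx = self.gene_indices(genes)
        return ExpressionDataset(
            [self.gene_ids[i] for i in idx], list(self.sample_ids),
            self.values[idx, :], list(self.labels),
        )

    def subset_samples(self, index: Sequence[int]) -> "ExpressionDataset":
        index = np.asarray(index, dtype=int)
        return ExpressionDataset(
            list(self.gene_ids), [self.sample_ids[j] for j in index],
            self.values[:, index], [self.labels[j] for j in index],
        )

    def label_mask(self, label: str) -> np.ndarray:
        if label not in self.labels:
            raise InputError(f"unknown class label {label!r}")
        return np.array([l == label for l in self.labels], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a dataset's gene universe.

    ``sets`` holds each set after intersection with ``universe`` — that is the
    set actually analyzed, and its length is the set size |j|. Sets that are
    empty after intersection are retained by name in ``unusable``.
    """

    sets: dict[str, list[str]]
    universe: list[str]
    unusable: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        uni = set(self.universe)
        restricted: dict[str, list[str]] = {}
        unusable = set()
        for name, members in self.sets.items():
            seen: set[str] = set()
            kept = [g for g in members if g in uni and not (g in seen or seen.add(g))]
            restricted[name] = kept
            if not kept:
                unusable.add(name)
        self.sets = restricted
        self.unusable = unusable

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    @property
    def usable_names(self) -> list[str]:
        return [n for n in self.sets if n not in self.unusable]

    def sizes(self) -> dict[str, int]:
        return {n: len(m) for n, m in self.sets.items()}

    def membership_counts(self) -> pd.Series:
        """Number of sets each universe gene belongs to."""
        counts = Counter(g for members in self.sets.values() for g in members)
        return pd.Series([counts.get(g, 0) for g in self.universe],
                         index=self.universe, dtype=int)


@dataclass
class EdgeList:
    """Undirected, deduplicated gene-gene edges with scores in (0, 1].

    (a, b) and (b, a) denote the same edge; duplicates are collapsed keeping
    the maximum score; self-edges are never stored (self-connection is added
    downstream through the a_ii = 1 convention of the connectivity weights).
    """

    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        best: dict[tuple[str, str], float] = {}
        for a, b, score in self.edges:
            a, b, score = str(a), str(b), float(score)
            if a == b:
                logger.warning("dropping self-edge %s-%s", a, b)
                continue
            if score <= 0:
                raise InputError(f"edge {a}-{b} has non-positive score {score}")
            if score > 1:
                raise InputError(f"edge {a}-{b} has score {score} > 1")
            key = (a, b) if a < b else (b, a)
            if score > best.get(key, 0.0):
                best[key] = score
        self.edges = [(a, b, s) for (a, b), s in sorted(best.items())]

    def __len__(self) -> int:
        return len(self.edges)


def read_expression(path: str | Path, label_path: str | Path) -> ExpressionDataset:
    """Read a delimited expression table plus a sample->class label table.

    The expression file has gene IDs in its first column and sample IDs in the
    header row; ``.csv`` files are comma-separated, anything else tab. The
    label file is two columns (sample_id, class) without a header. Labels are
    attached by sample-ID join, never by position.
    """
    path, label_path = Path(path), Path(label_path)
    table = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    gene_ids = [str(g) for g in table.index]
    dups = [g for g, c in Counter(gene_ids).items() if c > 1]
    if dups:
        raise InputError(f"duplicate gene IDs in {path.name}: {sorted(dups)}")
    lab = pd.read_csv(label_path, sep=_sep_for(label_path), header=None,
                      names=["sample_id", "class"], dtype=str)
    label_map = dict(zip(lab["sample_id"], lab["class"]))
    samples = [str(s) for s in table.columns]
    missing = [s for s in samples if s not in label_map]
    if missing:
        raise InputError(f"samples missing from label file: {missing}")
    return ExpressionDataset(gene_ids, samples, table.to_numpy(dtype=float),
                             [label_map[s] for s in samples])


def write_expression(ds: ExpressionDataset, path: str | Path,
                     label_path: str | Path | None = None) -> None:
    path = Path(path)
    ds.to_frame().to_csv(path, sep=_sep_for(path), index_label="gene_id")
    if label_path is not None:
        label_path = Path(label_path)
        pd.DataFrame({"sample_id": ds.sample_ids, "class": ds.labels}).to_csv(
            label_path, sep=_sep_for(label_path), index=False, header=False)


def read_gmt(path: str | Path, universe: Iterable[str]) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB member genes ...).

    Sets are restricted to ``universe``; sets empty after that intersection
    are kept but flagged unusable. Duplicate set names are an error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"{path.name}:{lineno}: GMT line has {len(fields)} "
                    "tab-separated fields, need at least 3 (name, description, genes)")
            name, members = fields[0], [g for g in fields[2:] if g]
            if name in sets:
                raise InputError(f"{path.name}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = members
    return GeneSetCollection(sets, list(universe))


def write_gmt(gsc: GeneSetCollection, path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in gsc.sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_edge_list(path: str | Path, mode: str = "binary") -> EdgeList:
    """Read a 2-column (binary) or 3-column (scored) edge list.

    Scored files carry STRING-style combined scores: values above 1 are taken
    to be on the 0-1000 scale and divided by 1000; values already in (0, 1]
    pass through unchanged.
    """
    if mode not in ("binary", "scored"):
        raise InputError(f"mode must be 'binary' or 'scored', got {mode!r}")
    path = Path(path)
    raw: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if mode == "binary":
                if len(fields) < 2:
                    raise InputError(f"{path.name}:{lineno}: need 2 columns")
                raw.append((fields[0], fields[1], 1.0))
            else:
                if len(fields) < 3:
                    raise InputError(f"{path.name}:{lineno}: need 3 columns in scored mode")
                try:
                    score = float(fields[2])
                except ValueError:
                    raise InputError(
                        f"{path.name}:{lineno}: bad score {fields[2]!r}") from None
                if score <= 0:
                    raise InputError(f"{path.name}:{lineno}: score must be positive")
                raw.append((fields[0], fields[1], score))
    if mode == "scored" and raw and max(s for _, _, s in raw) > 1:
        raw = [(a, b, s / 1000.0) for a, b, s in raw]
    return EdgeList(raw)


def write_edge_list(edges: EdgeList, path: str | Path, scored: bool | None = None) -> None:
    if scored is None:
        scored = any(s != 1.0 for _, _, s in edges.edges)
    with open(path, "w") as fh:
        for a, b, s in edges.edges:
            if scored:
                fh.write(f"{a}\t{b}\t{s:.6g}\n")
            else:
                fh.write(f"{a}\t{b}\n")
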