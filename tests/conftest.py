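import numpy as np
import pytest

from samgsr import ExpressionDataset, GeneSetCollection


def make_dataset(values, labels, gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i+1}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j+1}" for j in range(n_samples)]
    return ExpressionDataset(gene_ids, sample_ids, values, labels)


@pytest.fixture
def planted_dataset():
    """30 genes x 24 samples; genes g1, g2 shifted +2 in the case group."""
    rng = np.random.default_rng(42)
    values = rng.standard_normal((30, 24))
    labels = ["d"] * 12 + ["c"] * 12
    values[0, :12] += 2.0
    values[1, :12] += 2.0
    return make_dataset(values, labels)


@pytest.fixture
def planted_sets(planted_dataset):
    genes = planted_dataset.gene_ids
    return GeneSetCollection(
        {"SIG": genes[:10], "NULL1": genes[10:20], "NULL2": genes[20:30]},
        genes)
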