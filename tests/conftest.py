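import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scatlas.io import AnnotatedDataset, CountMatrix, METADATA_FIELDS, MISSING
from scatlas.synth import SynthConfig, default_tree, simulate_atlas


def make_dataset(counts, gene_ids=None, metadata=None, **kwargs):
    """Build an AnnotatedDataset from a dense integer array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    cell_ids = np.array([f"c{i}" for i in range(n)], dtype=object)
    if gene_ids is None:
        gene_ids = np.array([f"g{j}" for j in range(g)], dtype=object)
    cm = CountMatrix(sp.csr_matrix(counts), cell_ids, np.asarray(gene_ids, dtype=object))
    if metadata is None:
        metadata = pd.DataFrame({f: [MISSING] * n for f in METADATA_FIELDS})
        metadata["cell_ID"] = cell_ids.astype(str)
    return AnnotatedDataset(cm, metadata, **kwargs)


@pytest.fixture(scope="session")
def small_atlas():
    """3 classes x 2 subtypes, 60 cells/subtype: quick but separable."""
    cfg = SynthConfig(
        tree=default_tree(3, 2), n_cells_per_subtype=60, n_genes=400,
        markers_per_type=10, n_samples=3, seed=7,
    )
    return simulate_atlas(cfg), cfg
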