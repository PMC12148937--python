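import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from enskit.containers import CountMatrix
from enskit.synthetic_data import SimCountsConfig, gen_counts


@pytest.fixture(scope="session")
def small_sim():
    """A modest 3-class simulation with doublets and contaminants."""
    cfg = SimCountsConfig(n_cells=600, n_genes=800, seed=11)
    counts, truth = gen_counts(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def clean_sim():
    """3 classes, no doublets or contaminants, for clustering tests."""
    cfg = SimCountsConfig(
        n_cells=600, n_genes=800, doublet_fraction=0.0, contaminant_fraction=0.0, seed=12
    )
    counts, truth = gen_counts(cfg)
    return cfg, counts, truth


def toy_counts(matrix, genes=None, cells=None) -> CountMatrix:
    X = np.asarray(matrix)
    genes = genes or [f"g{i}" for i in range(X.shape[0])]
    cells = cells or [f"c{i}" for i in range(X.shape[1])]
    return CountMatrix(sp.csr_matrix(X), pd.Index(genes), pd.Index(cells))
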