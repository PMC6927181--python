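import numpy as np
import pytest
import scipy.sparse as sp

from nbvst import CountMatrix, RegularizedNBModel, default_gene_params, simulate_homogeneous


@pytest.fixture
def toy_counts():
    """3 genes x 4 cells with hand-checkable values."""
    dense = np.array(
        [
            [0, 1, 2, 3],
            [5, 0, 0, 1],
            [1, 1, 1, 1],
        ]
    )
    return CountMatrix(sp.csr_matrix(dense), ["g1", "g2", "g3"], ["c1", "c2", "c3", "c4"])


@pytest.fixture(scope="session")
def homogeneous_sim():
    """Homogeneous NB population: 500 genes x 2000 cells, lognormal depths."""
    params = default_gene_params(500, seed=100)
    return simulate_homogeneous(params, n_cells=2000, seed=200)


@pytest.fixture(scope="session")
def homogeneous_fit(homogeneous_sim):
    """Full pipeline fit of the shared homogeneous dataset."""
    model = RegularizedNBModel(homogeneous_sim.counts, n_genes=200, seed=300)
    return model.fit()
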