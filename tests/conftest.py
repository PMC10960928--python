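import numpy as np
import pytest
import scipy.sparse as sp

import scktld


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_design():
    """120-bin, 4-domain planted design used across modules."""
    return scktld.SimulationDesign(
        n_bins=120, boundaries=(30, 60, 90), contacts_per_cell=8000, n_cells=3, seed=7
    )


@pytest.fixture
def small_expected(small_design):
    return scktld.expected_matrix(small_design)


@pytest.fixture
def small_cell(small_design, small_expected):
    return scktld.sample_cell(small_expected, small_design.contacts_per_cell, seed=11)


def random_graph_adjacency(n, rng, density=0.15):
    """Random symmetric non-negative adjacency with positive degrees."""
    A = sp.random(n, n, density=density, random_state=np.random.RandomState(rng.integers(2**31)),
                  data_rvs=lambda k: rng.uniform(0.5, 5.0, size=k))
    A = sp.triu(A, k=1)
    A = A + A.T
    deg = np.asarray(A.sum(axis=1)).ravel()
    A = (A + sp.diags((deg == 0).astype(float))).tocsr()
    return A


@pytest.fixture
def contact_matrix_factory():
    def make(dense, resolution=50_000, chrom="chrT"):
        return scktld.ContactMatrix(chrom=chrom, resolution=resolution,
                                    counts=sp.csr_matrix(np.asarray(dense, dtype=float)))
    return make
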