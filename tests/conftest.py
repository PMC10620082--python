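import numpy as np
import pytest

from cortexmap import qc as qcm
from cortexmap.codebook import assign_genes, build_codebook
from cortexmap.synthetic import default_tissue_config, generate_tissue


@pytest.fixture(scope="session")
def tissue_config():
    """Default study conditions at a small size for unit tests."""
    return default_tissue_config(seed=11, n_slices=2, n_cells_per_slice=500,
                                 n_surface_cells_per_slice=40)


@pytest.fixture(scope="session")
def tissue(tissue_config):
    return generate_tissue(tissue_config)


@pytest.fixture(scope="session")
def qc_tissue(tissue_config):
    """QC'd, normalized, log-transformed tissue (own copy)."""
    adata = generate_tissue(tissue_config)
    return qcm.qc_pipeline(adata, doublets=False, seed=0)


@pytest.fixture(scope="session")
def small_codebook():
    """A 24-bit codebook built with a light search budget, 60 blanks."""
    cb = build_codebook(n_codewords_requested=200, seed=7, n_restarts=2,
                        n_improve=0)
    genes = [f"g{i:03d}" for i in range(len(cb) - 60)]
    return assign_genes(cb, genes, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
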