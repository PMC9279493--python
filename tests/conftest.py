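import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scimmune.io import CountMatrix, lognormalize


def make_counts(rng, n_genes=50, n_cells=20, mean=2.0, mito_genes=0, gene_prefix="G"):
    """Random NB-ish count matrix with optional mitochondrial genes."""
    names = [f"{gene_prefix}{i:04d}" for i in range(n_genes - mito_genes)]
    names += [f"MT-{i}" for i in range(mito_genes)]
    counts = rng.poisson(mean, size=(n_genes, n_cells))
    return CountMatrix(
        genes=pd.Index(names),
        cells=pd.Index([f"cell{i:04d}" for i in range(n_cells)]),
        counts=sp.csr_matrix(counts),
    )


def nb_counts(rng, mu, dispersion=0.3):
    """Gamma-Poisson draws with mean matrix mu."""
    lam = rng.gamma(1.0 / dispersion, mu * dispersion)
    return rng.poisson(lam)


def make_norm(rng, n_genes=50, n_cells=40, mean=2.0, gene_prefix="G"):
    cm = make_counts(rng, n_genes, n_cells, mean, gene_prefix=gene_prefix)
    keep = np.asarray(cm.counts.sum(axis=0)).ravel() > 0
    cm = cm.subset_cells(keep)
    return lognormalize(cm)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (read-only)."""
    from scimmune.simulate import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(seed=123))
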