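import numpy as np
import pandas as pd
import pytest

from txqivive import simulate
from txqivive.dataset import ConcentrationResponseDataset

PAPER_DESIGN = [0.0, 0.02, 0.1, 0.2, 1.0, 2.0, 10.0, 20.0, 50.0]


def make_dataset(values, concentrations, n_replicates, gene_ids=None):
    """Build a dataset from a (genes x samples) array with samples grouped
    by concentration."""
    cols = pd.MultiIndex.from_tuples(
        [(c, str(r + 1)) for c in concentrations for r in range(n_replicates)],
        names=["concentration", "replicate"],
    )
    gene_ids = gene_ids or [f"G{i:05d}" for i in range(values.shape[0])]
    return ConcentrationResponseDataset(
        pd.DataFrame(values, index=gene_ids, columns=cols)
    )


@pytest.fixture(scope="session")
def design_x():
    """Per-sample concentration vector of the 8+control, 3-replicate design."""
    return np.repeat(PAPER_DESIGN, 3).astype(float)


@pytest.fixture(scope="session")
def small_synthetic():
    """60-gene dataset + truth shared across cheap tests."""
    return simulate.generate_expression_matrix(
        n_genes=60, responsive_fraction=0.3, seed=101
    )


@pytest.fixture(scope="session")
def zero_noise_synthetic():
    return simulate.generate_expression_matrix(
        n_genes=20, responsive_fraction=0.5, noise_sd=0.0, seed=7
    )
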