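import numpy as np
import pytest

from laminamap import SimulationConfig, simulate_study
from laminamap.expression import make_expression_matrix


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic study shared across tests (read-only)."""
    return simulate_study(SimulationConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def toy_matrix(per_cell, n_genes=6500):
    """Build a dense matrix realizing per-cell (n_gene, n_umi, mito_count) specs.

    ``per_cell`` is a list of (n_gene, n_umi, mito_count) tuples; gene 0 is
    the mitochondrial gene, carrying the whole mito mass.  Each cell gets
    n_gene - 1 ordinary genes at count 1 with the count remainder dumped on
    gene 1.
    """
    counts = np.zeros((n_genes, len(per_cell)), dtype=int)
    for c, (n_gene, n_umi, mito) in enumerate(per_cell):
        if n_gene == 0:
            continue
        counts[0, c] = mito
        n_plain = n_gene - 1
        counts[1 : 1 + n_plain, c] = 1
        remainder = n_umi - mito - n_plain
        assert remainder >= 0
        counts[1, c] += remainder
    gene_ids = ["mt-1"] + [f"g{i}" for i in range(1, n_genes)]
    cell_ids = [f"c{i}" for i in range(len(per_cell))]
    return make_expression_matrix(counts, gene_ids, cell_ids)
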