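import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from troutatlas.atlas import RpkmMatrix
from troutatlas.synthgen import SimulationConfig


def make_rpkm(rows, tissue_ids=None, gene_ids=None) -> RpkmMatrix:
    """Build an RpkmMatrix from a list of per-gene RPKM rows."""
    arr = np.asarray(rows, dtype=float)
    n_genes, n_tissues = arr.shape
    return RpkmMatrix(
        gene_ids=gene_ids or [f"g{i}" for i in range(n_genes)],
        tissue_ids=tissue_ids or [f"t{j}" for j in range(n_tissues)],
        rpkm=arr,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    return SimulationConfig(n_genes=300, seed=7)
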