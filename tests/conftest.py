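import numpy as np
import pandas as pd
import pytest

from liverscope.reference_prep import ReferenceCellAtlas


def make_atlas(counts: np.ndarray, genes, cell_types, sample_ids=None) -> ReferenceCellAtlas:
    """Small atlas builder used throughout the suite."""
    n_cells = counts.shape[1]
    cells = [f"c{i}" for i in range(n_cells)]
    if sample_ids is None:
        sample_ids = ["s0"] * n_cells
    obs = pd.DataFrame(
        {"cell_type": list(cell_types), "sample_id": list(sample_ids)},
        index=pd.Index(cells, name="cell_id"),
    )
    return ReferenceCellAtlas(
        counts=pd.DataFrame(counts, index=pd.Index(list(genes), name="gene"), columns=cells),
        obs=obs,
    )


@pytest.fixture
def tiny_atlas() -> ReferenceCellAtlas:
    """3 genes x 4 cells, 2 types, 1 sample."""
    counts = np.array([
        [4, 4, 0, 0],
        [1, 1, 1, 1],
        [0, 0, 3, 5],
    ])
    return make_atlas(counts, ["gA", "gB", "gC"], ["T1", "T1", "T2", "T2"])


@pytest.fixture
def random_atlas_factory():
    """Random small atlases for property checks."""

    def _make(seed: int, n_genes: int = 30, n_types: int = 4, cells_per_type: int = 6):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(3.0, size=(n_genes, n_types * cells_per_type))
        counts[rng.random(counts.shape) < 0.1] = 0
        genes = [f"g{i}" for i in range(n_genes)]
        types = np.repeat([f"T{t}" for t in range(n_types)], cells_per_type)
        samples = rng.choice(["sA", "sB"], size=n_types * cells_per_type)
        return make_atlas(counts, genes, types, samples)

    return _make
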