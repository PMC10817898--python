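import numpy as np
import pandas as pd
import pytest

from neuroact.io import CountMatrix
from neuroact.simdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """2000-cell, 120-gene synthetic dataset shared by read-only tests."""
    return simulate_dataset(SimConfig(n_cells=2000, n_genes=120, seed=42))


@pytest.fixture(scope="session")
def trained_small_model(small_dataset):
    """A model trained once on the small dataset (read-only across tests)."""
    from neuroact.model import fit_activity_model

    ds = small_dataset
    tr = ds.counts.subset_cells(np.arange(1500))
    return fit_activity_model(
        tr,
        ds.counts.gene_ids[:22],
        metadata=ds.metadata.iloc[:1500],
        aux_cols=("cell_class", "dataset"),
        seed=7,
    )


@pytest.fixture
def toy_counts():
    rng = np.random.default_rng(0)
    x = rng.poisson(3.0, (10, 8))
    return CountMatrix(
        x, [f"g{i}" for i in range(10)], [f"c{i}" for i in range(8)]
    )


@pytest.fixture
def toy_metadata():
    return pd.DataFrame(
        {
            "species": ["mouse"] * 6 + ["human"] * 4,
            "cell_class": ["glut", "glut", "gaba", "gaba", "glut", "gaba"]
            + ["glut", "glut", "gaba", "gaba"],
            "subclass": list("aabbcc") + list("ddee"),
        },
        index=[f"c{i}" for i in range(10)],
    )
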