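import numpy as np
import pandas as pd
import pytest

from annoflow import (
    ExpressionMatrix,
    MultimodalDataset,
    differential_scenario,
    isoform_scenario,
)


def make_random_dataset(rng, n_cells=None, max_labels=6, n_features=3,
                        missing_rate=0.0):
    """Small random two-annotation dataset for oracle/property tests."""
    if n_cells is None:
        n_cells = int(rng.integers(2, 51))
    def column():
        n_labels = int(rng.integers(2, max_labels + 1))
        labels = [f"L{i}" for i in range(n_labels)]
        col = rng.choice(labels, size=n_cells).astype(object)
        if missing_rate > 0:
            col[rng.random(n_cells) < missing_rate] = "NA"
        return col
    matrix = ExpressionMatrix(
        rng.normal(size=(n_cells, n_features)),
        [f"f{j}" for j in range(n_features)],
    )
    return MultimodalDataset(
        [f"c{i}" for i in range(n_cells)],
        {"M": matrix},
        pd.DataFrame({"A": column(), "B": column()}),
    )


@pytest.fixture
def tiny_dataset():
    """10 cells, 2 small modalities, 2 annotations; 4 cells labelled 'CD4 T'."""
    rng = np.random.default_rng(0)
    ann = pd.DataFrame(
        {
            "main": ["CD4 T"] * 4 + ["B"] * 3 + ["NK"] * 3,
            "fine": ["TCM", "TCM", "Naive", "Naive", "B mem", "B mem",
                     "B naive", "NK", "NK", "NK"],
        }
    )
    return MultimodalDataset(
        [f"cell{i}" for i in range(10)],
        {
            "RNA": ExpressionMatrix(rng.normal(size=(10, 6)),
                                    [f"gene{j}" for j in range(6)]),
            "ADT": ExpressionMatrix(rng.normal(size=(10, 3)),
                                    ["CD4", "CD8", "CD19"]),
        },
        ann,
    )


@pytest.fixture(scope="session")
def isoform_data():
    return isoform_scenario(seed=11)


@pytest.fixture(scope="session")
def differential_data():
    return differential_scenario(seed=11)
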