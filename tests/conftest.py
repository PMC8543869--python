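import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from itemclust import ChecklistDataset, ItemMeta, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_dataset():
    """4 subjects x 3 items, one missing cell."""
    items = [ItemMeta(f"q{i}", section=3) for i in range(1, 4)]
    responses = np.array(
        [
            [1, 1, 0],
            [1, 0, np.nan],
            [0, 1, 1],
            [0, 0, 1],
        ],
        dtype=float,
    )
    return ChecklistDataset(subject_ids=["s1", "s2", "s3", "s4"], items=items, responses=responses)


@pytest.fixture(scope="session")
def planted():
    """Default planted-structure simulation (seed 7) plus its truth."""
    ds, truth = simulate_dataset(SimulationConfig(seed=7))
    return ds, truth


@pytest.fixture(scope="session")
def planted_assoc(planted):
    from itemclust import association_matrix, to_dissimilarity

    ds, truth = planted
    assoc = association_matrix(ds)
    return ds, truth, assoc, to_dissimilarity(assoc)
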