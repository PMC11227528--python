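import numpy as np
import pandas as pd
import pytest

from cellprop.cell_table import CellTable


@pytest.fixture
def toy_cells() -> CellTable:
    """Six cells, two samples, two conditions, two clusters."""
    frame = pd.DataFrame(
        {
            "sample": ["s1", "s1", "s1", "s2", "s2", "s2"],
            "cluster": ["A", "A", "B", "A", "B", "B"],
            "condition": ["ctrl", "ctrl", "ctrl", "treat", "treat", "treat"],
        }
    )
    return CellTable(frame)


def random_cell_table(rng: np.random.Generator, n_samples=4, n_clusters=3,
                      n_conditions=2, max_cells=40) -> CellTable:
    """Random valid cell table: samples nested in conditions, >=1 cell each."""
    rows = []
    for s in range(n_samples):
        cond = f"cond{s % n_conditions + 1}"
        n = int(rng.integers(1, max_cells + 1))
        clusters = rng.integers(0, n_clusters, size=n)
        for k in clusters:
            rows.append((f"s{s + 1}", f"K{k + 1}", cond))
    return CellTable(pd.DataFrame(rows, columns=["sample", "cluster", "condition"]))
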