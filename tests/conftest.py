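import numpy as np
import pandas as pd
import pytest

import mrfde as M


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def net6():
    """Fixed 6-node cell-type network with 8 edges (two clusters + bridge)."""
    nodes = [f"CT{i + 1}" for i in range(6)]
    edges = {("CT1", "CT2"), ("CT2", "CT3"), ("CT1", "CT3"), ("CT3", "CT4"),
             ("CT4", "CT5"), ("CT5", "CT6"), ("CT4", "CT6"), ("CT2", "CT5")}
    return M.CellTypeNetwork(nodes, edges)


@pytest.fixture
def path3():
    return M.CellTypeNetwork(["A", "B", "C"], {("A", "B"), ("B", "C")})


@pytest.fixture
def tiny_cells(rng):
    """50 cells, 8 genes, 2 samples per condition, 3 cell types."""
    genes = [f"g{i}" for i in range(8)]
    cells = [f"c{i}" for i in range(50)]
    matrix = rng.poisson(5.0, size=(8, 50))
    samples = ["sA1", "sA2", "sB1", "sB2"]
    conds = {"sA1": "A", "sA2": "A", "sB1": "B", "sB2": "B"}
    ann = pd.DataFrame({
        "cell_id": cells,
        "sample_id": [samples[i % 4] for i in range(50)],
        "cell_type": [f"T{i % 3}" for i in range(50)],
        "condition": [conds[samples[i % 4]] for i in range(50)],
    })
    return M.CellCounts(matrix, genes, cells), M.CellAnnotations(ann)


@pytest.fixture(scope="session")
def sim_small():
    """Small fast-mode simulated dataset shared across read-only tests."""
    cfg = M.SimulationConfig(n_genes=80, n_cells=50, n_samples=4, tau=2.0, seed=11)
    return M.simulate(cfg), cfg
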