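import numpy as np
import pytest

from memlin import SimulationConfig, normalize_depth, simulate
from memlin.data_io import ExpressionMatrix


@pytest.fixture(scope="session")
def default_sim():
    """Default strong-memory simulation (~200 cells, 2000 genes)."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_norm(default_sim):
    return normalize_depth(default_sim.counts)


@pytest.fixture(scope="session")
def null_sim():
    """No planted lineage structure: lineage labels are pure bookkeeping."""
    cfg = SimulationConfig(
        seed=11,
        sigma_lineage=0.0,
        frac_quant_memory=0.0,
        frac_qual_memory=0.0,
        mean_shift_memory=0.0,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def null_norm(null_sim):
    return normalize_depth(null_sim.counts)


@pytest.fixture
def small_matrix():
    """4 genes x 4 cells, integer counts, no structure."""
    values = np.array(
        [
            [10, 0, 3, 7],
            [0, 4, 4, 1],
            [5, 6, 0, 2],
            [1, 2, 9, 0],
        ],
        dtype=float,
    )
    return ExpressionMatrix(
        values,
        gene_ids=[f"g{i}" for i in range(4)],
        cell_ids=[f"c{i}" for i in range(4)],
    )


@pytest.fixture
def dup_profile_matrix():
    """Cells A, A2 identical; B, B2 identical; A- and B-profiles distinct."""
    a = np.array([10.0, 1.0, 5.0, 2.0, 8.0])
    b = np.array([1.0, 9.0, 2.0, 7.0, 1.0])
    values = np.column_stack([a, a, b, b])
    return ExpressionMatrix(
        values,
        gene_ids=[f"g{i}" for i in range(5)],
        cell_ids=["A", "A2", "B", "B2"],
        normalized=True,
    )
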