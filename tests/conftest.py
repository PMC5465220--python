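import numpy as np
import pandas as pd
import pytest

from pufstress import CountMatrix, ExpressionDesign, simulate_counts


@pytest.fixture
def toy_matrix() -> CountMatrix:
    """3 genes x 2 samples, spanning the >100-read filter boundary."""
    counts = pd.DataFrame(
        [[101, 0], [100, 100], [5, 150]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    samples = pd.DataFrame(
        {"strain": ["WT-a", "WT-a"], "timepoint": ["T0", "T45"],
         "replicate_batch": ["R1", "R1"]},
        index=["s1", "s2"],
    )
    return CountMatrix(counts=counts, samples=samples)


@pytest.fixture(scope="session")
def small_sim():
    """A small full-design simulation shared across tests (null effects)."""
    design = ExpressionDesign(n_genes=400, n_replicates=3, seed=11)
    matrix, truth = simulate_counts(design)
    return design, matrix, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
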