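import numpy as np
import pandas as pd
import pytest

from lactoseq.expression import ExpressionMatrix, compute_rpkm
from lactoseq.simulate import SimulationConfig, simulate_annotation, simulate_counts


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic dataset (2000 genes, 3 stages x 3 replicates)."""
    cfg = SimulationConfig(seed=7)
    ds = simulate_counts(cfg)
    ds.terms = simulate_annotation(cfg, ds.truth)
    return ds


@pytest.fixture(scope="session")
def default_rpkm(default_dataset):
    return compute_rpkm(default_dataset.counts, default_dataset.lengths)


@pytest.fixture
def tiny_matrix():
    """3 genes x 6 samples, 2 stages, hand-checkable counts."""
    values = pd.DataFrame(
        {
            "L1": [10, 0, 90],
            "L2": [20, 5, 75],
            "L3": [15, 2, 83],
            "D1": [40, 1, 59],
            "D2": [35, 0, 65],
            "D3": [42, 3, 55],
        },
        index=["gA", "gB", "gC"],
    )
    stages = {s: s[0] for s in values.columns}
    return ExpressionMatrix(values=values, stage_of_sample=stages, stages=("L", "D"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
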