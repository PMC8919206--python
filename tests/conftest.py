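import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from refstab.cq import CqMatrix


@pytest.fixture
def toy_matrix() -> CqMatrix:
    """Three genes, four samples; the worked example used across modules."""
    return CqMatrix(pd.DataFrame(
        {
            "s1": [20.0, 25.0, 18.0],
            "s2": [21.0, 26.1, 20.0],
            "s3": [22.0, 26.9, 19.5],
            "s4": [23.0, 28.0, 21.5],
        },
        index=["A", "B", "C"],
    ))


@pytest.fixture
def random_matrix_factory():
    """Random complete Cq matrices in a realistic 15-35 cycle window."""
    def make(n_genes=5, n_samples=8, seed=0) -> CqMatrix:
        rng = np.random.default_rng(seed)
        base = rng.uniform(15, 30, n_genes)[:, None]
        vals = base + rng.normal(0, rng.uniform(0.1, 1.5, n_genes)[:, None],
                                 (n_genes, n_samples))
        return CqMatrix(pd.DataFrame(
            vals,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n_samples)],
        ))
    return make
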