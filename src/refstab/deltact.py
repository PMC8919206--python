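"""Comparative dCt stability.

For every gene pair the per-sample Cq difference Cq_j - Cq_k is formed; its
SD across samples (n-1 denominator) measures how consistently the pair
co-varies. A gene's stability is the mean of its pair SDs over all G-1
partners — small when the gene moves with the consensus, large when it
drifts on its own. Per-sample loading offsets cancel in the differences,
so the statistic is loading-invariant; with all amplification factors at 2
it coincides exactly with the geNorm pairwise variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cq import CqMatrix


@dataclass
class DeltaCtResult:
    pair_sd: pd.DataFrame   # symmetric genes x genes matrix, zero diagonal
    stability: pd.Series    # per gene: mean pair SD, cycles
    ranks: pd.Series        # competition ranks, most stable = 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.stability.index,
             "stability": self.stability.to_numpy(),
             "rank": self.ranks.to_numpy()}
        )


def delta_ct_stability(m: CqMatrix | pd.DataFrame) -> DeltaCtResult:
    """Mean pairwise SD of per-sample Cq differences, per gene."""
    values = m.values if isinstance(m, CqMatrix) else m
    if values.isna().any().any():
        raise ValueError("comparative dCt requires a complete Cq matrix")
    k, n = values.shape
    if k < 2:
        raise ValueError("comparative dCt requires >= 2 genes")
    if n < 3:
        raise ValueError("comparative dCt requires >= 3 samples")
    arr = values.to_numpy()
    cov = np.atleast_2d(np.cov(arr, ddof=1))
    d = np.diag(cov)
    var = np.maximum(d[:, None] + d[None, :] - 2.0 * cov, 0.0)
    sd = np.sqrt(var)
    np.fill_diagonal(sd, 0.0)
    pair_sd = pd.DataFrame(sd, index=values.index, columns=values.index)
    stability = pd.Series(sd.sum(axis=1) / (k - 1), index=values.index,
                          name="stability")
    ranks = stability.rank(method="min").astype(int)
    return DeltaCtResult(pair_sd, stability, ranks)
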