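"""geNorm stability: M-values by iterative exclusion, normalization factors,
pairwise variation V and the optimal number of reference genes.

The method works on relative quantities Q_ij = A_j ** (minCq_j - Cq_ij)
(A_j = per-cycle amplification factor of gene j, 2.0 at perfect doubling),
so the best-expressed sample of each gene sits at Q = 1. For a gene pair
(j, k) the pairwise variation

    V_jk = SD_i[ log2(Q_ij / Q_ik) ]          (n-1 denominator)

measures how much their expression ratio moves across samples; a gene's
M-value is the mean V against all other surviving candidates. Ranking is
by iterative exclusion: the worst (highest-M) gene is removed and M is
recomputed, until two genes remain — which necessarily share their final
pair M and the top rank, the tie signature characteristic of geNorm output.

The number of reference genes needed for a stable normalization factor
(NF_n = per-sample geometric mean of the n most stable genes' Q) is read
from the pairwise variation profile V_{n,n+1} = SD_i[log2(NF_n/NF_{n+1})]:
the smallest n with V below threshold (conventionally 0.15) suffices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cq import CqMatrix

logger = logging.getLogger(__name__)

DEFAULT_V_THRESHOLD = 0.15


@dataclass
class RelativeQuantityMatrix:
    """Per-gene relative quantities Q in (0, 1]; rows genes, columns samples."""

    q: pd.DataFrame
    factors: pd.Series  # per-gene amplification factor used in the transform

    @property
    def genes(self) -> list[str]:
        return list(self.q.index)

    @property
    def samples(self) -> list[str]:
        return list(self.q.columns)

    @property
    def log2q(self) -> pd.DataFrame:
        return np.log2(self.q)


@dataclass
class GenormResult:
    """M-values at exclusion, exclusion order and competition ranks."""

    m_values: pd.Series          # per gene: M at its exclusion step
    exclusion_order: pd.Series   # 1 = removed first (least stable)
    ranks: pd.Series             # competition ranks, most stable = 1
    stability_order: list[str] = field(default_factory=list)
    # most-stable-first order used to grow NF sets; the final surviving pair
    # comes first (input order), then exclusions in reverse order.

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.m_values.index,
             "m_value": self.m_values.to_numpy(),
             "rank": self.ranks.reindex(self.m_values.index).to_numpy()}
        )


@dataclass
class NormalizationFactorSeries:
    """Per-sample geometric-mean normalization factor over a gene subset."""

    nf: pd.Series
    genes: list[str]

    @property
    def n(self) -> int:
        return len(self.genes)


@dataclass
class PairwiseVariationProfile:
    """V_{n,n+1} for n = 2..G-1, the threshold, and the recommended n."""

    v_values: dict[int, float]
    threshold: float
    recommended_n: int | None

    def to_frame(self) -> pd.DataFrame:
        ns = sorted(self.v_values)
        return pd.DataFrame(
            {"n": ns,
             "v": [self.v_values[n] for n in ns],
             "below_threshold": [self.v_values[n] < self.threshold for n in ns]}
        )


def _as_factor_series(genes: Sequence[str], factors) -> pd.Series:
    if factors is None:
        factors = 2.0
    if np.isscalar(factors):
        s = pd.Series(float(factors), index=list(genes))
    else:
        s = pd.Series(factors, dtype=float).reindex(list(genes))
        if s.isna().any():
            missing = s.index[s.isna()].tolist()
            raise ValueError(f"no amplification factor for genes: {missing}")
    if (s <= 1.0).any():
        bad = s.index[s <= 1.0].tolist()
        raise ValueError(f"amplification factors must exceed 1: {bad}")
    return s


def to_relative_quantities(
    m: CqMatrix | pd.DataFrame,
    factors: float | Mapping[str, float] | pd.Series | None = 2.0,
) -> RelativeQuantityMatrix:
    """Transform Cq to relative quantities Q_ij = A_j ** (minCq_j - Cq_ij).

    With A_j = 2 this is 2**(-dCq) relative to each gene's best sample.
    Requires a complete matrix (no NaN).
    """
    values = m.values if isinstance(m, CqMatrix) else m
    if values.isna().any().any():
        raise ValueError("relative quantities require a complete Cq matrix")
    fac = _as_factor_series(values.index, factors)
    delta = values.min(axis=1).to_numpy()[:, None] - values.to_numpy()
    q = np.power(fac.to_numpy()[:, None], delta)
    return RelativeQuantityMatrix(
        pd.DataFrame(q, index=values.index, columns=values.columns), fac
    )


def genorm_pair_variation(q: RelativeQuantityMatrix, gene_j: str, gene_k: str) -> float:
    """SD across samples of log2(Q_j/Q_k) for one gene pair (n-1 denominator)."""
    if gene_j == gene_k:
        raise ValueError("pair variation requires two distinct genes")
    ratio = np.log2(q.q.loc[gene_j].to_numpy() / q.q.loc[gene_k].to_numpy())
    return float(np.std(ratio, ddof=1))


def _pair_sd_matrix(log2q: np.ndarray) -> np.ndarray:
    """All pairwise SDs of log2-ratio rows via var_j + var_k - 2 cov_jk."""
    cov = np.cov(log2q, ddof=1)
    cov = np.atleast_2d(cov)
    d = np.diag(cov)
    var = d[:, None] + d[None, :] - 2.0 * cov
    # numerical floor: tiny negatives from cancellation
    return np.sqrt(np.maximum(var, 0.0))


def genorm_rank(q: RelativeQuantityMatrix) -> GenormResult:
    """Iterative-exclusion geNorm ranking.

    Repeatedly computes M_j = mean pairwise variation against surviving
    genes, records M for and removes the worst gene (ties: the later gene
    in input order is removed, deterministically), until two genes remain;
    both survivors are assigned their common final pair variation. Ranks
    are competition ranks over the recorded M values.
    """
    genes = q.genes
    if len(genes) < 3:
        raise ValueError("geNorm ranking requires >= 3 genes")
    log2q = q.log2q.to_numpy()
    pair_sd = _pair_sd_matrix(log2q)

    alive = list(range(len(genes)))
    m_at_exclusion = {}
    exclusion_order: list[int] = []
    step = 1
    while len(alive) > 2:
        sub = pair_sd[np.ix_(alive, alive)]
        m = sub.sum(axis=1) / (len(alive) - 1)
        worst_local = int(np.flatnonzero(m == m.max())[-1])  # later gene on ties
        worst = alive[worst_local]
        if int((m == m.max()).sum()) > 1:
            logger.info("geNorm tie on max M at step %d; removing later gene %s",
                        step, genes[worst])
        m_at_exclusion[worst] = float(m[worst_local])
        exclusion_order.append(worst)
        alive.remove(worst)
        step += 1
    final_m = float(pair_sd[alive[0], alive[1]])
    for idx in alive:
        m_at_exclusion[idx] = final_m

    m_values = pd.Series({genes[i]: m_at_exclusion[i] for i in range(len(genes))},
                         name="m_value").reindex(genes)
    excl = pd.Series(0, index=genes, name="exclusion_order")
    for pos, idx in enumerate(exclusion_order, start=1):
        excl.iloc[idx] = pos
    ranks = m_values.rank(method="min").astype(int)
    stability_order = [genes[i] for i in alive] + [genes[i] for i in reversed(exclusion_order)]
    return GenormResult(m_values, excl, ranks, stability_order)


def normalization_factor(
    q: RelativeQuantityMatrix, genes: Sequence[str]
) -> NormalizationFactorSeries:
    """Per-sample geometric mean of Q over the given reference-gene subset."""
    genes = list(genes)
    if not genes:
        raise ValueError("normalization factor requires a non-empty gene set")
    sub = np.log(q.q.loc[genes].to_numpy())
    nf = np.exp(sub.mean(axis=0))
    return NormalizationFactorSeries(pd.Series(nf, index=q.samples, name="nf"), genes)


def pairwise_variation_profile(
    q: RelativeQuantityMatrix,
    ranking: GenormResult | None = None,
    threshold: float = DEFAULT_V_THRESHOLD,
) -> PairwiseVariationProfile:
    """V_{n,n+1} profile over nested most-stable-first gene sets.

    ``recommended_n`` is the smallest n whose V falls below the threshold,
    or None when no V does. When every V is already below threshold the
    minimal set (n = 2) is recommended and the full profile is left for the
    user's own trend judgement.
    """
    if ranking is None:
        ranking = genorm_rank(q)
    order = ranking.stability_order
    if len(order) < 3:
        raise ValueError("pairwise variation requires >= 3 genes")
    v_values: dict[int, float] = {}
    for n in range(2, len(order)):
        nf_n = normalization_factor(q, order[:n]).nf.to_numpy()
        nf_n1 = normalization_factor(q, order[: n + 1]).nf.to_numpy()
        v_values[n] = float(np.std(np.log2(nf_n / nf_n1), ddof=1))
    recommended = next((n for n in sorted(v_values) if v_values[n] < threshold), None)
    return PairwiseVariationProfile(v_values, threshold, recommended)
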