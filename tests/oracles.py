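"""Naive, loop-based reference implementations used as independent oracles.

These deliberately avoid the vectorized covariance identities the package
uses: every statistic is computed pair by pair, sample by sample, straight
from its definition.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def sd(values) -> float:
    """Sample SD, n-1 denominator, computed longhand."""
    values = list(values)
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def naive_pair_variation(q: pd.DataFrame, j: str, k: str) -> float:
    ratios = [math.log2(q.loc[j, s] / q.loc[k, s]) for s in q.columns]
    return sd(ratios)


def naive_genorm_m(q: pd.DataFrame) -> pd.Series:
    """One-round M values (mean pair variation), no exclusion."""
    genes = list(q.index)
    out = {}
    for j in genes:
        out[j] = sum(naive_pair_variation(q, j, k) for k in genes if k != j) / (
            len(genes) - 1
        )
    return pd.Series(out)


def naive_genorm_iterative(q: pd.DataFrame):
    """Full iterative exclusion; returns (m_at_exclusion, exclusion_sequence)."""
    alive = list(q.index)
    recorded = {}
    excluded = []
    while len(alive) > 2:
        m = naive_genorm_m(q.loc[alive])
        worst_val = m.max()
        worst = [g for g in alive if m[g] == worst_val][-1]  # later on ties
        recorded[worst] = m[worst]
        excluded.append(worst)
        alive.remove(worst)
    final = naive_pair_variation(q, alive[0], alive[1])
    for g in alive:
        recorded[g] = final
    return pd.Series(recorded).reindex(q.index), excluded


def naive_deltact(values: pd.DataFrame) -> pd.Series:
    genes = list(values.index)
    out = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            diffs = [values.loc[j, s] - values.loc[k, s] for s in values.columns]
            sds.append(sd(diffs))
        out[j] = sum(sds) / len(sds)
    return pd.Series(out)


def naive_bestkeeper(values: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    index = [
        math.exp(sum(math.log(values.loc[g, s]) for g in values.index)
                 / len(values.index))
        for s in values.columns
    ]
    for g in values.index:
        x = [values.loc[g, s] for s in values.columns]
        n = len(x)
        arith = sum(x) / n
        geo = math.exp(sum(math.log(v) for v in x) / n)
        rows[g] = {
            "arith_mean": arith,
            "geo_mean": geo,
            "min": min(x),
            "max": max(x),
            "sd": sd(x),
            "cv_percent": sd(x) / arith * 100,
            "r_index": np.corrcoef(x, index)[0, 1] if sd(x) > 0 else float("nan"),
        }
    return pd.DataFrame(rows).T


def naive_normfinder_ungrouped(values: pd.DataFrame) -> pd.Series:
    k = len(values.index)
    z = {}
    for s in values.columns:
        col_mean = sum(values.loc[g, s] for g in values.index) / k
        for g in values.index:
            z.setdefault(g, []).append(values.loc[g, s] - col_mean)
    s2 = {g: sd(z[g]) ** 2 for g in values.index}
    mbar = sum(s2.values()) / k
    out = {}
    for g in values.index:
        sigma2 = max(0.0, (s2[g] - mbar / (k - 1)) * k / (k - 2))
        out[g] = math.sqrt(sigma2)
    return pd.Series(out)


def naive_geometric_mean_rank(ranks: list[int]) -> float:
    prod = 1.0
    for r in ranks:
        prod *= r
    return prod ** (1.0 / len(ranks))


def naive_competition_ranks(values: list[float]) -> list[int]:
    return [1 + sum(1 for w in values if w < v) for v in values]


def naive_nf(q: pd.DataFrame, genes: list[str]) -> list[float]:
    return [
        math.exp(sum(math.log(q.loc[g, s]) for g in genes) / len(genes))
        for s in q.columns
    ]


def naive_v_profile(q: pd.DataFrame, order: list[str]) -> dict[int, float]:
    out = {}
    for n in range(2, len(order)):
        nf_n = naive_nf(q, order[:n])
        nf_n1 = naive_nf(q, order[: n + 1])
        out[n] = sd([math.log2(a / b) for a, b in zip(nf_n, nf_n1)])
    return out


def naive_ols(x, y):
    """Closed-form simple OLS: slope, intercept, r^2."""
    x, y = list(x), list(y)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxx = sum((v - mx) ** 2 for v in x)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    syy = sum((v - my) ** 2 for v in y)
    slope = sxy / sxx
    return slope, my - slope * mx, (sxy * sxy) / (sxx * syy)
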