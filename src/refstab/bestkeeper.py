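"""BestKeeper-style descriptive stability: raw-Cq spread and index correlation.

BestKeeper judges a candidate by the dispersion of its raw Cq across samples
(SD / CV) and by how tightly it tracks the BestKeeper index, the per-sample
geometric mean Cq over all candidates. Unlike ratio-based methods this is
NOT invariant to per-sample loading differences — a feature, in that sloppy
loading shows up, and a caveat, in that it conflates loading with biology.
Genes with SD above one cycle are conventionally flagged as inconsistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cq import CqMatrix

SD_INCONSISTENT = 1.0  # cycles; classical exclusion heuristic, advisory only


@dataclass
class BestKeeperResult:
    table: pd.DataFrame       # per-gene descriptives (see columns below)
    index: pd.Series          # per-sample geometric mean Cq
    sd_estimator: str         # "sample_sd" | "mad_geo"

    @property
    def stability(self) -> pd.Series:
        """Ranking statistic: the per-gene SD column."""
        return self.table["sd"]

    def to_frame(self) -> pd.DataFrame:
        df = self.table.reset_index(names="gene")
        df["rank"] = self.table["sd"].rank(method="min").astype(int).to_numpy()
        return df


def bestkeeper_index(m: CqMatrix | pd.DataFrame) -> pd.Series:
    """Per-sample geometric mean Cq over all candidate genes."""
    values = m.values if isinstance(m, CqMatrix) else m
    return pd.Series(
        np.exp(np.log(values.to_numpy()).mean(axis=0)),
        index=values.columns, name="bestkeeper_index",
    )


def bestkeeper_describe(
    m: CqMatrix | pd.DataFrame, sd_estimator: str = "sample_sd"
) -> BestKeeperResult:
    """Per-gene Cq descriptives, index correlation, and SD-based ranking.

    ``sd_estimator='sample_sd'`` is the n-1 SD about the arithmetic mean;
    ``'mad_geo'`` is the mean absolute deviation about the geometric mean
    (the original tool's spread flavour). Constant genes get an undefined
    (NaN) index correlation with a warning.
    """
    values = m.values if isinstance(m, CqMatrix) else m
    if values.isna().any().any():
        raise ValueError("BestKeeper requires a complete Cq matrix")
    if sd_estimator not in ("sample_sd", "mad_geo"):
        raise ValueError(f"unknown sd_estimator {sd_estimator!r}")
    arr = values.to_numpy()
    geo = np.exp(np.log(arr).mean(axis=1))
    if sd_estimator == "sample_sd":
        sd = arr.std(axis=1, ddof=1)
    else:
        sd = np.abs(arr - geo[:, None]).mean(axis=1)
    arith = arr.mean(axis=1)
    idx = bestkeeper_index(values)

    r = np.full(len(values), np.nan)
    p = np.full(len(values), np.nan)
    for i, gene in enumerate(values.index):
        if np.ptp(arr[i]) == 0:
            warnings.warn(
                f"gene {gene!r} is constant: correlation with the BestKeeper "
                "index is undefined", stacklevel=2)
            continue
        res = stats.pearsonr(arr[i], idx.to_numpy())
        r[i], p[i] = res.statistic, res.pvalue

    table = pd.DataFrame(
        {
            "n": values.shape[1],
            "geo_mean": geo,
            "arith_mean": arith,
            "min": arr.min(axis=1),
            "max": arr.max(axis=1),
            "sd": sd,
            "cv_percent": sd / arith * 100.0,
            "r_index": r,
            "p_value": p,
            "inconsistent": sd > SD_INCONSISTENT,
        },
        index=values.index,
    )
    return BestKeeperResult(table, idx, sd_estimator)
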