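"""Model-based (NormFinder-style) stability via variance decomposition.

Cq is already log-scale expression, so the analysis works on sample-centered
values z_ij = x_ij - mean_j(x_ij): centering removes per-sample loading
offsets exactly, and what remains per gene is its own biological scatter
minus the shared average. Because the k candidate genes are forced to sum
to zero per sample, a gene's raw centered variance s2_j is a biased view of
its true variance sigma2_j; the method-of-moments correction

    sigma2_hat_j = max(0, (s2_j - mbar/(k-1)) * k/(k-2)),   mbar = mean_j s2_j

undoes the centering-induced covariance (hence the k >= 3 requirement).
Ungrouped stability is sqrt(sigma2_hat_j).

With a group design (conditions), per-group deviations d_gj (the gene's
group mean of z relative to its cross-group average) capture systematic
condition effects. They are shrunk toward zero empirical-Bayes style by
the ratio gamma2/(gamma2 + sigma2_gj/n_g), where gamma2 is the shared
between-group variance component (clamped at 0 when the observed scatter
of d is within sampling noise). Stability combines both error sources:

    stability_j = mean_g( |d_shrunk_gj| + sqrt(sigma2_hat_gj / n_g) ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cq import CqMatrix, SampleAnnotation


@dataclass
class NormFinderResult:
    stability: pd.Series                  # per gene, >= 0
    sigma2_hat: pd.Series                 # intragroup variance estimates
    grouped: bool = False
    d_hat: pd.DataFrame | None = None     # genes x groups raw deviations
    d_shrunk: pd.DataFrame | None = None  # genes x groups shrunken deviations
    gamma2_hat: float | None = None       # shared between-group component
    n_per_group: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"gene": self.stability.index,
             "stability": self.stability.to_numpy(),
             "rank": self.stability.rank(method="min").astype(int).to_numpy()}
        )
        if self.grouped:
            df["gamma2"] = self.gamma2_hat
        return df


def _matrix(m: CqMatrix | pd.DataFrame) -> pd.DataFrame:
    values = m.values if isinstance(m, CqMatrix) else m
    if values.isna().any().any():
        raise ValueError("NormFinder requires a complete Cq matrix")
    return values


def center_by_sample(m: CqMatrix | pd.DataFrame) -> pd.DataFrame:
    """z_ij = x_ij - (mean over genes of sample i); column sums become 0."""
    values = _matrix(m)
    return values - values.mean(axis=0)


def _corrected_sigma2(s2: np.ndarray, k: int) -> np.ndarray:
    """Moment correction for the k-gene centering; clamps negatives to 0."""
    if k < 3:
        raise ValueError("variance correction requires >= 3 genes")
    return np.maximum(0.0, (s2 - s2.mean() / (k - 1)) * k / (k - 2))


def normfinder_ungrouped(m: CqMatrix | pd.DataFrame) -> NormFinderResult:
    """Stability = sqrt of the corrected per-gene variance of centered Cq."""
    values = _matrix(m)
    k, n = values.shape
    if k < 3:
        raise ValueError("NormFinder requires >= 3 genes")
    if n < 3:
        raise ValueError("NormFinder requires >= 3 samples")
    z = center_by_sample(values)
    s2 = z.var(axis=1, ddof=1).to_numpy()
    sigma2 = _corrected_sigma2(s2, k)
    return NormFinderResult(
        stability=pd.Series(np.sqrt(sigma2), index=values.index, name="stability"),
        sigma2_hat=pd.Series(sigma2, index=values.index, name="sigma2_hat"),
    )


def normfinder_grouped(
    m: CqMatrix | pd.DataFrame, ann: SampleAnnotation | pd.Series
) -> NormFinderResult:
    """Grouped stability combining shrunken group deviations and noise terms."""
    values = _matrix(m)
    k = values.shape[0]
    if k < 3:
        raise ValueError("NormFinder requires >= 3 genes")
    groups = (
        ann.groups_for(list(values.columns))
        if isinstance(ann, SampleAnnotation)
        else pd.Series(ann).reindex(values.columns)
    )
    if groups.isna().any():
        raise ValueError(f"samples without group label: "
                         f"{list(groups.index[groups.isna()])}")
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("grouped analysis requires >= 2 groups")
    counts = groups.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"groups with < 3 samples: {dict(small)}")

    z = center_by_sample(values)
    group_means = pd.DataFrame(index=values.index, columns=labels, dtype=float)
    sigma2 = pd.DataFrame(index=values.index, columns=labels, dtype=float)
    for g in labels:
        cols = groups.index[groups == g]
        zg = z[cols]
        group_means[g] = zg.mean(axis=1)
        sigma2[g] = _corrected_sigma2(zg.var(axis=1, ddof=1).to_numpy(), k)
    d_hat = group_means.sub(group_means.mean(axis=1), axis=0)

    n_g = pd.Series({g: int(counts[g]) for g in labels})
    noise = sigma2 / n_g  # per (gene, group) sampling variance of d
    gamma2 = max(0.0, float(np.var(d_hat.to_numpy(), ddof=1) - noise.to_numpy().mean()))
    shrink = gamma2 / (gamma2 + noise) if gamma2 > 0 else noise * 0.0
    d_shrunk = d_hat * shrink

    stability = (d_shrunk.abs() + np.sqrt(noise)).mean(axis=1)
    return NormFinderResult(
        stability=stability.rename("stability"),
        sigma2_hat=sigma2.mean(axis=1).rename("sigma2_hat"),
        grouped=True,
        d_hat=d_hat,
        d_shrunk=d_shrunk,
        gamma2_hat=gamma2,
        n_per_group=n_g,
    )
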