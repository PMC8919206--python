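"""Standard-curve fitting and amplification-efficiency math.

A qPCR standard curve regresses Cq on log10 template amount over a serial
dilution (classically six 10-fold steps, 1e4..1e9 copies/uL). The slope
gives the per-cycle amplification factor A and the efficiency percentage

    E = (10**(-1/slope) - 1) * 100,        A = 1 + E/100.

Perfect doubling (A = 2) corresponds to slope -1/log10(2) = -3.321928 and
E = 100%. Assays with E roughly in the 90-110% band are conventionally
considered acceptable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Slope of an ideal (perfect-doubling) standard curve, cycles per log10 unit.
PERFECT_SLOPE: float = -1.0 / np.log10(2.0)


class DegenerateDesignError(ValueError):
    """All dilution points share one template amount; slope is unidentifiable."""


@dataclass
class DilutionSeries:
    """Dilution points for one assay: log10 template amount vs measured Cq."""

    log10_amount: np.ndarray
    cq: np.ndarray
    gene_id: str | None = None

    def __post_init__(self) -> None:
        self.log10_amount = np.asarray(self.log10_amount, dtype=float)
        self.cq = np.asarray(self.cq, dtype=float)
        if self.log10_amount.shape != self.cq.shape:
            raise ValueError("log10_amount and cq must have equal length")
        if len(np.unique(self.log10_amount)) < 3:
            raise ValueError("need >= 3 distinct log10_amount values")
        if not np.all(np.isfinite(self.cq)):
            raise ValueError("non-finite Cq in dilution series")


@dataclass
class StandardCurveFit:
    """OLS fit of Cq on log10 amount, plus derived efficiency quantities."""

    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float
    amplification_factor: float
    gene_id: str | None = None

    def predict(self, log10_amount: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(log10_amount, dtype=float)


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent from a standard-curve slope.

    E = (10**(-1/slope) - 1) * 100. Raises on slope 0; a positive slope
    (Cq rising with template) is almost certainly a data error and triggers
    a warning, but the value is still returned.
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    if slope > 0:
        warnings.warn(
            "positive standard-curve slope: Cq increasing with template "
            "amount (anti-correlated curve)", stacklevel=2)
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def amplification_factor(efficiency_percent: float) -> float:
    """Per-cycle fold change A = 1 + E/100 (A = 2 at 100% efficiency)."""
    if efficiency_percent <= -100.0:
        raise ValueError("efficiency must exceed -100%")
    return 1.0 + efficiency_percent / 100.0


def slope_from_factor(factor: float) -> float:
    """Standard-curve slope implied by a per-cycle factor: -1/log10(A)."""
    if factor <= 1.0:
        raise ValueError("amplification factor must exceed 1")
    return -1.0 / np.log10(factor)


def fit_standard_curve(series: DilutionSeries) -> StandardCurveFit:
    """Fit Cq = intercept + slope * log10(amount) by ordinary least squares.

    R^2 is the squared Pearson correlation, i.e. the determination
    coefficient of the simple linear regression.
    """
    x, y = series.log10_amount, series.cq
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all dilution points share one amount")
    res = stats.linregress(x, y)
    eff = efficiency_from_slope(res.slope)
    return StandardCurveFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        efficiency_percent=float(eff),
        amplification_factor=amplification_factor(eff),
        gene_id=series.gene_id,
    )


def read_dilution_table(path, sep: str | None = None) -> list[DilutionSeries]:
    """Read a curve TSV/CSV with headers ``gene``, ``log10_amount``, ``cq``."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    needed = {"gene", "log10_amount", "cq"}
    if not needed.issubset(df.columns):
        raise ValueError(f"curve table requires headers {sorted(needed)}")
    return [
        DilutionSeries(sub["log10_amount"].to_numpy(), sub["cq"].to_numpy(), gene)
        for gene, sub in df.groupby("gene", sort=False)
    ]


def fits_to_frame(fits: list[StandardCurveFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [f.gene_id for f in fits],
            "slope": [f.slope for f in fits],
            "intercept": [f.intercept for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "efficiency_percent": [f.efficiency_percent for f in fits],
        }
    )
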