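"""Cq (quantification-cycle) data model: reading, validation, replicate averaging.

RT-qPCR instruments report, per well, the cycle at which amplification
fluorescence crosses a threshold (Cq, historically Ct). Cq is a log-scale
proxy for starting template amount: one cycle difference is one fold-change
at perfect doubling. Experiments measure each (sample, gene) in technical
replicates; downstream stability analysis works on the replicate-averaged
genes x samples matrix.

Two plain-text layouts are supported:

* wide  -- first column header ``gene``, remaining headers are sample ids,
  one row per gene; yields a :class:`CqMatrix` directly.
* long  -- required headers ``sample``, ``gene``, ``replicate``, ``cq``
  (optional ``group``); yields a :class:`ReplicateTable`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default validity interval for Cq values, in cycles. The upper bound sits
#: above the common 40-cycle protocol ceiling; values outside it almost always
#: indicate parsing or instrument-export problems rather than biology.
CQ_RANGE: tuple[float, float] = (0.0, 45.0)

LONG_COLUMNS = ("sample", "gene", "replicate", "cq")


class CqParseError(ValueError):
    """Malformed Cq table: names the offending row/column."""


@dataclass
class ReplicateTable:
    """Replicate-level Cq records: one row per (sample, gene, replicate).

    Parameters
    ----------
    data
        DataFrame with columns ``sample``, ``gene``, ``replicate``, ``cq``
        and optionally ``group``. Replicate indices must be unique within a
        (sample, gene) cell; Cq values must be finite and inside
        ``cq_range`` (missing values allowed when ``allow_missing``).
    """

    data: pd.DataFrame
    cq_range: tuple[float, float] = CQ_RANGE
    allow_missing: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in LONG_COLUMNS if c not in self.data.columns]
        if missing:
            raise CqParseError(f"long table missing required columns: {missing}")
        dup = self.data.duplicated(subset=["sample", "gene", "replicate"])
        if dup.any():
            row = self.data.loc[dup.idxmax()]
            raise CqParseError(
                "duplicate replicate index "
                f"{row['replicate']!r} for (sample={row['sample']!r}, gene={row['gene']!r})"
            )
        cq = self.data["cq"].to_numpy(dtype=float)
        bad = ~np.isfinite(cq)
        if bad.any() and not self.allow_missing:
            i = int(np.flatnonzero(bad)[0])
            row = self.data.iloc[i]
            raise CqParseError(
                f"non-finite Cq for (sample={row['sample']!r}, gene={row['gene']!r})"
            )
        lo, hi = self.cq_range
        out = np.isfinite(cq) & ((cq <= lo) | (cq > hi))
        if out.any():
            i = int(np.flatnonzero(out)[0])
            row = self.data.iloc[i]
            raise CqParseError(
                f"Cq {row['cq']} outside ({lo}, {hi}] for "
                f"(sample={row['sample']!r}, gene={row['gene']!r})"
            )

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.data["gene"]))

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.data["sample"]))

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class CqMatrix:
    """Genes x samples matrix of (replicate-averaged) Cq values.

    ``values`` is indexed by gene id with sample ids as columns. Order is
    meaningful (first-seen order from the input) and preserved throughout.
    NaN marks a missing cell; stability computations require complete cases
    and drop incomplete samples via :meth:`complete`.
    """

    values: pd.DataFrame
    cq_range: tuple[float, float] = CQ_RANGE

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise CqParseError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise CqParseError(f"duplicate sample ids: {dups}")
        self.values = self.values.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def complete(self) -> "CqMatrix":
        """Drop samples containing any missing gene, logging the drop."""
        bad = self.values.columns[self.values.isna().any(axis=0)]
        if len(bad):
            logger.warning(
                "dropping %d sample(s) with missing Cq values: %s",
                len(bad), list(bad),
            )
            return CqMatrix(self.values.drop(columns=bad), self.cq_range)
        return self

    def to_wide_tsv(self, path: str | Path, sep: str = "\t") -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep=sep, na_rep="NA")


@dataclass
class SampleAnnotation:
    """Per-sample condition labels (group/condition and replicate id)."""

    data: pd.DataFrame  # columns: sample, group, optional replicate_id

    def __post_init__(self) -> None:
        for col in ("sample", "group"):
            if col not in self.data.columns:
                raise CqParseError(f"annotation missing column {col!r}")
        if self.data["sample"].duplicated().any():
            dup = self.data.loc[self.data["sample"].duplicated(), "sample"].tolist()
            raise CqParseError(f"duplicate sample ids in annotation: {dup}")

    def groups_for(self, samples: Sequence[str]) -> pd.Series:
        """Group label per sample, ordered like ``samples``."""
        mapping = self.data.set_index("sample")["group"]
        missing = [s for s in samples if s not in mapping.index]
        if missing:
            raise CqParseError(f"samples without annotation: {missing}")
        return mapping.reindex(samples)


@dataclass
class ValidationIssue:
    kind: str      # "range" | "missing" | "dimension"
    message: str
    gene: str | None = None
    sample: str | None = None


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __iter__(self):
        return iter(self.issues)

    def __len__(self) -> int:
        return len(self.issues)


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_cq_table(
    path: str | Path,
    layout: str = "wide",
    allow_missing: bool = False,
    cq_range: tuple[float, float] = CQ_RANGE,
) -> ReplicateTable | CqMatrix:
    """Read a Cq table from TSV/CSV.

    ``layout='wide'`` returns a :class:`CqMatrix`; ``layout='long'`` a
    :class:`ReplicateTable`. ``NA``/empty cells become missing markers when
    ``allow_missing`` is set and raise otherwise. Gene and sample order is
    preserved as first seen.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path)
    if layout == "wide":
        df = pd.read_csv(path, sep=sep, dtype={0: str}, na_values=["NA", ""])
        if df.columns[0] != "gene":
            raise CqParseError(
                f"wide layout requires first header 'gene', got {df.columns[0]!r}"
            )
        df = df.set_index("gene")
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.argmax()]
                raise CqParseError(
                    f"malformed numeric cell at gene={gene!r}, sample={col!r}: "
                    f"{df.loc[gene, col]!r}"
                )
            df[col] = coerced
        if df.isna().any().any() and not allow_missing:
            sample = df.columns[df.isna().any(axis=0).argmax()]
            gene = df.index[df[sample].isna().argmax()]
            raise CqParseError(
                f"missing Cq at gene={gene!r}, sample={sample!r} "
                "(pass allow_missing=True to accept)"
            )
        return CqMatrix(df, cq_range)
    if layout == "long":
        df = pd.read_csv(path, sep=sep, na_values=["NA", ""])
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise CqParseError(f"long layout requires headers {LONG_COLUMNS}, missing {missing}")
        coerced = pd.to_numeric(df["cq"], errors="coerce")
        bad = coerced.isna() & df["cq"].notna()
        if bad.any():
            row = df.loc[bad.idxmax()]
            raise CqParseError(
                f"malformed Cq {row['cq']!r} at sample={row['sample']!r}, gene={row['gene']!r}"
            )
        df["cq"] = coerced
        df["sample"] = df["sample"].astype(str)
        df["gene"] = df["gene"].astype(str)
        return ReplicateTable(df, cq_range, allow_missing)
    raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def write_replicate_table(reps: ReplicateTable, path: str | Path) -> None:
    reps.data.to_csv(path, sep=_sep_for(path), index=False, na_rep="NA")


def read_sample_annotation(path: str | Path) -> SampleAnnotation:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    return SampleAnnotation(df)


def average_technical_replicates(reps: ReplicateTable) -> CqMatrix:
    """Collapse technical replicates to their arithmetic mean Cq.

    The mean is the standard aggregation for technical replicates; no
    outlier rejection is applied. Output rows/columns follow first-seen
    gene/sample order from the replicate table.
    """
    genes = reps.genes
    samples = reps.samples
    means = (
        reps.data.groupby(["gene", "sample"], sort=False)["cq"]
        .mean()
        .unstack("sample")
        .reindex(index=genes, columns=samples)
    )
    return CqMatrix(means, reps.cq_range)


def validate_cq_matrix(
    m: CqMatrix,
    min_genes: int = 2,
    min_samples: int = 3,
    cq_range: tuple[float, float] | None = None,
) -> ValidationReport:
    """Collect range, missingness and dimension violations (non-raising)."""
    lo, hi = cq_range if cq_range is not None else m.cq_range
    report = ValidationReport()
    if m.n_genes < min_genes:
        report.issues.append(ValidationIssue(
            "dimension", f"{m.n_genes} gene(s), need >= {min_genes}"))
    if m.n_samples < min_samples:
        report.issues.append(ValidationIssue(
            "dimension", f"{m.n_samples} sample(s), need >= {min_samples}"))
    vals = m.values.to_numpy()
    for i, j in zip(*np.nonzero(~np.isfinite(vals))):
        report.issues.append(ValidationIssue(
            "missing", "missing/non-finite Cq",
            gene=m.genes[i], sample=m.samples[j]))
    with np.errstate(invalid="ignore"):
        out = np.isfinite(vals) & ((vals <= lo) | (vals > hi))
    for i, j in zip(*np.nonzero(out)):
        report.issues.append(ValidationIssue(
            "range", f"Cq {vals[i, j]} outside ({lo}, {hi}]",
            gene=m.genes[i], sample=m.samples[j]))
    return report
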