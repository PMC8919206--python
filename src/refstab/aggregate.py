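"""Geometric-mean rank aggregation across stability methods.

Each method contributes competition ranks (ties share the minimum rank and
the next rank skips: 1, 1, 3, ...). The comprehensive score per gene is the
geometric mean of its method ranks; genes are ordered ascending in that
score. Ties on the geometric mean are broken deterministically by a chain
applied one link at a time: mean rank, then the NormFinder rank when that
method is present (the model-based method is the natural arbiter between
genes the consensus cannot separate), then input gene order. Internally the
sort keys are exact integers (rank product / rank sum), so equal products
never suffer float-equality surprises.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class MethodRanking:
    """One method's stability values and competition ranks over a gene set."""

    method: str
    values: pd.Series   # per-gene stability (lower = more stable by default)
    ranks: pd.Series    # competition ranks starting at 1

    @property
    def genes(self) -> list[str]:
        return list(self.ranks.index)


@dataclass
class AggregateRanking:
    """Per-gene method ranks, geometric-mean rank and final ordering."""

    table: pd.DataFrame      # columns: rank_<method>..., geo_mean, final_rank
    ordering: list[str]      # most stable first
    tie_breaks: list[str]    # log of tie-break decisions taken

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index(names="gene")


@dataclass
class OrderingMatchReport:
    matches: bool
    computed: list[str]
    expected: list[str]
    first_divergence: int | None = None  # 0-based position, None if equal


def rank_from_stability(values: pd.Series, ascending: bool = True) -> MethodRanking:
    """Competition ranks from stability values (lower value = rank 1)."""
    values = pd.Series(values, dtype=float)
    if not np.all(np.isfinite(values.to_numpy())):
        bad = values.index[~np.isfinite(values)].tolist()
        raise ValueError(f"non-finite stability values for: {bad}")
    ranks = values.rank(method="min", ascending=ascending).astype(int)
    return MethodRanking("unnamed", values, ranks)


def aggregate_geometric(
    rankings: Sequence[MethodRanking],
    normfinder_method: str = "normfinder",
) -> AggregateRanking:
    """Aggregate 2..M method rankings by geometric mean of ranks.

    All rankings must cover an identical gene set. Ordering ties are broken
    by mean rank, then the NormFinder rank (if such a method is present),
    then input gene order; each link applies only when the previous ties,
    and every invocation is logged.
    """
    if len(rankings) < 2:
        raise ValueError("aggregation requires >= 2 method rankings")
    genes = rankings[0].genes
    gene_set = set(genes)
    for r in rankings[1:]:
        if set(r.genes) != gene_set:
            extra = sorted(set(r.genes) - gene_set)
            missing = sorted(gene_set - set(r.genes))
            raise ValueError(
                f"gene-set mismatch in method {r.method!r}: "
                f"extra={extra}, missing={missing}"
            )

    rank_mat = pd.DataFrame(
        {f"rank_{r.method}": r.ranks.reindex(genes) for r in rankings}, index=genes
    )
    prod = rank_mat.prod(axis=1)
    total = rank_mat.sum(axis=1)
    geo_mean = prod.astype(float) ** (1.0 / len(rankings))

    nf_col = f"rank_{normfinder_method}"
    nf = rank_mat[nf_col] if nf_col in rank_mat.columns else pd.Series(0, index=genes)
    order_index = pd.Series(range(len(genes)), index=genes)

    key = pd.DataFrame({"prod": prod, "total": total, "nf": nf, "pos": order_index})
    ordering = list(key.sort_values(["prod", "total", "nf", "pos"]).index)

    tie_breaks: list[str] = []
    for val, grp in key.groupby("prod"):
        if len(grp) > 1:
            members = list(grp.sort_values(["total", "nf", "pos"]).index)
            if grp["total"].nunique() > 1:
                how = "mean rank"
            elif grp["nf"].nunique() > 1:
                how = "NormFinder rank"
            else:
                how = "input order"
            msg = f"tie on geometric mean among {members}: broken by {how}"
            tie_breaks.append(msg)
            logger.info(msg)

    table = rank_mat.copy()
    table["geo_mean"] = geo_mean
    final = pd.Series({g: i + 1 for i, g in enumerate(ordering)}, name="final_rank")
    table["final_rank"] = final.reindex(genes)
    return AggregateRanking(table, ordering, tie_breaks)


def reproduce_condition_ordering(
    table: pd.DataFrame,
    printed_order: Sequence[str],
    normfinder_method: str = "normfinder",
) -> OrderingMatchReport:
    """Aggregate per-method rank columns and compare to a published ordering.

    ``table`` is indexed by gene with one ``rank_<method>`` column per
    method (stability-value columns, if present, are ignored: aggregation
    consumes ranks).
    """
    rank_cols = [c for c in table.columns if c.startswith("rank_")]
    if len(rank_cols) < 2:
        raise ValueError("need >= 2 rank_<method> columns")
    rankings = [
        MethodRanking(c.removeprefix("rank_"),
                      table[c].astype(float), table[c].astype(int))
        for c in rank_cols
    ]
    agg = aggregate_geometric(rankings, normfinder_method=normfinder_method)
    expected = list(printed_order)
    computed = agg.ordering
    first_div = next(
        (i for i, (a, b) in enumerate(zip(computed, expected)) if a != b), None
    )
    if len(computed) != len(expected) and first_div is None:
        first_div = min(len(computed), len(expected))
    return OrderingMatchReport(first_div is None, computed, expected, first_div)


# ---------------------------------------------------------------------------
# Published reference data: per-method stability ranks for 12 candidate
# reference genes of the pharaoh ant (Monomorium pharaonis) across seven
# experimental conditions, and the corresponding published comprehensive
# orderings. Used by the validation/acceptance layer.

def load_published_ranks() -> pd.DataFrame:
    """Long table: condition, gene, rank_genorm/normfinder/bestkeeper/deltact."""
    with resources.files("refstab.data").joinpath("published_ranks.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_published_orderings() -> dict[str, list[str]]:
    """Published comprehensive ordering per condition, most stable first."""
    with resources.files("refstab.data").joinpath("published_orderings.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return {
        cond: list(sub.sort_values("position")["gene"])
        for cond, sub in df.groupby("condition", sort=False)
    }


def published_rank_table(condition: str) -> pd.DataFrame:
    """Gene-indexed rank_<method> table for one published condition."""
    df = load_published_ranks()
    sub = df[df["condition"] == condition]
    if sub.empty:
        known = list(pd.unique(df["condition"]))
        raise KeyError(f"unknown condition {condition!r}; available: {known}")
    return sub.set_index("gene").drop(columns="condition")
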