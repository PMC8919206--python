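"""RNA-seq pre-selection of candidate reference genes.

Candidates come from homolog families of widely used reference genes
(Actin, RPL, Tubulin, GAPDH, RPS, 18S, EF1A, TATA, HSP, SDHA...). Given a
TPM matrix over developmental stages and a gene -> family map, the screen:

1. drops lowly expressed genes (TPM below a floor in too many stages);
2. variance-stabilizes expression so SD does not simply track the mean;
3. ranks genes within each family by SD across stages;
4. picks, per family, the lowest-SD gene that is also abundantly expressed
   (TPM above a high threshold in enough stages) — abundance matters
   because a reference assay must amplify reliably in every sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """TPM per (gene, stage); rows genes, columns stages."""

    tpm: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")
        if self.tpm.shape[1] < 2:
            raise ValueError("need >= 2 stages")

    @property
    def genes(self) -> list[str]:
        return list(self.tpm.index)


@dataclass
class FamilyMap:
    """gene_id -> family label; each gene belongs to exactly one family."""

    mapping: pd.Series

    @property
    def families(self) -> list[str]:
        return list(pd.unique(self.mapping))

    def genes_in(self, family: str) -> list[str]:
        return list(self.mapping.index[self.mapping == family])


@dataclass
class CandidateSelection:
    surviving_genes: list[str]
    sd_vst: pd.Series                 # per surviving gene, SD across stages
    table: pd.DataFrame               # family, gene, sd_vst, n_high_stages, selected, reason
    chosen: dict[str, str | None]     # family -> winning gene (None if empty)


def filter_low_expression(
    e: ExpressionMatrix, tpm_floor: float = 5.0, max_low_stages: int = 2
) -> ExpressionMatrix:
    """Remove genes with TPM < ``tpm_floor`` in >= ``max_low_stages`` stages."""
    low_counts = (e.tpm < tpm_floor).sum(axis=1)
    keep = low_counts < max_low_stages
    return ExpressionMatrix(e.tpm.loc[keep])


def variance_stabilize(e: ExpressionMatrix, method: str = "log2p1") -> pd.DataFrame:
    """Monotone variance-stabilizing transform of TPM.

    ``log2p1``: log2(tpm + 1) — the workhorse for TPM-scale data.
    ``anscombe``: 2*sqrt(tpm + 3/8) — Poisson-flavoured alternative.
    """
    tpm = e.tpm
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    if method == "log2p1":
        return np.log2(tpm + 1.0)
    if method == "anscombe":
        return 2.0 * np.sqrt(tpm + 0.375)
    raise ValueError(f"unknown VST method {method!r}")


def rank_by_sd(t: pd.DataFrame, fam: FamilyMap) -> pd.DataFrame:
    """Per-gene SD across stages (n-1) with ascending rank within family."""
    genes = [g for g in t.index if g in fam.mapping.index]
    sd = t.loc[genes].std(axis=1, ddof=1)
    out = pd.DataFrame(
        {"family": fam.mapping.reindex(genes), "sd_vst": sd}
    )
    out["family_rank"] = out.groupby("family")["sd_vst"].rank(method="first").astype(int)
    return out.sort_values(["family", "family_rank"])


def select_candidates(
    raw: ExpressionMatrix,
    fam: FamilyMap,
    transformed: pd.DataFrame | None = None,
    tpm_floor: float = 5.0,
    max_low_stages: int = 2,
    tpm_high: float = 1000.0,
    min_high_stages: int = 8,
    vst_method: str = "log2p1",
) -> CandidateSelection:
    """Full screen: low-expression filter, VST SD ranking, per-family pick.

    Per family the winner is the lowest-SD gene among those with TPM above
    ``tpm_high`` in at least ``min_high_stages`` stages; a family where no
    survivor qualifies is reported empty with the reason. SD ties resolve
    to the first gene in input order.
    """
    filtered = filter_low_expression(raw, tpm_floor, max_low_stages)
    if transformed is None:
        transformed = variance_stabilize(filtered, vst_method)
    else:
        transformed = transformed.loc[[g for g in transformed.index
                                       if g in filtered.tpm.index]]
    in_family = [g for g in filtered.genes if g in fam.mapping.index]
    sd = transformed.loc[in_family].std(axis=1, ddof=1)
    n_high = (filtered.tpm.loc[in_family] > tpm_high).sum(axis=1)

    rows = []
    chosen: dict[str, str | None] = {}
    for family in fam.families:
        members = [g for g in in_family if fam.mapping[g] == family]
        ordered = sorted(members, key=lambda g: (sd[g], members.index(g)))
        winner = None
        for g in ordered:
            if n_high[g] >= min_high_stages:
                winner = g
                break
        chosen[family] = winner
        for g in members:
            if g == winner:
                if ordered and ordered[0] != g:
                    reason = (f"lowest-SD qualifying gene "
                              f"({ordered[0]} fails TPM>{tpm_high:g} "
                              f"in >={min_high_stages} stages)")
                else:
                    reason = "lowest SD and abundance criteria met"
            elif n_high[g] < min_high_stages:
                reason = (f"TPM > {tpm_high:g} in only {int(n_high[g])} "
                          f"stage(s), need >= {min_high_stages}")
            else:
                reason = "higher SD than selected family member"
            rows.append({"family": family, "gene": g,
                         "sd_vst": float(sd[g]),
                         "n_high_stages": int(n_high[g]),
                         "selected": g == winner, "reason": reason})
        if winner is None:
            rows.append({"family": family, "gene": "",
                         "sd_vst": float("nan"), "n_high_stages": 0,
                         "selected": False,
                         "reason": "no family member passes the abundance rule"
                         if members else "no family member survives filtering"})
    table = pd.DataFrame(rows,
                         columns=["family", "gene", "sd_vst", "n_high_stages",
                                  "selected", "reason"])
    return CandidateSelection(list(filtered.genes), sd, table, chosen)


def read_tpm_table(path) -> ExpressionMatrix:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep).set_index("gene")
    return ExpressionMatrix(df.astype(float))


def read_family_map(path) -> FamilyMap:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    return FamilyMap(df.set_index("gene")["family"])
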