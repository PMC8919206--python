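"""Synthetic Cq experiments, standard curves and TPM matrices with known truth.

The Cq generative model is additive on the cycle (log-expression) scale:

    Cq_ijr = B_j + L_i + Delta_{g(i), j} + eps_ij + tau_ijr

with gene baseline B_j, per-sample loading offset L_i ~ N(0, loading_sd^2)
(pipetting / input-amount variation, shared by all genes of a sample),
optional per-group condition effects Delta, per-(gene, sample) biological
noise eps ~ N(0, sigma_j^2) and technical replicate noise tau ~ N(0,
tech_sd^2). Because Cq is log-domain, multiplicative expression noise is
additive here. Among genes without condition effects the true stability
order is ascending sigma_j.

Defaults mirror a realistic RT-qPCR validation design: 12 candidate genes,
36 samples, 3 technical replicates, baselines spread over 14-33 cycles,
loading SD 1 cycle, gene noise SDs spread 0.05-1.2 cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .candidates import ExpressionMatrix, FamilyMap
from .cq import CqMatrix, ReplicateTable, SampleAnnotation
from .standard_curve import DilutionSeries, slope_from_factor


def default_gene_noise_sd(n_genes: int) -> np.ndarray:
    """Evenly spread biological noise SDs from 0.05 to 1.2 cycles."""
    return np.linspace(0.05, 1.2, n_genes)


def default_baselines(n_genes: int) -> np.ndarray:
    """Gene baseline Cq spread over 14-33 cycles (abundant to scarce)."""
    return np.linspace(14.0, 33.0, n_genes)


@dataclass
class SimulationConfig:
    n_genes: int = 12
    n_samples: int = 36
    n_tech_reps: int = 3
    baselines: np.ndarray | None = None       # B_j, cycles
    loading_sd: float = 1.0                   # SD of L_i, cycles
    gene_noise_sd: np.ndarray | None = None   # sigma_j, cycles
    tech_sd: float = 0.1                      # tau SD, cycles
    group_labels: list[str] | None = None     # per-sample labels, len n_samples
    group_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    # (group_label, gene_id) -> Delta in cycles
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_samples < 3 or self.n_tech_reps < 1:
            raise ValueError("need >= 2 genes, >= 3 samples, >= 1 replicate")
        if self.baselines is None:
            self.baselines = default_baselines(self.n_genes)
        self.baselines = np.asarray(self.baselines, dtype=float)
        if self.gene_noise_sd is None:
            self.gene_noise_sd = default_gene_noise_sd(self.n_genes)
        self.gene_noise_sd = np.asarray(self.gene_noise_sd, dtype=float)
        if len(self.baselines) != self.n_genes:
            raise ValueError("baselines length must equal n_genes")
        if len(self.gene_noise_sd) != self.n_genes:
            raise ValueError("gene_noise_sd length must equal n_genes")
        for name, val in (("loading_sd", self.loading_sd), ("tech_sd", self.tech_sd)):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if (self.gene_noise_sd < 0).any():
            raise ValueError("gene_noise_sd must be >= 0")
        if self.group_labels is not None and len(self.group_labels) != self.n_samples:
            raise ValueError("group_labels length must equal n_samples")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{j+1:02d}" for j in range(self.n_genes)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i+1:02d}" for i in range(self.n_samples)]


@dataclass
class GroundTruth:
    baselines: pd.Series
    loading: pd.Series
    gene_noise_sd: pd.Series
    group_effects: dict[tuple[str, str], float]
    stability_order: list[str]  # ascending sigma among zero-effect genes


@dataclass
class SyntheticExperiment:
    replicates: ReplicateTable
    annotation: SampleAnnotation
    truth: GroundTruth
    mean_cq: CqMatrix  # noise-realized per-(gene, sample) means (pre tech noise)


def generate_cq_experiment(cfg: SimulationConfig) -> SyntheticExperiment:
    """Draw a replicate-level Cq experiment from the additive model."""
    rng = np.random.default_rng(cfg.seed)
    genes, samples = cfg.gene_ids, cfg.sample_ids
    groups = cfg.group_labels or ["all"] * cfg.n_samples

    loading = rng.normal(0.0, cfg.loading_sd, cfg.n_samples)
    eps = rng.normal(0.0, 1.0, (cfg.n_genes, cfg.n_samples)) * cfg.gene_noise_sd[:, None]
    delta = np.zeros((cfg.n_genes, cfg.n_samples))
    for (grp, gene), eff in cfg.group_effects.items():
        if gene not in genes:
            raise ValueError(f"group effect on unknown gene {gene!r}")
        j = genes.index(gene)
        cols = [i for i, g in enumerate(groups) if g == grp]
        if not cols:
            raise ValueError(f"group effect on unknown group {grp!r}")
        delta[j, cols] = eff

    mean_cq = cfg.baselines[:, None] + loading[None, :] + delta + eps
    tau = rng.normal(0.0, cfg.tech_sd, (cfg.n_genes, cfg.n_samples, cfg.n_tech_reps))
    cq = mean_cq[:, :, None] + tau

    records = []
    for i, s in enumerate(samples):
        for j, g in enumerate(genes):
            for r in range(cfg.n_tech_reps):
                records.append((s, g, r + 1, cq[j, i, r], groups[i]))
    reps = ReplicateTable(pd.DataFrame(
        records, columns=["sample", "gene", "replicate", "cq", "group"]))
    ann = SampleAnnotation(pd.DataFrame(
        {"sample": samples, "group": groups,
         "replicate_id": [str(i + 1) for i in range(cfg.n_samples)]}))

    affected = {gene for (_, gene) in cfg.group_effects}
    quiet = [g for g in genes if g not in affected]
    order = sorted(quiet, key=lambda g: cfg.gene_noise_sd[genes.index(g)])
    truth = GroundTruth(
        baselines=pd.Series(cfg.baselines, index=genes),
        loading=pd.Series(loading, index=samples),
        gene_noise_sd=pd.Series(cfg.gene_noise_sd, index=genes),
        group_effects=dict(cfg.group_effects),
        stability_order=order,
    )
    mean_matrix = CqMatrix(pd.DataFrame(mean_cq, index=genes, columns=samples))
    return SyntheticExperiment(reps, ann, truth, mean_matrix)


def generate_standard_curve(
    true_factor: float = 2.0,
    intercept: float = 40.0,
    noise_sd: float = 0.0,
    n_points: int = 6,
    log10_start: float = 4.0,
    seed: int = 0,
    gene_id: str | None = None,
) -> DilutionSeries:
    """Ten-fold dilution curve (log10 grid 4..4+n-1) under a true factor.

    Cq = intercept + slope * log10(amount) with slope = -1/log10(A),
    plus optional Gaussian cycle noise.
    """
    slope = slope_from_factor(true_factor)
    rng = np.random.default_rng(seed)
    x = log10_start + np.arange(n_points, dtype=float)
    y = intercept + slope * x + rng.normal(0.0, noise_sd, n_points)
    return DilutionSeries(x, y, gene_id)


def generate_tpm_matrix(
    n_families: int = 8,
    genes_per_family: int = 3,
    n_stages: int = 16,
    seed: int = 0,
    mean_log2_tpm: tuple[float, float] = (2.0, 12.0),
    sd_log2: tuple[float, float] = (0.1, 1.5),
) -> tuple[ExpressionMatrix, FamilyMap, dict]:
    """Log-normal TPM matrix with per-family structure and known truth.

    Each family gets ``genes_per_family`` members with graded dispersion
    (the first member is the least variable). Truth records which genes
    were built to fail the low-expression filter (one low-expression decoy
    per family, when family size allows) and each family's intended winner:
    the lowest-dispersion member that is also highly expressed.
    """
    rng = np.random.default_rng(seed)
    rows, fam_rows = [], []
    truth: dict = {"low_expression": [], "intended_winner": {}}
    for f in range(n_families):
        family = f"FAM{f+1}"
        base = rng.uniform(*mean_log2_tpm)
        sds = np.linspace(sd_log2[0], sd_log2[1], genes_per_family)
        winner = None
        for g in range(genes_per_family):
            gene = f"{family}_g{g+1}"
            fam_rows.append((gene, family))
            if genes_per_family >= 3 and g == genes_per_family - 1:
                # low-expression decoy: TPM < 5 in >= 2 stages
                expr = rng.uniform(5.5, 50.0, n_stages)
                expr[rng.choice(n_stages, 2, replace=False)] = rng.uniform(0.1, 4.0, 2)
                truth["low_expression"].append(gene)
            else:
                mu = max(base, 10.5) if g == 0 else base  # first member abundant
                expr = 2.0 ** rng.normal(mu, sds[g], n_stages)
                if g == 0:
                    winner = gene
            rows.append(pd.Series(expr, name=gene))
        truth["intended_winner"][family] = winner
    tpm = pd.DataFrame(rows)
    tpm.columns = [f"stage{s+1}" for s in range(n_stages)]
    fam = FamilyMap(pd.DataFrame(fam_rows, columns=["gene", "family"])
                    .set_index("gene")["family"])
    return ExpressionMatrix(tpm), fam, truth
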