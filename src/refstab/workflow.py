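"""End-to-end workflow: read Cq data, run methods, write a report directory.

Artifacts written by :func:`write_report` (TSV + JSON, deterministic given
inputs): ``genorm.tsv``, ``normfinder.tsv``, ``bestkeeper.tsv``,
``deltact.tsv`` (those requested), ``aggregate.tsv``,
``pairwise_variation.tsv`` and ``report.json`` with the config echo,
warnings and recommended gene number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .cq import read_cq_table, read_sample_annotation, average_technical_replicates, ReplicateTable
from .model import ALL_METHODS, ReferenceGeneStability, StabilityResults
from .standard_curve import read_dilution_table, fit_standard_curve, fits_to_frame

logger = logging.getLogger(__name__)


@dataclass
class WorkflowConfig:
    input_path: str
    layout: str = "wide"                      # wide | long
    methods: tuple[str, ...] = ALL_METHODS
    efficiency_source: str = "none"           # none | table | curves
    efficiency_path: str | None = None
    groups_path: str | None = None
    sd_estimator: str = "sample_sd"
    threshold: float = 0.15
    output_dir: str = "refstab_out"
    plots: bool = False

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one method required")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.efficiency_source not in ("none", "table", "curves"):
            raise ValueError("efficiency_source must be none|table|curves")
        if self.efficiency_source != "none" and not self.efficiency_path:
            raise ValueError("efficiency_source requires efficiency_path")


@dataclass
class StabilityReport:
    results: StabilityResults
    config: WorkflowConfig
    warnings: list[str] = field(default_factory=list)


def _load_efficiencies(cfg: WorkflowConfig):
    if cfg.efficiency_source == "none":
        return 2.0
    if cfg.efficiency_source == "table":
        sep = "," if cfg.efficiency_path.endswith(".csv") else "\t"
        df = pd.read_csv(cfg.efficiency_path, sep=sep)
        if not {"gene", "efficiency_percent"}.issubset(df.columns):
            raise ValueError("efficiency table needs headers gene, efficiency_percent")
        return 1.0 + df.set_index("gene")["efficiency_percent"] / 100.0
    series = read_dilution_table(cfg.efficiency_path)
    fits = [fit_standard_curve(s) for s in series]
    return pd.Series({f.gene_id: f.amplification_factor for f in fits})


def run_stability_workflow(cfg: WorkflowConfig) -> StabilityReport:
    """Replicate averaging -> per-method stability -> aggregation -> V-profile."""
    data = read_cq_table(cfg.input_path, layout=cfg.layout, allow_missing=True)
    if isinstance(data, ReplicateTable):
        matrix = average_technical_replicates(data)
    else:
        matrix = data
    groups = None
    if cfg.groups_path:
        groups = read_sample_annotation(cfg.groups_path)
    model = ReferenceGeneStability(
        matrix,
        groups=groups,
        efficiencies=_load_efficiencies(cfg),
        sd_estimator=cfg.sd_estimator,
        v_threshold=cfg.threshold,
    )
    results = model.fit(cfg.methods)
    return StabilityReport(results, cfg, list(results.warnings))


def write_report(report: StabilityReport, out_dir: str | Path) -> list[Path]:
    """Write per-method TSVs, the aggregate table, V-profile and report.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    res = report.results

    for method in res.methods:
        if method not in res.method_results:
            continue
        path = out / f"{method}.tsv"
        res.method_table(method).to_csv(path, sep="\t", index=False,
                                        float_format="%.6g")
        written.append(path)
    if res.aggregate is not None:
        path = out / "aggregate.tsv"
        res.aggregate.to_frame().to_csv(path, sep="\t", index=False,
                                        float_format="%.6g")
        written.append(path)
    else:
        logger.warning("aggregate skipped: needs >= 2 methods")
    if res.v_profile is not None:
        path = out / "pairwise_variation.tsv"
        res.v_profile.to_frame().to_csv(path, sep="\t", index=False,
                                        float_format="%.6g")
        written.append(path)

    meta = {
        "refstab_version": __version__,
        "config": asdict(report.config),
        "ranking": res.ranking,
        "recommended_n": res.recommended_n,
        "warnings": report.warnings,
    }
    path = out / "report.json"
    path.write_text(json.dumps(meta, indent=2) + "\n")
    written.append(path)

    if report.config.plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        ax = res.plot_stability()
        ax.figure.savefig(out / "stability.png", dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
        if res.v_profile is not None:
            ax = res.plot_pairwise_variation()
            ax.figure.savefig(out / "pairwise_variation.png", dpi=150,
                              bbox_inches="tight")
            plt.close(ax.figure)
    return written


def write_curve_report(curve_path: str, out_path: str | Path) -> Path:
    """Fit every assay in a dilution table; write gene/slope/R^2/E TSV."""
    fits = [fit_standard_curve(s) for s in read_dilution_table(curve_path)]
    out_path = Path(out_path)
    fits_to_frame(fits).to_csv(out_path, sep="\t", index=False,
                               float_format="%.6g")
    return out_path
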