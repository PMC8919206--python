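"""Model/Results interface over the stability methods.

`ReferenceGeneStability` is constructed from data (a Cq matrix, long-format
replicates, or a plain DataFrame) and `fit()` runs the requested methods,
returning a `StabilityResults` object that carries per-method stability
values, ranks, the aggregated comprehensive ranking, the geNorm pairwise
variation profile with the recommended number of reference genes, and a
`summary()` table. `StandardCurve`/`StandardCurveResults` do the same for
dilution-series efficiency fits.

Example
-------
>>> from refstab import simulate, model
>>> exp = simulate.generate_cq_experiment(simulate.SimulationConfig(seed=1))
>>> res = model.ReferenceGeneStability.from_replicates(exp.replicates).fit()
>>> res.ranking[:3]          # doctest: +SKIP
['G01', 'G02', 'G03']
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import bestkeeper as bk
from . import deltact as dc
from . import genorm as gn
from . import normfinder as nf
from .cq import (CqMatrix, ReplicateTable, SampleAnnotation,
                 average_technical_replicates, validate_cq_matrix)

ALL_METHODS = ("genorm", "normfinder", "bestkeeper", "deltact")


class ReferenceGeneStability:
    """Stability model for a panel of candidate reference genes.

    Parameters
    ----------
    data
        Complete Cq matrix (genes x samples) as `CqMatrix` or DataFrame.
        Samples with missing genes are dropped (logged) before analysis.
    groups
        Optional sample annotation; enables grouped NormFinder.
    efficiencies
        Per-gene amplification factors (fold per cycle) for the geNorm
        relative-quantity transform; default 2.0 (perfect doubling).
    sd_estimator
        BestKeeper spread flavour: ``sample_sd`` or ``mad_geo``.
    v_threshold
        Pairwise-variation cutoff for the recommended gene number.
    """

    def __init__(
        self,
        data: CqMatrix | pd.DataFrame,
        groups: SampleAnnotation | pd.Series | None = None,
        efficiencies: float | Mapping[str, float] | pd.Series | None = 2.0,
        sd_estimator: str = "sample_sd",
        v_threshold: float = gn.DEFAULT_V_THRESHOLD,
    ) -> None:
        m = data if isinstance(data, CqMatrix) else CqMatrix(pd.DataFrame(data))
        self.cq = m.complete()
        report = validate_cq_matrix(self.cq)
        if not report.ok:
            msgs = [f"{i.kind}: {i.message} (gene={i.gene}, sample={i.sample})"
                    for i in report]
            raise ValueError("invalid Cq matrix:\n" + "\n".join(msgs))
        self.groups = groups
        self.efficiencies = efficiencies
        self.sd_estimator = sd_estimator
        self.v_threshold = v_threshold

    @classmethod
    def from_replicates(cls, reps: ReplicateTable, **kwargs) -> "ReferenceGeneStability":
        """Build from replicate-level records, averaging technical replicates."""
        if "groups" not in kwargs and "group" in reps.data.columns:
            per_sample = reps.data.drop_duplicates("sample").set_index("sample")["group"]
            if per_sample.nunique() >= 2:  # a single label carries no design
                kwargs["groups"] = per_sample
        return cls(average_technical_replicates(reps), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ReferenceGeneStability":
        return cls(CqMatrix(df), **kwargs)

    def fit(self, methods: Sequence[str] = ALL_METHODS) -> "StabilityResults":
        """Run the requested stability methods and aggregate their ranks."""
        methods = list(methods)
        unknown = [m for m in methods if m not in ALL_METHODS]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; choose from {ALL_METHODS}")
        if not methods:
            raise ValueError("at least one method required")

        warnings_log: list[str] = []
        method_results: dict[str, object] = {}
        stabilities: dict[str, pd.Series] = {}
        v_profile = None

        if "genorm" in methods:
            q = gn.to_relative_quantities(self.cq, self.efficiencies)
            g = gn.genorm_rank(q)
            method_results["genorm"] = g
            stabilities["genorm"] = g.m_values
            v_profile = gn.pairwise_variation_profile(q, g, self.v_threshold)
        if "normfinder" in methods:
            if self.groups is not None:
                n = nf.normfinder_grouped(self.cq, self.groups)
            else:
                n = nf.normfinder_ungrouped(self.cq)
            method_results["normfinder"] = n
            stabilities["normfinder"] = n.stability
        if "bestkeeper" in methods:
            b = bk.bestkeeper_describe(self.cq, self.sd_estimator)
            method_results["bestkeeper"] = b
            stabilities["bestkeeper"] = b.stability
        if "deltact" in methods:
            d = dc.delta_ct_stability(self.cq)
            method_results["deltact"] = d
            stabilities["deltact"] = d.stability

        rankings = []
        for name in methods:
            s = stabilities[name]
            if s.isna().any():
                warnings_log.append(
                    f"method {name}: undefined stability for "
                    f"{list(s.index[s.isna()])}; excluded from aggregation")
                continue
            r = agg.rank_from_stability(s)
            r.method = name
            rankings.append(r)
        aggregate = None
        if len(rankings) >= 2:
            aggregate = agg.aggregate_geometric(rankings)
            warnings_log.extend(aggregate.tie_breaks)
        else:
            warnings_log.append("aggregation skipped: needs >= 2 methods")

        return StabilityResults(
            model=self,
            methods=methods,
            method_results=method_results,
            stabilities=stabilities,
            aggregate=aggregate,
            v_profile=v_profile,
            warnings=warnings_log,
        )


@dataclass
class StabilityResults:
    """Fitted stability analysis: per-method scores, ranks and aggregation."""

    model: ReferenceGeneStability
    methods: list[str]
    method_results: dict[str, object]
    stabilities: dict[str, pd.Series]
    aggregate: agg.AggregateRanking | None
    v_profile: gn.PairwiseVariationProfile | None
    warnings: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return self.model.cq.genes

    @property
    def ranking(self) -> list[str]:
        """Comprehensive ordering, most stable first."""
        if self.aggregate is not None:
            return self.aggregate.ordering
        only = next(iter(self.stabilities.values()))
        return list(only.sort_values().index)

    @property
    def recommended_n(self) -> int | None:
        return self.v_profile.recommended_n if self.v_profile else None

    def method_table(self, method: str) -> pd.DataFrame:
        res = self.method_results[method]
        return res.to_frame()

    def summary(self) -> str:
        """Human-readable stability report (per-method values and ranks)."""
        df = pd.DataFrame(index=self.genes)
        for name in self.methods:
            s = self.stabilities[name]
            r = s.rank(method="min")
            df[name] = [f"{s[g]:.3f} ({int(r[g])})" if np.isfinite(s[g]) else "NA"
                        for g in self.genes]
        if self.aggregate is not None:
            df["geo_mean"] = self.aggregate.table["geo_mean"].round(3)
            df["final_rank"] = self.aggregate.table["final_rank"]
            df = df.loc[self.ranking]
        lines = ["Reference-gene stability summary",
                 f"  genes: {len(self.genes)}  samples: {self.model.cq.n_samples}",
                 ""]
        lines.append(df.to_string())
        if self.v_profile is not None:
            vp = self.v_profile
            lines.append("")
            lines.append("Pairwise variation V(n, n+1) "
                         f"[threshold {vp.threshold}]:")
            for n in sorted(vp.v_values):
                mark = " *" if vp.v_values[n] < vp.threshold else ""
                lines.append(f"  n={n}: V={vp.v_values[n]:.4f}{mark}")
            lines.append(f"  recommended number of reference genes: "
                         f"{vp.recommended_n}")
        for w in self.warnings:
            lines.append(f"  note: {w}")
        return "\n".join(lines)

    def plot_stability(self, ax=None):
        """Bar chart of per-method stability values, genes in final order."""
        from .plotting import plot_stability_bars
        return plot_stability_bars(self, ax=ax)

    def plot_pairwise_variation(self, ax=None):
        from .plotting import plot_v_profile
        if self.v_profile is None:
            raise ValueError("no pairwise-variation profile (run geNorm)")
        return plot_v_profile(self.v_profile, ax=ax)


class StandardCurve:
    """Dilution-series model: Cq regressed on log10 template amount."""

    def __init__(self, log10_amount, cq, gene: str | None = None) -> None:
        from .standard_curve import DilutionSeries
        self.series = DilutionSeries(np.asarray(log10_amount, float),
                                     np.asarray(cq, float), gene)

    @classmethod
    def from_series(cls, series) -> "StandardCurve":
        obj = cls.__new__(cls)
        obj.series = series
        return obj

    def fit(self) -> "StandardCurveResults":
        from .standard_curve import fit_standard_curve
        return StandardCurveResults(fit_standard_curve(self.series), self.series)


@dataclass
class StandardCurveResults:
    fit_: object
    series: object

    @property
    def slope(self) -> float:
        return self.fit_.slope

    @property
    def intercept(self) -> float:
        return self.fit_.intercept

    @property
    def r_squared(self) -> float:
        return self.fit_.r_squared

    @property
    def efficiency_percent(self) -> float:
        return self.fit_.efficiency_percent

    @property
    def amplification_factor(self) -> float:
        return self.fit_.amplification_factor

    def summary(self) -> str:
        f = self.fit_
        name = f.gene_id or "assay"
        return (
            f"Standard curve [{name}]\n"
            f"  slope      {f.slope:10.4f} cycles / log10 unit\n"
            f"  intercept  {f.intercept:10.4f} cycles\n"
            f"  R^2        {f.r_squared:10.4f}\n"
            f"  E          {f.efficiency_percent:10.2f} %\n"
            f"  A          {f.amplification_factor:10.4f} fold / cycle"
        )
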