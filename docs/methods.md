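# Methods

## Problem setting

Relative quantification by RT-qPCR divides a target gene's signal by that of
one or more reference genes, so the conclusions are only as good as the
references' stability across the samples being compared. `refstab`
implements the four stability algorithms in standard use for validating
candidate reference genes from quantification-cycle (Cq) data, the
geometric-mean rank aggregation used to reconcile them, the pairwise-
variation rule for choosing how many references to use, standard-curve
efficiency estimation, and an RNA-seq pre-screen for nominating candidates.
The reference dataset built into the package comes from a validation study
of 12 candidate genes in the pharaoh ant (*Monomorium pharaonis*) across
seven experimental conditions (developmental series, adult phenotypes,
tissues, and two abiotic stress treatments); the aggregation layer
reproduces that study's published orderings exactly from its printed
per-method ranks.

Throughout, Cq is treated as log-scale expression: one cycle equals one
fold-change at perfect doubling, so additive structure on the Cq scale is
multiplicative on the expression scale.

## Input model and replicate handling

Technical replicates of each (sample, gene) well are collapsed to their
arithmetic mean Cq; no outlier rejection is applied. Valid Cq values lie in
(0, 45] cycles (configurable) — the ceiling sits above the common 40-cycle
protocol so genuine late signals are kept while unit errors are caught.
Missing cells are accepted on input but all stability statistics require
complete cases: samples containing any missing gene are dropped, and the
drop is logged. This is the least surprising completion for the small, dense
matrices typical of validation experiments; imputation would manufacture
stability where there is none.

## The four stability statistics

Let `x_ij` be the Cq of gene *j* in sample *i*, with *k* genes and *n*
samples.

**geNorm.** Cq is first transformed to relative quantities
`Q_ij = A_j^(minCq_j − x_ij)` with `A_j` the per-cycle amplification factor
(2.0 by default; measured factors may be supplied per gene). For a pair
(j, l), `V_jl = SD_i[log2(Q_ij/Q_il)]` (n−1 denominator). A gene's M-value
is the mean `V_jl` over the other surviving genes; the highest-M gene is
removed and M recomputed until two genes remain. The value reported per gene
is its M at the exclusion step; the two survivors share their final pair
variation, which is why every geNorm column of a validation table carries a
duplicated top value with two rank-1 entries. Ranks are competition ranks
over the recorded M values; a tie on the maximal M during exclusion removes
the later gene in input order (deterministic, logged).

**Normalization factors and V-profile.** `NF_n` is the per-sample geometric
mean of Q over the *n* most stable genes (final pair first in input order,
then earlier exclusions in reverse order). `V_{n,n+1} =
SD_i[log2(NF_n/NF_{n+1})]` for n = 2 … k−1; the recommended number of
reference genes is the smallest *n* with V below the threshold (default
0.15). When every V is below threshold the minimal pair is recommended and
the full profile is reported, leaving trend judgements — which are
inherently subjective — to the analyst.

**NormFinder-style variance decomposition.** Sample-centering
`z_ij = x_ij − mean_j(x_ij)` removes loading offsets exactly but couples the
genes: the centered values sum to zero per sample, so raw per-gene variances
`s²_j` are biased. The method-of-moments correction

    σ̂²_j = max(0, (s²_j − m̄/(k−1)) · k/(k−2)),   m̄ = mean_j s²_j

undoes the centering covariance (this is why k ≥ 3 is required), and
ungrouped stability is `√σ̂²_j`. With a group design, per-(gene, group)
deviations `d_gj` (group mean of z minus the gene's cross-group average) are
shrunk empirical-Bayes style by `γ̂²/(γ̂² + σ̂²_gj/n_g)`, where `γ̂²` is the
shared between-group variance component, clamped at zero when the observed
scatter of d is within its sampling noise (the clamp makes zero the best
achievable score, as for all the variance estimates here). Grouped stability
is `mean_g(|d̃_gj| + √(σ̂²_gj/n_g))`. The within-group variance correction is
applied per group, the natural per-group analogue of the ungrouped formula;
`γ̂²` uses the n−1 variance over all (gene, group) deviations. This is a
from-definitions operationalization of the model-based approach — agreement
with any particular historical implementation to the last digit is not
claimed; parameter recovery and the invariance structure are what the test
suite verifies.

**BestKeeper descriptives.** Per gene: arithmetic and geometric mean,
min/max, spread (default: n−1 sample SD about the arithmetic mean;
`mad_geo`, the mean absolute deviation about the geometric mean, is provided
because the original tool's convention is ambiguous — the choice is recorded
in the output), CV%, and the Pearson correlation (with two-sided p-value) of
each gene's Cq with the BestKeeper index, the per-sample geometric mean Cq
over all candidates. Ranking is by SD. Genes with SD above one cycle are
flagged "inconsistent" (the classical heuristic), advisory only. BestKeeper
is deliberately *not* loading-invariant; the tests assert that a per-sample
loading shift strictly inflates every gene's SD.

**Comparative ΔCt.** For every pair, the SD across samples of
`x_ij − x_il`; a gene's stability is the mean over its k−1 pair SDs. With
all amplification factors at 2, each pair SD coincides exactly with the
geNorm pair variation (log2 ratios are Cq differences up to a constant) —
an identity the suite checks to 1e−12 — and ΔCt stability equals the
first-round geNorm M.

## Rank aggregation

Each method's stability values become competition ranks (ties share the
minimum rank; the next rank skips). The comprehensive score is the geometric
mean of the method ranks and genes are ordered ascending in it. Ties are
broken by a chain applied one link at a time: mean rank, then the NormFinder
rank when present, then input order. The chain is implemented on exact
integer keys (rank product, rank sum), so genes with equal products compare
exactly. This rule, with geometric means taken over the raw ranks without
re-ranking between steps, reproduces all seven published condition orderings
in the built-in reference tables, including both printed tie cases — the
strongest available evidence for the aggregation convention; the tie-break
chain beyond the mean rank is inferred from those two cases, not from any
stated rule, and every invocation is logged.

## Standard curves

Cq is regressed on log10 template amount by ordinary least squares
(`scipy.stats.linregress`); R² is the squared Pearson correlation, i.e. the
determination coefficient of the simple regression. Efficiency is
`E = (10^(−1/slope) − 1)·100` and the amplification factor `A = 1 + E/100`;
perfect doubling corresponds to slope −3.321928. The x-axis is strictly
log10 of copy number — natural-log input is not accepted, avoiding silent
unit bugs. A positive slope warns (anti-correlated curve) but still returns
the value; an all-equal design raises.

## Candidate pre-selection from RNA-seq

Given a TPM matrix over developmental stages and a gene→family map of
reference-gene homologs: genes with TPM < 5 in at least 2 stages are
removed; surviving expression is variance-stabilized (default
`log2(tpm+1)`; an Anscombe-flavoured `2√(tpm+3/8)` variant is available);
per-family genes are ranked by SD across stages; and each family's nominee
is its lowest-SD member with TPM > 1000 in at least 8 stages (every
threshold configurable). Families with no qualifying member are reported
empty, with the reason per gene. `log2(tpm+1)` is a pragmatic, monotone
choice that flattens the mean–variance trend at TPM scale; a model-based
VST fitted to count data can order borderline genes slightly differently,
so SD rankings are reproducible only up to the choice of transform.

## Synthetic data

The generator draws `Cq_ijr = B_j + L_i + Δ_{g(i),j} + ε_ij + τ_ijr` with
gene baselines `B_j`, per-sample loading `L_i ~ N(0, loading_sd²)`, optional
per-(group, gene) condition effects Δ in cycles, biological noise
`ε ~ N(0, σ_j²)` and technical noise `τ ~ N(0, tech_sd²)`. Gaussian noise on
the Cq scale is the simplest defensible model because Cq is log-domain:
multiplicative expression noise is additive here. Defaults are a realistic
validation design: 12 genes × 36 samples × 3 technical replicates, baselines
spread 14–33 cycles (matching the Cq range seen across abundant 18S-like to
scarce TATA-like transcripts), loading SD 1 cycle, σ spread 0.05–1.2 cycles,
technical SD 0.1 cycles. Among zero-Δ genes the true stability order is
ascending σ, giving every method a recoverable ground truth. What the model
does **not** emulate: efficiency drift between runs, amplification
inhibition, plate effects beyond a scalar offset, non-Gaussian dropout near
the detection limit, or correlated co-regulation between candidate genes —
so passing recovery tests demonstrates correctness of the statistics under
the stated model, not robustness to those real-world pathologies. TPM
fixtures are log-normal with per-family dispersion grading and deliberate
filter violations, so the selection rules can be checked against
construction truth.

## Numerical choices

- All SDs use the n−1 denominator (sample statistics).
- Pairwise SD matrices are computed from the covariance matrix via
  `Var(a−b) = Var(a) + Var(b) − 2Cov(a,b)`, with tiny negative values
  floored at zero before the square root; the loop-based oracles in the
  test suite confirm agreement to better than 1e−10.
- Variance estimates clamp at zero rather than going negative.
- Degenerate inputs fail loudly: fewer than 3 genes (geNorm, NormFinder),
  fewer than 3 samples, groups smaller than 3, zero-range dilution designs,
  amplification factors ≤ 1.
- Simulation problem sizes used by the validation script (100 replicate
  experiments per scenario; n = 200 samples for variance recovery) were
  chosen so that Monte-Carlo error is an order of magnitude below the
  tolerances being checked.

## Known limitations

- The NormFinder operationalization is method-of-moments with EB shrinkage;
  small-sample grouped estimates of γ² are noisy and the clamp produces a
  point mass at zero.
- BestKeeper's ranking convention (SD vs index correlation) varies between
  practitioners; both statistics are reported, SD is ranked.
- The V < 0.15 rule is a convention, not a test; the package reports the
  full profile and never automates trend judgements.
- Published-table reconstruction validates the aggregation layer only; the
  per-method stability values of the reference study are not recomputable
  because its raw Cq data is not published.
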