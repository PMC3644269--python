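# Methods

## Scoring model

One observation is a scored carcinoma nucleus with non-negative integer
HER2 and CEP17 signal counts and a cluster flag. A *cluster* is a nucleus
with more than 16 HER2 signals or coalesced signals that cannot be counted
individually; for all ratio arithmetic a cluster cell contributes exactly 16
HER2 signals. A raw count above 16 without the flag meets the cluster
definition and is capped the same way, with a warning, so the cap is an
invariant of everything downstream (the cohort mean HER2 can never exceed
16).

The tumour-level ratio is the **ratio of means** — total effective (capped)
HER2 signals over total CEP17 signals — not the mean of per-cell ratios.
This is the standard dual-probe convention and is well defined even when
individual cells have zero CEP17 signals. Per-cell ratios are needed only
for the heterogeneity statistic (fraction of cells with effective-HER2/CEP17
\> 2.2); cells with CEP17 = 0 have no per-cell ratio and are excluded from
that denominator while remaining in both means. Each exclusion is warned
about, since a high rate of CEP17-null cells would itself be a quality flag.

### Classification boundaries

All cutoffs are configuration fields (`ScoringThresholds`), defaulting to
the conventional values; the boundary conventions are:

| call | rule | boundary handling |
|---|---|---|
| three-way (ASCO/CAP-era) | non-amplified / equivocal / amplified | equivocal band **closed**: ratio ∈ [1.8, 2.2]; amplified strictly > 2.2 |
| alternative ratio cutoff | amplified | ratio **≥ 2.0** (inclusive) |
| mean-copies definition | amplified | mean HER2 **> 6.0** (strict) |
| heterogeneity | present | fraction strictly **between** 5% and 50% |
| cluster positivity | present | cluster cells **≥ 1%** of scored cells |
| polysomy 17 | present | mean CEP17 **> 3.00** (strict) |

No rounding is applied before classification; calls use full floating
precision. Published reports round ratios to two decimals without stating a
rounding rule, so classifying the unrounded value is the only convention
that never manufactures a boundary artefact.

### Equivocal reflex

The initial read is exactly 60 cells. If (and only if) its ratio falls in
the closed equivocal band, a further 40 cells are required and the final
score is recomputed over the pooled 100 cells; otherwise the 60-cell score
is final, bit-identical to scoring those 60 cells directly. Supplying too
few cells for a triggered reflex is an error, not a silent fallback. The
batch scorer (`score_table`) treats the first 60 cells in `cell_id` order as
the initial read when a sample carries ≥100 cells; samples with any other
cell count are scored whole, without reflex, with a warning.

An optional per-cell `area` label represents the protocol requirement that
cells come from at least three tumour areas; fewer distinct labels produce a
warning rather than an error, because toy and synthetic inputs legitimately
omit areas.

## Agreement statistics

Categorical agreement between two methods over a joint K×K table uses the
concordance rate (trace/N) and Cohen's κ = (p₀ − pₑ)/(1 − pₑ) with the
textbook marginal-product chance term. The degenerate table with all mass
in one diagonal cell has pₑ = p₀ = 1 and is defined as κ = 1. Association
is tested with the two-sided Fisher exact test for 2×2 tables (the
point-probability convention: the p-value sums all tables with probability
not exceeding the observed one — conventions differ between packages, so
this one is stated) and the Pearson chi-square test for larger tables;
which test ran is recorded in the result. Rows and columns that are empty
in both margins are dropped jointly first; a table that collapses below 2×2
has no testable association and reports NaN.

Continuous agreement treats method A (the reference, e.g. manual scoring)
as x and method B as y: Pearson's r, ordinary least squares of y on x
(slope, intercept, R² = r²), and a two-sided paired Student's t test on the
per-sample differences. Identical vectors give t = 0, p = 1; a constant
non-zero difference has no variance to test against and is an error. The
standard fits are delegated to scipy.stats; stored p-values are never
formatted — "<0.001" appears only in the rendered TSV report.

### Joint-table reconstruction

Validation studies often print only per-method positive/negative totals
plus a narrative like "four cases positive by A tested negative by B". With
marginals (pos_a, neg_a), (pos_b, neg_b) and a one-directional discordance
constraint, marginal conservation forces a unique 2×2 table — e.g.
manual 50/50 vs automated 46/54 with all discordance manual-positive forces
[[46, 4], [0, 50]], giving κ = 0.920 and concordance 96%. Without a
direction the integer tables consistent with the marginals form a family;
the reconstruction then succeeds only if that family has size one, and
otherwise reports the family size in the error. κ for the three published
amplification definitions is reproduced on **binary** (amplified vs
not-amplified, equivocal pooled with non-amplified) tables; a 3×3
cross-tabulation consistent with the printed marginals and only four
discordances does not exist, so the three-class κ is offered as a report
option but has no published reference value.

## Synthetic cohort generator

The generator emulates a paired validation cohort: each virtual tumour gets
a state — amplified, equivocal, heterogeneous, or non-amplified — plus
independent polysomy, and both methods score cells drawn from the same
underlying composition.

* **Counts.** Per-cell counts are gamma-mixed Poisson (negative binomial)
  draws around the tumour's mean: cell intensity λ ~ Gamma(shape *k*,
  mean μ), count ~ Poisson(λ). `cell_dispersion` is *k*: large values
  approach the Poisson limit; any value ≤ 0 selects the degenerate
  deterministic limit (count = rounded mean), which makes exact-recovery
  tests possible. Real signal counts are over-dispersed relative to
  Poisson, hence the default *k* = 8.
* **Method bias.** Method B's means are method A's multiplied by
  `method_b_her2_factor` (default 0.92) and `method_b_cep17_factor`
  (default 1.11) — the direction and magnitude reported for automated vs
  manual scoring (cohort mean HER2 5.87 vs 6.41 ≈ 0.92; CEP17 2.24 vs
  2.02 ≈ 1.11). Multiplicative bias on shared per-tumour means is the
  simplest structure that produces both a systematic ratio shift (≈ −17%)
  and high inter-method correlation simultaneously; its characteristic
  signature — discordant amplification calls concentrating in tumours with
  true ratios near the 2.2 cutoff — is asserted by the tests.
* **States.** Amplified tumours draw cells at `her2_mean_amp` (default 10
  signals/cell, consistent with an amplified cohort mean HER2 of ~6.4 over
  a mixed cohort), non-amplified at 2.0. Equivocal tumours target a ratio
  uniform in [1.8, 2.2] (exercising the reflex path); the per-tumour latent
  intensity is not applied to them, since it would move them out of the
  band that defines the state. Heterogeneous tumours mix amplified and
  non-amplified cells at a fraction drawn uniformly in [0.08, 0.45] —
  strictly inside the (5%, 50%) heterogeneity band, with margin so finite
  sampling does not leak across the defining boundary. Cluster cells (among
  amplified cells, probability `cluster_prob_given_amplified`) are emitted
  with their uncapped counts >16 and the flag set: capping is deliberately
  left to the scorer so the cap logic is exercised end to end.
* **Cohort composition defaults** (fractions 0.44 amplified / 0.06
  equivocal / 0.17 heterogeneous / 0.04 polysomy) follow the manual-FISH
  prevalences of a published 100-biopsy validation cohort; the per-tumour
  latent intensity (lognormal, σ = 0.25) is a free parameter because
  published cohort summaries report standard errors of means, from which
  between-tumour variance of true means is not recoverable.
* Every tumour emits `cells_per_tumour` (default 60) initial cells plus a
  40-cell reflex reserve, so equivocal tumours can always complete the
  reflex; generation is fully reproducible from `seed`.

`paper_like_cohort(seed)` is the 100-tumour preset. Its calibration is
deliberately loose — scored amplified fraction under method A in
[0.40, 0.60], cohort mean HER2 in [5.0, 8.0] — because the generator
emulates the *structure* of such a cohort, not any particular slide set.

What passing tests on synthetic data do **not** show: the generator has no
tissue areas, no fixation or hybridisation artefacts, no reader fatigue or
inter-observer variability, no spatial correlation between neighbouring
cells, and cell-level noise that is exactly negative binomial. Agreement
statistics measured on it validate the arithmetic and the qualitative bias
mechanics, not the performance of any real assay.

## Pipeline and reporting

`run_comparison` scores both methods' cell tables, inner-joins on
`sample_id` (mismatched samples are an error by default — silent cohort
shrinkage is worse than a loud failure; `allow_partial=True` downgrades it
to a warning), and emits categorical blocks for the binary and three-class
amplification calls, both alternative definitions, heterogeneity, cluster
positivity and polysomy, plus continuous blocks for mean HER2, mean CEP17,
the ratio and the >2.2 cell fraction. An optional IHC label table (0+/1+/
2+/3+ scores consumed as given labels only) adds per-stratum concordance
rates; stratum κ is reported only when the stratum occupies at least two
categories, because κ is undefined in a single-category stratum. Reports
(TSV + JSON) use stable key ordering and fixed float formatting, so
regeneration from identical inputs is byte-identical; percentages are
rendered to one decimal from full-precision internals, and "<0.001"
formatting exists only in the rendered TSV.

## Problem sizes and numerical choices

The test suite and acceptance checks use cohorts of 100–300 tumours at 100
cells per tumour and oracle comparisons on 1,000 random small instances per
statistic, sizes at which every quantity of interest is already stable;
real-valued comparisons against independent oracles use absolute tolerances
of 1e-9 (1e-12 for pure tallies). Ties in the Fisher two-sided sum use a
1 + 1e-9 relative guard, matching scipy's convention. Joint tables with
zero total are rejected as input errors rather than returning NaN.

## Known limitations

* The three-class κ option has no published reference to validate against
  (see above); only binary κ values are reproduced.
* The reconstruction of published joint tables assumes the narrated
  discordance direction is exhaustive; a study with bidirectional
  discordance hidden in its totals would need `discordance="unknown"` and
  may be non-identifiable (the error then reports the family size).
* Stratified reporting covers concordance rates and κ only; stratified
  continuous regression is intentionally out of scope.
* The generator draws both methods' cells from the same composition with
  independent counting noise; it cannot represent area-selection effects,
  where the two methods score genuinely different tumour regions.
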