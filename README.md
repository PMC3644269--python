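# her2fish

Scoring and inter-method concordance analysis for dual-probe **HER2/CEP17
FISH** testing of breast carcinoma.

Positive HER2 status — the criterion for trastuzumab eligibility — is
established in situ by counting fluorescent *HER2* and chromosome-17
centromere (CEP17) probe signals in carcinoma nuclei. When a laboratory
introduces a new assay (for example an automated FISH platform alongside
manual scoring), it must demonstrate agreement with the established method
over a validation cohort. `her2fish` provides the two halves of that
workflow as a reusable library plus a small CLI:

1. **Cell-level scoring.** From per-nucleus signal counts it computes, per
   tumour and method, the mean HER2 and CEP17 copy numbers, the ratio

   *R* = mean(HER2, cluster-capped at 16) / mean(CEP17),

   the fraction of cells with per-cell ratio > 2.2, and the categorical
   calls: the ASCO/CAP three-way classification (non-amplified *R* < 1.8,
   equivocal 1.8 ≤ *R* ≤ 2.2, amplified *R* > 2.2) with the equivocal
   **reflex rule** (an equivocal 60-cell ratio triggers scoring of 40 more
   cells; the final ratio uses all 100), the alternative cutoffs *R* ≥ 2.0
   and mean HER2 > 6.0, HER2 genetic heterogeneity (>5% and <50% of cells
   with per-cell ratio > 2.2), HER2-cluster positivity (clusters in ≥1% of
   cells; a cluster is >16 signals or uncountable coalesced signals), and
   chromosome-17 polysomy (mean CEP17 > 3.00).
2. **Concordance statistics.** Between two methods over a cohort: the
   concordance rate, Cohen's κ = (p₀ − pₑ)/(1 − pₑ), two-sided Fisher exact
   or chi-square association tests, Pearson *r* with ordinary least squares
   (method B on method A), paired Student's *t* tests, and reconstruction of
   a 2×2 joint table from published marginals plus a one-directional
   discordance constraint — the situation a reader faces when a study
   prints only per-method totals and narrates the discordant cases.

A **synthetic paired-cohort generator** produces ground-truthed cell tables
(amplified, equivocal, heterogeneous, polysomic and cluster-bearing tumours,
with a configurable multiplicative inter-method bias) so the entire pipeline
is testable without any slide data.

## Worked example

```python
import her2fish as hf

truth, cells_a, cells_b = hf.paper_like_cohort(seed=1)   # 100 virtual tumours
report = hf.run_comparison(cells_a, cells_b)

c = report["categorical"]["asco_binary"]
print(f"binary amplification: concordance {c['concordance_rate']:.2f}, kappa {c['kappa']:.3f}")
r = report["continuous"]["mean_her2"]
print(f"HER2 copy number: r {r['pearson_r']:.3f}, slope {r['slope']:.3f}")
```

prints (seed 1):

```
binary amplification: concordance 0.92, kappa 0.841
HER2 copy number: r 0.987, slope 0.953
```

The two methods disagree on 8 of 100 tumours — the generator's default bias
(method B records ~8% fewer HER2 and ~11% more CEP17 signals, so ratios
shrink by ~17%) flips tumours whose true ratio sits near the 2.2 cutoff —
while the continuous HER2 copy numbers stay tightly correlated, the pattern
this kind of method-comparison study reports.

The same pipeline runs from the shell:

```sh
her2fish simulate --seed 1 --out-dir scratch/sim
her2fish score scratch/sim/cells_A.tsv --out scratch/scores_A.tsv
her2fish compare scratch/sim/cells_A.tsv scratch/sim/cells_B.tsv --out-dir scratch/report
her2fish reproduce-paper-tables
```

`reproduce-paper-tables` rebuilds the published manual-vs-automated 2×2
tables from their printed marginals (e.g. 50 vs 46 of 100 amplified with all
discordance manual-positive) and recomputes the agreement statistics: the
forced tables give κ = 0.920, 0.920 and 0.939 with concordance 96%, 96% and
97% for the three amplification definitions, matching the published values.

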