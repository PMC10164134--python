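# wntgct

Integrated genomic analysis of WNT-pathway alterations in germ cell tumors
(GCTs) — neoplasms of the testis, ovary and extragonadal sites spanning
pre-pubertal (type I) and post-pubertal (type II) disease. The package
re-implements, as a tested and reusable pipeline, the analysis chain that
links somatic mutation, copy number, promoter methylation and clinical
outcome to canonical WNT/β-catenin signaling:

1. **Somatic variant filtering** of tumor–normal candidate calls by a
   five-rule cascade: tumor VAF ≥ 10% with 0% VAF in the matched normal;
   alt reads on both strands and > 6 alt reads total; mapping quality ≥ 30
   and base quality ≥ 15; depth ≥ 10 in both tissues; population allele
   frequency ≤ 0.01. Mutation rates per Mb, protein-altering
   classification, mutual-exclusivity permutation tests and
   expression-by-mutation comparisons sit on top.
2. **Direction-aware WNT copy-number burden.** Per-gene CN states are called
   from segmented profiles (length-weighted mean log2 ratio, gain ≥ +0.3,
   loss ≤ −0.3; *focal* when the supporting run of altered segments spans
   < 50% of the chromosome arm). The burden score of a sample is

   *score = #{activator genes with focal gain} + #{repressor genes with focal loss}*,

   and samples are stratified as **none** (score 0), **CN-poor** (1..t) or
   **CN-rich** (> t), t = 5 by default with sensitivity analysis at
   t ∈ {3, 7, 9}. A genome-wide altered-gene count control checks that the
   stratification is not a proxy for global instability.
3. **Reciprocal promoter methylation.** After probe filtering (missing
   values, cross-hybridizing probes, repeat regions, sex chromosomes),
   promoter-window β values are summarized per gene and WNT activators are
   tested against repressors: activators are expected hypomethylated and
   repressors hypermethylated — the epigenetic configuration favoring
   pathway activity.
4. **Arm-level LOH by age.** An arm is called LOH when LOH-flagged segments
   cover ≥ 70% of it; per-sample arm-LOH counts are compared between
   patients under and over 6 years of age.
5. **Outcome statistics.** Relapse proportions by burden stratum (t-test as
   primary, Fisher exact alongside), Kaplan–Meier curves, two-group
   log-rank tests, and median-dichotomized Cox proportional-hazards
   associations (HR, Wald 95% CI) for single genes.
6. **Synthetic cohort generator.** All real cohorts of this kind are
   controlled-access, so the package ships a fully deterministic simulator
   that emits every input format (clinical TSV, per-pair VCFs, SEG, BED
   annotations, β and expression matrices) with planted ground truth:
   stratum-dependent relapse probabilities (0 / 0.07 / 0.30) and survival
   hazards (CN-rich 3×), reciprocal methylation means (0.2 vs 0.7),
   age-dependent arm-LOH burdens (Poisson 1 vs 12) and variants violating
   every subset of the filter rules.

## Worked example

```bash
wntgct run-all --out-dir out --seed 1 --n-samples 114
```

simulates a 114-patient cohort, re-reads it from disk, and runs every stage.
Key numbers from `out/results/summary.json` for this seed:

| quantity | value | meaning |
|---|---|---|
| `mean_nonsilent_per_mb` | 0.239 | mean non-silent somatic mutation rate (planted 0.23/Mb) |
| `relapse_by_stratum` | 0.0 / 0.049 / 0.226 | relapse proportion in none / CN-poor / CN-rich |
| `relapse_rich_vs_none.fisher_p` | 0.0018 | CN-rich vs no-alteration relapse contrast |
| `logrank_rich_vs_none.p_value` | 1.4e-4 | survival contrast, CN-rich vs no-alteration |
| `reciprocal_methylation` | 0.198 vs 0.707, p = 3.1e-4 | activator vs repressor mean promoter β |
| `loh_by_age` | median 1 vs 12, p ≈ 1e-20 | arm-LOH counts, younger vs older than 6 y |
| `instability_control.p_value` | 0.79 | CN-rich vs CN-poor genome-wide altered-gene counts |

The no-alteration group shows no relapses, the CN-poor group a small
increase and the CN-rich group a striking one, with a significantly worse
survival curve — while the instability control stays non-significant,
indicating the burden score is not merely tracking global copy-number chaos.

Library use mirrors the CLI:

```python
from wntgct import (SimulationConfig, generate_cohort, load_cohort,
                    assign_gene_cn, wnt_burden_score)

truth = generate_cohort(SimulationConfig(n_samples=50, seed=7), "cohort/")
cohort = load_cohort("cohort/")
states = assign_gene_cn(cohort.cn_layer["S0001"], cohort.genes,
                        arms=cohort.arms)
print(wnt_burden_score(states, cohort.geneset))
```

## Layout

```
src/wntgct/
  annotations.py          gene/arm annotations, promoter windows
  cohort_io.py            clinical TSV, VCF, SEG, BED, gene-set I/O; cohort assembly
  somatic_filter.py       filter cascade, mutation rates, co-occurrence tests
  cn_burden.py            gene CN states, burden score, strata, arm-level LOH
  methylation_expression.py  probe filter, promoter β, reciprocal pattern, markers
  survival_outcomes.py    KM, log-rank, relapse tables, median-dichotomized Cox
  synthetic_cohort.py     deterministic multi-omic simulator with ground truth
  pipeline.py, cli.py     orchestration and the `wntgct` command
docs/methods.md           model assumptions, parameter defaults, limitations
```
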