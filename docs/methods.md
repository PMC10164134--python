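# Methods

This note documents the models and conventions behind `wntgct`: what each
stage assumes, which parameters matter and why their defaults were chosen,
what the synthetic generator does and does not emulate, and the numerical
decisions made where the design was genuinely open.

## Coordinates and formats

Internally every interval is 0-based half-open. VCF positions stay 1-based
at the file boundary (pysam handles the conversion); SEG input defaults to
the 1-based closed dialect and is shifted at ingest (`seg_dialect`
configurable). Gene and promoter annotations travel as paired BED6 files.
Chromosome arms come from a packaged hg19 cytoband-derived table using
approximate centromere midpoints; arm boundaries only enter the analysis
through arm lengths (focality fractions, LOH coverage), where megabase-level
precision is immaterial.

## Somatic filter cascade

Five independent rules, each configurable (`FilterThresholds`):

| rule | condition to pass | default |
|---|---|---|
| R1_vaf | tumor VAF ≥ `tumor_vaf_min` and normal alt reads ≤ `normal_alt_max` | 0.10, 0 |
| R2_strand_reads | ≥ 1 alt read per strand and alt total > `min_alt_total` | strict > 6 |
| R3_quality | mapping quality ≥ 30, base quality ≥ 15 | |
| R4_depth | tumor and normal depth ≥ 10 | |
| R5_popaf | population AF ≤ 0.01, absent = pass | |

Open readings resolved here: "VAF in normal is 0%" is taken literally as
zero alt reads in the normal (`normal_alt_max=0`; a relaxation is available
but off). "Supported by both strand and > 6 reads" is read as at least one
alt read on each strand *and* more than six alt reads in total (the
alternative reading — more than six per strand — would make the both-strand
clause redundant). A missing population-AF annotation passes R5, because
the rule excludes *catalogued* polymorphisms. Every failing variant reports
the complete set of violated rules, which makes the cascade
order-independent and lets the report populate a VCF FILTER column.

VAFs are computed as alt depth over total allele depth when the caller does
not provide them. Records lacking any required annotation are flagged
unscorable, counted, and excluded before filtering rather than silently
passed or failed.

Mutation rates divide non-silent (protein-altering) survivor counts by the
exome target size, `target_mb` (default 38 Mb, a conventional coding-exome
footprint; it is a config input because rates scale inversely with it).
Group summaries use linear-interpolation percentiles (5/25/50/75/95), the
boxplot convention.

The mutual-exclusivity permutation test is an extension beyond a purely
descriptive claim: each gene's mutation column is permuted independently
(`numpy.random.default_rng(seed)`, genes permuted in their given order
within each replicate), and the one-sided p-value
`(1 + #{perm ≤ obs}) / (n_perm + 1)` tests for fewer co-occurrences than
expected. Expression-by-mutation-status comparisons use the two-sided
Mann–Whitney U test, exact when the data are tie-free and the group-size
product is small enough to enumerate (≤ 5000), asymptotic with tie
correction otherwise.

## Gene copy-number states and the WNT burden

A gene's summary log2 ratio is the overlap-length-weighted mean of the
segments covering it (a max-magnitude alternative is available via
`aggregation`). Thresholds ±0.3 approximate a single-copy change on the
array log2 scale; segmentation itself is assumed done upstream. Calls are
*focal* when the contiguous run of same-direction altered segments around
the gene spans less than half the arm holding the gene midpoint — the
broad/focal arm-fraction convention. Defining focality on the contiguous
run (rather than a single segment) makes the call invariant to splitting a
segment into abutting halves. Genes with no overlapping segment are neutral
with an `uncovered` flag.

The burden score counts each WNT-set gene at most once and only in the
signaling-increasing direction: activator gains and repressor losses.
Broad alterations are excluded by default (`focal_only=True`) since the
stratification is defined on focal events; a toggle exists. Stratification:
score 0 → none, 1..t → CN-poor, > t → CN-rich, with t = 5 and a sensitivity
sweep over {3, 5, 7, 9}. Gene-level (not event-level) counting was chosen:
a gene hit by two overlapping events still contributes one.

The packaged activator/repressor list (8 activators: CTNNB1, FZD1, FZD7,
LRP5, LRP6, WNT5B, CCND2, TCF7L2; 7 repressors: APC, BTRC, CHD8, FAT1–4)
is a reconstruction from genes recurrently implicated in GCT WNT biology,
not an exhaustive pathway annotation; any two-column TSV can replace it.

The instability control compares per-sample counts of gained and lost genes
over *all* genes between CN-rich and CN-poor samples (Welch t-test; the
degenerate identical-constant case is defined as p = 1). A non-significant
control indicates the burden difference is not driven by genome-wide
instability.

## Arm-level LOH

An arm is LOH when LOH-flagged segments cover at least
`loh_min_arm_fraction` (default 0.7, inclusive) of it; arms with no segment
coverage are called negative with an `uncovered` flag. The age comparison
is a two-sided Mann–Whitney test on per-sample arm-LOH counts with the
younger group defined as age < 6 years (an age of exactly 6 goes to the
older group; the boundary is configurable). Total ties across both groups
are defined as p = 1.

## Methylation and expression

Probe filtering removes probes with any missing β, cross-hybridizing or
repeat-region flags, or sex-chromosome location; it is idempotent and
reports per-criterion counts. Array normalization is out of scope: the
pipeline accepts already-normalized β values.

Promoters are TSS−1500..TSS+500, strand-aware — a conventional 450k-style
window, configurable, since no single definition is canonical. Per-gene
promoter β is the unweighted mean of window probes (genes without probes
are omitted, logged). The reciprocal pattern test summarizes each gene by
its median β across samples, then compares activator and repressor genes
two-sided by rank; it is exactly symmetric under swapping the role labels.

Marker expression comparisons (defaults: CTNNB1, TCF7, TCF7L2, FZD7, MYC,
CCND1 — TCF7/TCF7L2 being the current symbols for the factors historically
called TCF1/TCF4) report group means ± SEM and Welch t-tests against the
PGC and normal-testis reference groups. Welch was chosen wherever a
"Student's t" is called for without a variance assumption; a pooled-variance
switch exists.

## Outcome statistics

Kaplan–Meier estimation, the two-group log-rank test and the Cox model are
delegated to lifelines; tied event times contribute jointly (log-rank) and
Cox uses the Efron approximation. Relapse-by-stratum reports a two-sided
t-test on the 0/1 relapse indicators as the primary p-value — an unusual
choice for proportions, kept because it is the convention this pipeline
mirrors — with Fisher's exact test reported alongside as the natural exact
companion. Expression is dichotomized at the within-cohort median with ties
going to the under-expressed group (strictly-above rule, configurable).
No multiple-testing correction is applied by default; raw p-values are
reported (a Benjamini–Hochberg helper is a candidate extension). Samples
with missing outcome fields are excluded from outcome stages only, never
from genomic stages.

## Synthetic cohort generator

The generator's purpose is statistical structure, not biological realism:
it plants exactly the effects the analyses are designed to detect, at
realistic cohort scale, and emits the same text formats the I/O layer
reads, so ground truth can be re-derived from the files alone.

Reference conditions (all `SimulationConfig` fields):

* cohort: n = 114; 45% type I (teratoma/YST histologies, ages 0–5) and 55%
  type II (five histologies, ages 12–24); site and sex consistent.
* strata: equal thirds none / CN-poor / CN-rich (each guaranteed
  non-empty); planted direction-aware focal WNT alterations: 1–5 genes
  (CN-poor) or 6–10 (CN-rich) at log2 ±0.8 over the gene ± 0.5 Mb.
* background instability: per-sample altered non-WNT gene counts are
  gamma-Poisson (mean 100, shape 3), equal across strata. The
  overdispersion matters: across-tumor variation in instability is large in
  real data, and it keeps the planted few-gene WNT delta statistically
  invisible in the genome-wide count control, as it would be at true genome
  scale.
* variants: non-silent rate 0.23/Mb over a 38 Mb target plus silent calls
  (Poisson 1.5); rule-violating decoys at Poisson(4) per sample with random
  violation subsets, every single rule guaranteed covered; KIT/KRAS/NRAS
  planted mutually exclusively (8%/8%/4% of samples); FAT2/FAT3
  protein-altering mutations in 15% of samples with a +1.5 log2 CTNNB1
  expression shift.
* outcomes: relapse probabilities 0.00 / 0.07 / 0.30 by stratum; survival
  exponential with baseline hazard 0.012/month (median ≈ 58 months) and
  per-stratum multipliers (1, 1.3, 3); independent exponential censoring at
  0.010/month (≈ 45% censoring in the baseline group); 2% of relapse flags
  set missing to exercise missing-data paths.
* methylation: promoter β per gene-role from beta distributions with means
  0.2 (activators) / 0.7 (repressors) / 0.5 (background), sd 0.1, three
  probes per promoter; decoy probes exercising every exclusion criterion.
* LOH: arm counts Poisson(12) for patients ≥ 6 years, Poisson(1) below,
  each planted arm covered 90% by LOH-flagged segments.
* expression: log2-scale values, N(5, 1), WNT markers shifted +2 (type I)
  and +1 (type II) against PGC and testis reference columns.

The synthetic genome reuses the packaged autosome arm table; genes (15 WNT,
12 named drivers, 400 background) are laid out deterministically on a 5 Mb
grid so that focal events never collide. One master seed spawns per-layer
child generators (`numpy.random.SeedSequence`) in a fixed order, making
every layer individually reproducible and the full output byte-identical
across runs.

What the generator does **not** emulate: mutational signatures, realistic
allele-specific copy number, probe-level methylation covariance, batch
effects, correlated censoring, or the joint dependence of relapse and death
on treatment. Passing tests therefore demonstrate that the pipeline's
statistics recover the effects they target under clean planted conditions —
not that those effects would survive the artifacts of real cohorts.

## Problem sizes used in checks

Replicate studies use the study's own scales: n = 114 for outcome recovery
(200 replicates, with 1000 null replicates for calibration), n = 108 for
Cox recovery (planted HR 2.5, 200 replicates), n = 60 per arm for log-rank
power (500 replicates), 8 genes per role × 40 samples for the reciprocal
methylation study (200 replicates), and 20 + 20 samples for the arm-LOH age
contrast (200 replicates). Null rejection rates are required to fall in
[0.03, 0.07] at α = 0.05; power and detection rates must meet 0.80–0.95
depending on the stage.

## Known limitations

* The WNT gene list is a curated reconstruction; burden scores depend on it
  and should be re-derived for any externally supplied list.
* Focality uses a single arm-fraction convention; amplicon-level focality
  (e.g., q-value-weighted peak calling) is out of scope, as is segmentation.
* The Cox stage supports a single binary covariate only (median
  dichotomization); multivariable models, competing risks and interval
  censoring are out of scope.
* Arm coordinates are approximate (centromere midpoints), which is adequate
  for fraction-based calls but not for breakpoint-precise annotation.
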