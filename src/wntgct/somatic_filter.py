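"""Post-calling somatic variant filter cascade and mutation summaries.

The cascade applies five independent rules to tumor-normal candidate calls:

* ``R1_vaf`` — tumor VAF >= 10% and no alt evidence in the matched normal;
* ``R2_strand_reads`` — alt reads on both strands and >6 alt reads in total;
* ``R3_quality`` — mapping quality >= 30 and base quality >= 15;
* ``R4_depth`` — tumor and normal depth >= 10 at the locus;
* ``R5_popaf`` — population alternate allele frequency <= 0.01 (a variant
  absent from population databases passes).

Every failing variant carries the full list of violated rules, so the report
is order-independent and suitable for writing back into a VCF FILTER column.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import FilterThresholds

logger = logging.getLogger(__name__)

RULES = ("R1_vaf", "R2_strand_reads", "R3_quality", "R4_depth", "R5_popaf")

CONSEQUENCES = (
    "missense", "stop_gain", "splice_site", "frameshift", "inframe_indel",
    "silent", "other",
)
PROTEIN_ALTERING = frozenset(
    {"missense", "stop_gain", "splice_site", "frameshift", "inframe_indel"}
)
NON_SILENT = PROTEIN_ALTERING  # non-silent == protein-altering consequence classes


@dataclass(frozen=True)
class VariantCall:
    """A candidate somatic call with the tumor/normal evidence the filter needs."""

    sample_id: str
    chrom: str
    pos: int  # 1-based, as in the VCF
    ref: str
    alt: str
    tumor_vaf: float
    normal_vaf: float
    tumor_depth: int
    normal_depth: int
    alt_fwd: int
    alt_rev: int
    mapping_quality: float
    base_quality: float
    pop_af: Optional[float]
    consequence: str
    gene: str
    normal_alt: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tumor_vaf <= 1.0 and 0.0 <= self.normal_vaf <= 1.0):
            raise ValueError(f"{self.key}: VAF outside [0,1]")
        if self.alt_fwd + self.alt_rev > self.tumor_depth:
            raise ValueError(f"{self.key}: alt reads exceed tumor depth")
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise ValueError(f"{self.key}: pop_af outside [0,1]")

    @property
    def key(self) -> str:
        return f"{self.sample_id}:{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class FilterReport:
    """Per-variant rule outcomes plus per-sample survivor counts by consequence."""

    calls: list[VariantCall]
    failed_rules: list[tuple[str, ...]]
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.failed_rules):
            raise ValueError("calls and failed_rules length mismatch")

    @property
    def passing(self) -> list[VariantCall]:
        return [c for c, f in zip(self.calls, self.failed_rules) if not f]

    def passes(self, i: int) -> bool:
        return not self.failed_rules[i]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c, f in zip(self.calls, self.failed_rules):
            rows.append({
                "sample_id": c.sample_id, "chrom": c.chrom, "pos": c.pos,
                "ref": c.ref, "alt": c.alt, "gene": c.gene,
                "consequence": c.consequence, "tumor_vaf": c.tumor_vaf,
                "pass": not f, "failed_rules": ";".join(f) if f else "PASS",
            })
        return pd.DataFrame(rows)

    def survivor_counts(self) -> pd.DataFrame:
        """Per-sample counts of passing variants by consequence class."""
        df = self.to_frame()
        surv = df[df["pass"]]
        if surv.empty:
            return pd.DataFrame(columns=["sample_id", "consequence", "n"])
        out = (surv.groupby(["sample_id", "consequence"]).size()
               .rename("n").reset_index())
        return out


def failed_rules(call: VariantCall, th: FilterThresholds) -> tuple[str, ...]:
    """All rules the call violates (empty tuple = pass)."""
    failed: list[str] = []
    if call.tumor_vaf < th.tumor_vaf_min or call.normal_alt > th.normal_alt_max:
        failed.append("R1_vaf")
    alt_total = call.alt_fwd + call.alt_rev
    if (call.alt_fwd < th.min_alt_per_strand or call.alt_rev < th.min_alt_per_strand
            or alt_total <= th.min_alt_total):
        failed.append("R2_strand_reads")
    if call.mapping_quality < th.mapq_min or call.base_quality < th.baseq_min:
        failed.append("R3_quality")
    if call.tumor_depth < th.min_depth or call.normal_depth < th.min_depth:
        failed.append("R4_depth")
    if call.pop_af is not None and call.pop_af > th.popaf_max:
        failed.append("R5_popaf")
    return tuple(failed)


def filter_somatic(calls: Sequence[VariantCall],
                   thresholds: FilterThresholds | None = None,
                   popaf_max: float | None = None) -> FilterReport:
    """Apply the five-rule somatic filter cascade to scorable calls."""
    th = thresholds or FilterThresholds()
    if popaf_max is not None:
        th = replace(th, popaf_max=popaf_max)
    return FilterReport(list(calls), [failed_rules(c, th) for c in calls], th)


def is_protein_altering(consequence: str) -> bool:
    """Whether a consequence class is predicted to alter the protein product."""
    if consequence not in CONSEQUENCES:
        raise ValueError(f"unknown consequence label {consequence!r}; "
                         f"expected one of {CONSEQUENCES}")
    return consequence in PROTEIN_ALTERING


def mutation_rate_per_mb(n_nonsilent: int, target_mb: float) -> float:
    """Non-silent mutations per megabase of sequenced target."""
    if target_mb <= 0:
        raise ValueError(f"target_mb must be positive, got {target_mb}")
    if n_nonsilent < 0:
        raise ValueError("mutation count cannot be negative")
    return n_nonsilent / target_mb


def rate_summary_by_group(counts: pd.DataFrame, target_mb: float,
                          group_col: str = "histology",
                          count_col: str = "n_nonsilent") -> pd.DataFrame:
    """Boxplot-style per-group summary of mutation rates.

    For each group: median, 25th/75th percentiles (box) and 5th/95th
    percentiles (whiskers) of per-sample mutations/Mb, using linear
    percentile interpolation.
    """
    if target_mb <= 0:
        raise ValueError(f"target_mb must be positive, got {target_mb}")
    df = counts.assign(rate=counts[count_col] / target_mb)

    def _summ(g: pd.Series) -> pd.Series:
        q = np.percentile(g, [5, 25, 50, 75, 95], method="linear")
        return pd.Series({"n": len(g), "p5": q[0], "q25": q[1], "median": q[2],
                          "q75": q[3], "p95": q[4]})

    out = df.groupby(group_col)["rate"].apply(_summ).unstack()
    out["n"] = out["n"].astype(int)
    return out


@dataclass
class MutualExclusivityResult:
    genes: tuple[str, ...]
    observed_cooccurrence: int
    n_perm: int
    p_value: float
    per_gene_mutated: dict[str, int]


def mutual_exclusivity(matrix: pd.DataFrame, genes: Sequence[str],
                       n_perm: int = 1000, seed: int = 0) -> MutualExclusivityResult:
    """Permutation test for mutual exclusivity of mutations across genes.

    ``matrix`` is a samples x genes boolean mutation matrix. The observed
    statistic is the number of samples mutated in >=2 of ``genes``. The null
    is built by independently permuting each gene's column with
    ``numpy.random.default_rng(seed)``, permuting genes in their given order
    within each replicate. The one-sided p-value
    ``(1 + #{perm cooccurrence <= observed}) / (n_perm + 1)`` tests the
    alternative "fewer co-occurrences than expected by chance".
    """
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    missing = [g for g in genes if g not in matrix.columns]
    if missing:
        raise KeyError(f"genes absent from mutation matrix: {missing}")
    cols = matrix[list(genes)].to_numpy(dtype=bool)
    observed = int((cols.sum(axis=1) >= 2).sum())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = np.column_stack([rng.permutation(cols[:, j]) for j in range(cols.shape[1])])
        if int((perm.sum(axis=1) >= 2).sum()) <= observed:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    per_gene = {g: int(cols[:, j].sum()) for j, g in enumerate(genes)}
    return MutualExclusivityResult(tuple(genes), observed, n_perm, p, per_gene)


@dataclass
class RankTestResult:
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int


def expression_by_mutation_status(expr: pd.Series,
                                  mutated: Iterable[bool]) -> RankTestResult:
    """Two-sided Mann-Whitney U comparison of expression by mutation status.

    Group A holds mutated samples. Uses the exact U null distribution when
    there are no ties and the product of group sizes is small enough to
    enumerate; otherwise the tie-corrected normal approximation.
    """
    mask = np.asarray(list(mutated), dtype=bool)
    values = np.asarray(expr, dtype=float)
    if mask.shape[0] != values.shape[0]:
        raise ValueError("expression and mutation status length mismatch")
    a, b = values[mask], values[~mask]
    if a.size == 0 or b.size == 0:
        raise ValueError("both mutated and non-mutated groups must be non-empty")
    method = "exact" if (np.unique(values).size == values.size
                         and a.size * b.size <= 5000) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankTestResult(float(res.statistic), float(res.pvalue),
                          float(np.median(a)), float(np.median(b)),
                          int(a.size), int(b.size))


def mutation_matrix(report: FilterReport, protein_altering_only: bool = True) -> pd.DataFrame:
    """Samples x genes boolean matrix of surviving (optionally protein-altering) mutations."""
    df = report.to_frame()
    df = df[df["pass"]]
    if protein_altering_only:
        df = df[df["consequence"].map(is_protein_altering)]
    samples = sorted({c.sample_id for c in report.calls})
    if df.empty:
        return pd.DataFrame(False, index=samples, columns=[])
    mat = (df.assign(v=True).pivot_table(index="sample_id", columns="gene",
                                         values="v", aggfunc="any", fill_value=False))
    return mat.reindex(samples, fill_value=False).astype(bool)
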