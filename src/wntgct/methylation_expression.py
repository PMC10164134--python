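"""Promoter methylation and WNT marker expression analyses.

Methylation enters as a probe x sample matrix of beta values in [0,1]
(0 = unmethylated, 1 = fully methylated) with per-probe annotation. Probe
filtering removes probes with missing values, cross-hybridizing probes,
probes in repeat regions and probes on sex chromosomes. Promoter-level gene
summaries feed the reciprocal activator/repressor pattern test: WNT
activators are expected to show low promoter methylation and repressors high,
the epigenetic configuration favoring pathway activity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import GeneAnnotation
from .cn_burden import WntGeneSet

logger = logging.getLogger(__name__)

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}
EXPRESSION_GROUPS = ("PGC", "testis", "type_I", "type_II")

#: Six frequently used markers of WNT pathway activity. TCF7 and TCF7L2 are
#: the current symbols for the transcription factors historically called
#: TCF1 and TCF4.
DEFAULT_MARKERS = ("CTNNB1", "TCF7", "TCF7L2", "FZD7", "MYC", "CCND1")

PROBE_FLAGS = ("cross_hybridizing", "in_repeat")


@dataclass
class MethylationMatrix:
    """Beta values (probes x samples) with probe annotation.

    ``annot`` is indexed by probe id with columns gene, chrom, pos and the
    boolean flags cross_hybridizing and in_repeat.
    """

    betas: pd.DataFrame
    annot: pd.DataFrame

    def __post_init__(self) -> None:
        if self.betas.index.has_duplicates:
            raise ValueError("duplicate probe ids in beta matrix")
        vals = self.betas.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nansum((vals < 0) | (vals > 1))
        if bad:
            raise ValueError(f"{int(bad)} beta values outside [0,1]")
        missing_annot = self.betas.index.difference(self.annot.index)
        if len(missing_annot):
            raise ValueError(f"probes without annotation: {list(missing_annot[:5])}")


@dataclass
class ProbeFilterResult:
    matrix: MethylationMatrix
    removed: dict[str, int]  # per-criterion removal counts (a probe may hit several)
    n_in: int
    n_out: int


def filter_probes(m: MethylationMatrix) -> ProbeFilterResult:
    """Remove probes with missing betas, exclusion flags or on sex chromosomes.

    Idempotent: re-filtering an already filtered matrix removes nothing.
    """
    annot = m.annot.loc[m.betas.index]
    missing = m.betas.isna().any(axis=1)
    cross = annot["cross_hybridizing"].astype(bool)
    repeat = annot["in_repeat"].astype(bool)
    sex = annot["chrom"].isin(SEX_CHROMS)
    drop = missing | cross | repeat | sex
    removed = {
        "missing_values": int(missing.sum()),
        "cross_hybridizing": int(cross.sum()),
        "in_repeat": int(repeat.sum()),
        "sex_chrom": int(sex.sum()),
    }
    keep = m.betas.index[~drop]
    logger.info("probe filter: %d -> %d probes (%s)", len(m.betas), len(keep), removed)
    out = MethylationMatrix(m.betas.loc[keep], m.annot.loc[keep])
    return ProbeFilterResult(out, removed, len(m.betas), len(keep))


def promoter_beta_by_gene(m: MethylationMatrix,
                          genes: Sequence[GeneAnnotation]) -> pd.DataFrame:
    """Mean beta of promoter-window probes per gene per sample.

    A probe belongs to a gene's promoter when it lies on the same chromosome
    within [promoter_start, promoter_end). Genes with no promoter probe are
    omitted (logged). The unweighted mean keeps the output in [0,1].
    """
    rows = {}
    annot = m.annot.loc[m.betas.index]
    for g in genes:
        in_prom = (annot["chrom"] == g.chrom) & \
                  (annot["pos"] >= g.promoter_start) & (annot["pos"] < g.promoter_end)
        probes = annot.index[in_prom]
        if len(probes) == 0:
            logger.info("gene %s has no promoter probes; omitted", g.gene)
            continue
        rows[g.gene] = m.betas.loc[probes].mean(axis=0)
    if not rows:
        return pd.DataFrame(columns=m.betas.columns)
    return pd.DataFrame(rows).T


@dataclass
class ReciprocalPatternResult:
    activator_mean: float
    repressor_mean: float
    direction: str          # "activators_lower" | "repressors_lower" | "none"
    u_statistic: float
    p_value: float
    n_activators: int
    n_repressors: int


def reciprocal_pattern_test(gene_betas: pd.DataFrame,
                            geneset: WntGeneSet) -> ReciprocalPatternResult:
    """Rank test for reciprocal promoter methylation of activators vs repressors.

    Each gene is summarized by its median beta across samples; activator and
    repressor gene summaries are compared two-sided by Mann-Whitney U. The
    result is symmetric under swapping the role labels (direction flips, p
    unchanged).
    """
    med = gene_betas.median(axis=1)
    act = med[med.index.isin(geneset.activators)]
    rep = med[med.index.isin(geneset.repressors)]
    if len(act) < 2 or len(rep) < 2:
        raise ValueError("need >=2 genes per role with beta values")
    method = "exact" if (np.unique(med.to_numpy()).size == med.size
                         and len(act) * len(rep) <= 5000) else "asymptotic"
    res = stats.mannwhitneyu(act, rep, alternative="two-sided", method=method)
    am, rm = float(act.mean()), float(rep.mean())
    if am < rm:
        direction = "activators_lower"
    elif rm < am:
        direction = "repressors_lower"
    else:
        direction = "none"
    return ReciprocalPatternResult(am, rm, direction, float(res.statistic),
                                   float(res.pvalue), len(act), len(rep))


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan


def marker_expression_comparison(expr: pd.DataFrame, groups: Mapping[str, str],
                                 markers: Sequence[str] = DEFAULT_MARKERS,
                                 welch: bool = True) -> tuple[pd.DataFrame, list[str]]:
    """Group means +/- SEM and t-tests of WNT-activity markers vs PGC and testis.

    ``expr`` is genes x samples; ``groups`` maps sample id to one of
    PGC/testis/type_I/type_II. For each marker and each group the table
    reports mean, SEM and the two-sided (Welch by default) t-test p-values
    against the PGC and testis reference groups. Markers missing from the
    matrix are skipped and returned in the second element.
    """
    glabels = pd.Series({s: g for s, g in groups.items() if s in expr.columns})
    bad = set(glabels) - set(EXPRESSION_GROUPS)
    if bad:
        raise ValueError(f"unknown expression groups: {sorted(bad)}")
    counts = glabels.value_counts()
    for g in counts.index:
        if counts[g] < 2:
            raise ValueError(f"group {g!r} has <2 samples")
    missing = [m for m in markers if m not in expr.index]
    if missing:
        logger.warning("markers absent from expression matrix: %s", missing)
    rows = []
    for marker in markers:
        if marker in missing:
            continue
        vals = expr.loc[marker]
        per_group = {g: vals[glabels.index[glabels == g]].to_numpy(dtype=float)
                     for g in EXPRESSION_GROUPS if (glabels == g).any()}
        for g, v in per_group.items():
            row = {"marker": marker, "group": g, "n": len(v),
                   "mean": float(v.mean()), "sem": _sem(v)}
            for ref in ("PGC", "testis"):
                if ref in per_group and g != ref:
                    a, b = v, per_group[ref]
                    if np.ptp(np.concatenate([a, b])) == 0:
                        p = 1.0
                    else:
                        p = float(stats.ttest_ind(a, b, equal_var=(not welch)).pvalue)
                    row[f"p_vs_{ref}"] = p
                else:
                    row[f"p_vs_{ref}"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows), missing
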