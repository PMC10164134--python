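"""Synthetic multi-omic GCT cohort generator with planted ground truth.

The generator emits exactly the formats the I/O layer reads — clinical TSV,
per-pair VCFs, SEG, beta and expression matrices, BED annotations — together
with ground-truth sidecars, so every analysis stage can be exercised and its
planted effect recovered without any external data.

What is planted, per layer:

* strata: each sample is assigned none / cn_poor / cn_rich; cn_poor samples
  receive 1..5 and cn_rich 6..10 direction-aware focal WNT alterations
  (activator gains, repressor losses) on top of a role-neutral background
  alteration rate that is equal across strata;
* variants: passing somatic calls at a configurable rate per Mb, plus
  variants violating known subsets of the five filter rules;
* outcomes: relapse probabilities 0.00 / 0.07 / 0.30 by stratum and
  exponential survival with per-stratum hazard multipliers (cn_rich 3x);
* methylation: promoter betas low for activators (mean 0.2) and high for
  repressors (mean 0.7), the reciprocal pattern;
* LOH: arm-level LOH counts Poisson(12) for patients >= 6 years and
  Poisson(1) below;
* expression: WNT-activity markers elevated in tumors (type I strongest) and
  CTNNB1 further elevated in FAT2/FAT3-mutant samples.

Randomness: one master seed; per-layer child generators are spawned from a
single ``numpy.random.SeedSequence`` in a fixed order (clinical, segments,
variants, methylation, expression, survival), so layers are individually
reproducible and byte-identical across runs.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotations import ArmDefinition, GeneAnnotation, default_arms, promoter_window
from .cn_burden import Segment, SegmentProfile, WntGeneSet, stratify
from .config import VcfFieldNames
from . import cohort_io
from .somatic_filter import RULES, VariantCall

STRATA = ("none", "cn_poor", "cn_rich")

#: Named driver genes given reserved slots in the synthetic genome so that
#: mutual-exclusivity and mutation/expression comparisons have targets.
NAMED_BACKGROUND_GENES = ("KIT", "KRAS", "NRAS", "KMT2D", "ATM", "PRKDC",
                          "MYC", "CCND1", "TCF7", "DMRT1", "PTEN", "NOTCH1")

CONSEQUENCE_PROBS = {
    "missense": 0.55, "stop_gain": 0.08, "splice_site": 0.05,
    "frameshift": 0.07, "inframe_indel": 0.05, "silent": 0.15, "other": 0.05,
}


@dataclass
class SimulationConfig:
    """All planted study conditions; defaults are the pipeline's reference scenario."""

    n_samples: int = 114
    seed: int = 0
    # cohort composition
    type_i_fraction: float = 0.45
    histology_probs_type_i: dict = field(default_factory=lambda: {"TER": 0.4, "YST": 0.6})
    histology_probs_type_ii: dict = field(default_factory=lambda: {
        "EC": 0.20, "SE": 0.35, "TER": 0.10, "MMGCT": 0.20, "YST": 0.15})
    site_probs: dict = field(default_factory=lambda: {
        "testis": 0.60, "ovary": 0.25, "extragonadal": 0.15})
    # somatic mutations
    target_mb: float = 38.0
    nonsilent_rate_per_mb: float = 0.23
    silent_rate: float = 1.5           # expected silent mutations per sample
    failing_rate: float = 4.0          # expected rule-violating candidates per sample
    fat_mutation_fraction: float = 0.15  # samples carrying a FAT2/FAT3 mutation
    kit_kras_nras_fractions: tuple = (0.08, 0.08, 0.04)  # mutually exclusive drivers
    # copy number
    stratum_probs: tuple = (1 / 3, 1 / 3, 1 / 3)   # none, cn_poor, cn_rich
    cn_poor_counts: tuple = (1, 5)     # inclusive range of planted WNT alterations
    cn_rich_counts: tuple = (6, 10)
    # Background instability: per-sample count of altered non-WNT genes is
    # gamma-Poisson (negative binomial), emulating the wide spread of genomic
    # instability across tumors. The overdispersion keeps the planted WNT
    # delta small relative to between-sample variation, as it is genome-wide.
    background_alteration_mean: float = 100.0
    background_dispersion_shape: float = 3.0
    altered_log2: float = 0.8
    focal_pad_bp: int = 500_000
    segment_noise_sd: float = 0.02
    # arm-level LOH
    loh_mean_older: float = 12.0
    loh_mean_younger: float = 1.0
    loh_arm_coverage: float = 0.9
    age_cut_years: float = 6.0
    # outcomes
    relapse_probs: tuple = (0.00, 0.07, 0.30)      # by stratum
    hazard_multipliers: tuple = (1.0, 1.3, 3.0)    # by stratum
    baseline_hazard: float = 0.012                 # per month
    censoring_rate: float = 0.010                  # per month
    missing_relapse_prob: float = 0.02
    # methylation
    beta_mean_activator: float = 0.2
    beta_mean_repressor: float = 0.7
    beta_mean_background: float = 0.5
    beta_sd: float = 0.1
    probes_per_promoter: int = 3
    n_background_meth_genes: int = 40
    # expression
    expr_base_mean: float = 5.0
    expr_sd: float = 1.0
    marker_effect_type_i: float = 2.0   # log2 shift of WNT markers in type I tumors
    marker_effect_type_ii: float = 1.0
    ctnnb1_fat_effect: float = 1.5      # extra CTNNB1 shift in FAT2/FAT3-mutant samples
    n_reference_pgc: int = 5
    n_reference_testis: int = 5
    n_background_expr_genes: int = 30
    burden_threshold: int = 5

    def validate(self) -> None:
        probs = list(self.stratum_probs) + list(self.relapse_probs) + \
            [self.type_i_fraction, self.fat_mutation_fraction]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0,1]")
        if abs(sum(self.stratum_probs) - 1.0) > 1e-9:
            raise ValueError("stratum probabilities must sum to 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if any(h <= 0 for h in self.hazard_multipliers):
            raise ValueError("hazard multipliers must be positive")
        if self.cn_rich_counts[0] <= self.burden_threshold:
            raise ValueError("cn_rich planted counts must exceed the burden threshold")
        if self.cn_poor_counts[0] < 1 or self.cn_poor_counts[1] > self.burden_threshold:
            raise ValueError("cn_poor planted counts must lie in 1..threshold")


@dataclass
class GroundTruth:
    """Planted truth per layer, consistent with the emitted files by construction."""

    samples: pd.DataFrame     # sample_id, stratum, planted_score, loh_arm_count, ...
    variants: pd.DataFrame    # sample_id, chrom, pos, gene, consequence, failed_rules
    gene_cn: pd.DataFrame     # sample_id, gene, state, focal
    arm_loh: pd.DataFrame     # sample_id, arm, loh

    def write(self, directory) -> None:
        d = Path(directory)
        self.samples.to_csv(d / "truth_samples.tsv", sep="\t", index=False)
        self.variants.to_csv(d / "truth_variants.tsv", sep="\t", index=False)
        self.gene_cn.to_csv(d / "truth_gene_cn.tsv", sep="\t", index=False)
        self.arm_loh.to_csv(d / "truth_arm_loh.tsv", sep="\t", index=False)


# ------------------------------------------------------------- gene layout

def layout_genes(geneset: WntGeneSet, arms: Sequence[ArmDefinition],
                 n_background: int = 400, gene_length: int = 100_000,
                 spacing: int = 5_000_000, offset: int = 3_000_000,
                 promoter_upstream: int = 1500,
                 promoter_downstream: int = 500) -> list[GeneAnnotation]:
    """Deterministic layout of WNT, named driver and background genes on the arms.

    Slots are placed every ``spacing`` bp starting ``offset`` bp into each
    arm, walking arms in their given order, so no two genes sit within the
    focal padding of each other. The layout is a pure function of its
    arguments (no randomness).
    """
    slots: list[tuple[str, int]] = []
    for arm in arms:
        pos = arm.start + offset
        while pos + gene_length + spacing // 2 < arm.end:
            slots.append((arm.chrom, pos))
            pos += spacing
    names = sorted(geneset.role) + list(NAMED_BACKGROUND_GENES) + \
        [f"GENE{i:04d}" for i in range(n_background)]
    if len(names) > len(slots):
        raise ValueError("synthetic genome too small for requested gene count")
    # spread genes across the genome rather than packing the first arms
    stride = len(slots) // len(names)
    genes = []
    for i, name in enumerate(names):
        chrom, start = slots[i * stride]
        strand = "+" if i % 2 == 0 else "-"
        end = start + gene_length
        ps, pe = promoter_window(start, end, strand, promoter_upstream,
                                 promoter_downstream)
        genes.append(GeneAnnotation(name, chrom, start, end, strand, ps, pe))
    return genes


# ----------------------------------------------------------- layer builders

def _gen_clinical(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_samples):
        sid = f"S{i + 1:04d}"
        is_type_i = rng.random() < cfg.type_i_fraction
        gct_type = "I" if is_type_i else "II"
        hist_probs = cfg.histology_probs_type_i if is_type_i else cfg.histology_probs_type_ii
        hists = sorted(hist_probs)
        histology = str(rng.choice(hists, p=[hist_probs[h] for h in hists]))
        sites = sorted(cfg.site_probs)
        site = str(rng.choice(sites, p=[cfg.site_probs[s] for s in sites]))
        sex = "female" if site == "ovary" else (
            "male" if site == "testis" else ("female" if rng.random() < 0.5 else "male"))
        age = float(rng.uniform(0.0, 5.0) if is_type_i else rng.uniform(12.0, 24.0))
        rows.append({"sample_id": sid, "age_years": round(age, 2), "sex": sex,
                     "site": site, "histology": histology, "gct_type": gct_type})
    df = pd.DataFrame(rows)
    assigned = list(rng.choice(STRATA, size=cfg.n_samples, p=cfg.stratum_probs))
    if cfg.n_samples >= len(STRATA):
        # guarantee every stratum is represented
        for i, missing in enumerate(s for s in STRATA if s not in set(assigned)):
            assigned[i] = missing
    df["stratum"] = assigned
    return df


def assign_outcomes(clinical: pd.DataFrame, cfg: SimulationConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Draw relapse flags and exponential survival per planted stratum."""
    idx = {s: i for i, s in enumerate(STRATA)}
    out = clinical.copy()
    relapse, times, events = [], [], []
    for stratum in out["stratum"]:
        k = idx[stratum]
        r: Optional[bool] = bool(rng.random() < cfg.relapse_probs[k])
        if rng.random() < cfg.missing_relapse_prob:
            r = None
        relapse.append(r)
        lam = cfg.baseline_hazard * cfg.hazard_multipliers[k]
        t_event = rng.exponential(1.0 / lam)
        t_cens = rng.exponential(1.0 / cfg.censoring_rate) if cfg.censoring_rate > 0 \
            else np.inf
        t = min(t_event, t_cens)
        times.append(max(round(t, 2), 0.1))
        events.append(bool(t_event <= t_cens))
    out["relapse"] = relapse
    out["survival_time"] = times
    out["event"] = events
    return out


def generate_survival(strata: Sequence[str], cfg: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Exponential event times with per-stratum hazards and independent censoring."""
    if any(h <= 0 for h in cfg.hazard_multipliers):
        raise ValueError("hazard multipliers must be positive")
    idx = {s: i for i, s in enumerate(STRATA)}
    lam = np.array([cfg.baseline_hazard * cfg.hazard_multipliers[idx[s]] for s in strata])
    t_event = rng.exponential(1.0 / lam)
    if cfg.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censoring_rate, size=len(lam))
    else:
        t_cens = np.full(len(lam), np.inf)
    return pd.DataFrame({
        "stratum": list(strata),
        "time": np.maximum(np.minimum(t_event, t_cens), 1e-3),
        "event": t_event <= t_cens,
    })


def simulate_outcome_layer(cfg: SimulationConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    """One replicate of the outcome layer alone: stratum, relapse, time, event.

    Used for replicate studies of the outcome statistics where the genomic
    layers are not needed; strata and relapse flags follow the same
    distributions as the full generator.
    """
    strata = list(rng.choice(STRATA, size=cfg.n_samples, p=cfg.stratum_probs))
    if cfg.n_samples >= len(STRATA):
        for i, missing in enumerate(s for s in STRATA if s not in set(strata)):
            strata[i] = missing
    idx = {s: i for i, s in enumerate(STRATA)}
    relapse = [bool(rng.random() < cfg.relapse_probs[idx[s]]) for s in strata]
    out = generate_survival(strata, cfg, rng)
    out["relapse"] = relapse
    return out


def _pick_planted_wnt(cfg: SimulationConfig, stratum: str, geneset: WntGeneSet,
                      rng: np.random.Generator) -> list[tuple[str, str]]:
    """(gene, direction) pairs: activator gains and repressor losses."""
    if stratum == "none":
        return []
    lo, hi = cfg.cn_poor_counts if stratum == "cn_poor" else cfg.cn_rich_counts
    hi = min(hi, len(geneset))
    k = int(rng.integers(lo, hi + 1))
    genes = list(rng.choice(sorted(geneset.role), size=k, replace=False))
    return [(g, "gain" if geneset.role[g] == "activator" else "loss") for g in genes]


def _build_profile(sid: str, planted: list[tuple[str, str]],
                   loh_arms: list[ArmDefinition], genes_by_name: dict,
                   arms: Sequence[ArmDefinition], cfg: SimulationConfig,
                   rng: np.random.Generator) -> SegmentProfile:
    """Segmented profile with focal alterations at planted genes plus LOH arms."""
    alt_by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for gene, direction in planted:
        g = genes_by_name[gene]
        lo = max(g.start - cfg.focal_pad_bp, 0)
        hi = g.end + cfg.focal_pad_bp
        val = cfg.altered_log2 if direction == "gain" else -cfg.altered_log2
        alt_by_chrom.setdefault(g.chrom, []).append((lo, hi, val))
    loh_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for arm in loh_arms:
        span = int(arm.length * cfg.loh_arm_coverage)
        loh_by_chrom.setdefault(arm.chrom, []).append((arm.start, arm.start + span))

    chroms = sorted({a.chrom for a in arms})
    arm_by_chrom: dict[str, list[ArmDefinition]] = {}
    for a in arms:
        arm_by_chrom.setdefault(a.chrom, []).append(a)
    segments: list[Segment] = []
    for chrom in chroms:
        chrom_end = max(a.end for a in arm_by_chrom[chrom])
        cuts = {0, chrom_end}
        for lo, hi, _ in alt_by_chrom.get(chrom, []):
            cuts.update((lo, min(hi, chrom_end)))
        for lo, hi in loh_by_chrom.get(chrom, []):
            cuts.update((lo, hi))
        for a in arm_by_chrom[chrom]:
            cuts.add(a.start)
        edges = sorted(cuts)
        for lo, hi in zip(edges, edges[1:]):
            if hi <= lo:
                continue
            mid = (lo + hi) // 2
            log2 = float(rng.normal(0.0, cfg.segment_noise_sd))
            for alo, ahi, val in alt_by_chrom.get(chrom, []):
                if alo <= mid < ahi:
                    log2 = val
                    break
            loh = any(llo <= mid < lhi for llo, lhi in loh_by_chrom.get(chrom, []))
            segments.append(Segment(chrom, lo, hi, round(log2, 4), loh,
                                    n_markers=max((hi - lo) // 5000, 1)))
    return SegmentProfile(sid, segments)


def _gen_cn_layer(clinical: pd.DataFrame, geneset: WntGeneSet,
                  genes: Sequence[GeneAnnotation], arms: Sequence[ArmDefinition],
                  cfg: SimulationConfig, rng: np.random.Generator):
    """Segment profiles plus gene-level and arm-LOH truth tables."""
    genes_by_name = {g.gene: g for g in genes}
    wnt_names = set(geneset.role)
    background_pool = sorted(set(genes_by_name) - wnt_names)
    profiles: dict[str, SegmentProfile] = {}
    cn_rows, loh_rows, planted_scores, loh_counts = [], [], [], []
    for r in clinical.itertuples():
        planted = _pick_planted_wnt(cfg, r.stratum, geneset, rng)
        # role-neutral background instability, equal in expectation across strata
        lam = rng.gamma(cfg.background_dispersion_shape,
                        cfg.background_alteration_mean / cfg.background_dispersion_shape)
        n_bg = int(rng.poisson(lam))
        bg_genes = list(rng.choice(background_pool, size=min(n_bg, len(background_pool)),
                                   replace=False))
        bg = [(g, "gain" if rng.random() < 0.5 else "loss") for g in bg_genes]
        is_older = r.age_years >= cfg.age_cut_years
        mean = cfg.loh_mean_older if is_older else cfg.loh_mean_younger
        n_loh = int(min(rng.poisson(mean), len(arms)))
        loh_arms = [arms[i] for i in sorted(rng.choice(len(arms), size=n_loh,
                                                       replace=False))]
        profiles[r.sample_id] = _build_profile(
            r.sample_id, planted + bg, loh_arms, genes_by_name, arms, cfg, rng)
        for gene, direction in planted + bg:
            cn_rows.append({"sample_id": r.sample_id, "gene": gene,
                            "state": direction, "focal": True})
        loh_names = {a.name for a in loh_arms}
        for a in arms:
            loh_rows.append({"sample_id": r.sample_id, "arm": a.name,
                             "loh": a.name in loh_names})
        planted_scores.append(len(planted))
        loh_counts.append(n_loh)
    return profiles, pd.DataFrame(cn_rows), pd.DataFrame(loh_rows), \
        planted_scores, loh_counts


def _violation_evidence(violations: frozenset, pop_af_base: Optional[float] = None):
    """Tumor/normal evidence realizing exactly the requested rule violations.

    Violations are engineered on independent fields so that any of the 2^5
    subsets can be produced: R1 via alt reads in the normal, R2 via one-sided
    strand support, R3 via mapping quality, R4 via normal depth, R5 via a
    catalogued population frequency.
    """
    tumor_ref, tumor_alt = 30, 20
    alt_fwd, alt_rev = (20, 0) if "R2_strand_reads" in violations else (10, 10)
    normal_alt = 2 if "R1_vaf" in violations else 0
    normal_total = 8 if "R4_depth" in violations else 60
    normal_ref = normal_total - normal_alt
    mq = 20.0 if "R3_quality" in violations else 50.0
    bq = 30.0
    pop_af = 0.05 if "R5_popaf" in violations else pop_af_base
    return {
        "ad_t": (tumor_ref, tumor_alt), "ad_n": (normal_ref, normal_alt),
        "adf": (15, alt_fwd), "adr": (15, alt_rev),
        "mq": mq, "bq": bq, "pop_af": pop_af,
    }


def generate_variant_panel() -> tuple[list[VariantCall], dict[str, frozenset]]:
    """32 variants enumerating every subset of the five filter-rule violations.

    Returns the calls plus a map from variant key to the planted violation
    set (the empty set variant is the only expected survivor).
    """
    calls, truth = [], {}
    for i, bits in enumerate(product((False, True), repeat=len(RULES))):
        violations = frozenset(r for r, b in zip(RULES, bits) if b)
        ev = _violation_evidence(violations)
        t_depth = sum(ev["ad_t"])
        n_depth = sum(ev["ad_n"])
        call = VariantCall(
            sample_id="PANEL", chrom="chr1", pos=1_000_000 + i * 1000,
            ref="A", alt="T",
            tumor_vaf=ev["ad_t"][1] / t_depth,
            normal_vaf=ev["ad_n"][1] / n_depth,
            tumor_depth=t_depth, normal_depth=n_depth,
            alt_fwd=ev["adf"][1], alt_rev=ev["adr"][1],
            mapping_quality=ev["mq"], base_quality=ev["bq"],
            pop_af=ev["pop_af"], consequence="missense", gene=f"GENE{i:04d}",
            normal_alt=ev["ad_n"][1],
        )
        calls.append(call)
        truth[call.key] = violations
    return calls, truth


def _gen_variants(clinical: pd.DataFrame, genes: Sequence[GeneAnnotation],
                  geneset: WntGeneSet, cfg: SimulationConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Per-sample candidate variants: passing calls plus rule-violating decoys."""
    genes_by_name = {g.gene: g for g in genes}
    pool = sorted(genes_by_name)
    cons = sorted(CONSEQUENCE_PROBS)
    cons_p = [CONSEQUENCE_PROBS[c] for c in cons]
    nonsilent = [c for c in cons if c not in ("silent", "other")]
    rule_cycle = list(RULES)
    rows = []
    exclusive = {}
    for gene, frac in zip(("KIT", "KRAS", "NRAS"), cfg.kit_kras_nras_fractions):
        exclusive[gene] = frac
    for si, r in enumerate(clinical.itertuples()):
        chosen: list[tuple[str, str, frozenset]] = []
        n_pass = int(rng.poisson(cfg.nonsilent_rate_per_mb * cfg.target_mb))
        for _ in range(n_pass):
            gene = str(rng.choice(pool))
            c = str(rng.choice(nonsilent))
            chosen.append((gene, c, frozenset()))
        n_silent = int(rng.poisson(cfg.silent_rate))
        for _ in range(n_silent):
            chosen.append((str(rng.choice(pool)), "silent", frozenset()))
        # mutually exclusive KIT/KRAS/NRAS drivers (at most one per sample)
        u = rng.random()
        acc = 0.0
        for gene, frac in exclusive.items():
            acc += frac
            if u < acc:
                chosen.append((gene, "missense", frozenset()))
                break
        if rng.random() < cfg.fat_mutation_fraction:
            chosen.append((str(rng.choice(["FAT2", "FAT3"])), "stop_gain", frozenset()))
        if si == 0:
            # guarantee every rule is violated by at least one planted variant
            for rule in rule_cycle:
                chosen.append((str(rng.choice(pool)), str(rng.choice(cons, p=cons_p)),
                               frozenset([rule])))
        n_fail = int(rng.poisson(cfg.failing_rate))
        for _ in range(n_fail):
            k = int(rng.integers(1, len(RULES) + 1))
            viol = frozenset(rng.choice(RULES, size=k, replace=False))
            chosen.append((str(rng.choice(pool)), str(rng.choice(cons, p=cons_p)), viol))
        used_pos: set[tuple[str, int]] = set()
        for gene, c, viol in chosen:
            g = genes_by_name[gene]
            for _ in range(20):
                pos = int(rng.integers(g.start + 1, g.end))  # 1-based within gene
                if (g.chrom, pos) not in used_pos:
                    break
            used_pos.add((g.chrom, pos))
            ev = _violation_evidence(viol)
            ref, alt = (b := rng.choice(list("ACGT"), size=2, replace=False))[0], b[1]
            rows.append({
                "sample_id": r.sample_id, "chrom": g.chrom, "pos": pos,
                "ref": str(ref), "alt": str(alt), "gene": gene, "consequence": c,
                "failed_rules": ";".join(sorted(viol)) if viol else "",
                **{k: v for k, v in ev.items()},
            })
    return pd.DataFrame(rows)


def _write_vcfs(variants: pd.DataFrame, clinical: pd.DataFrame,
                arms: Sequence[ArmDefinition], out_dir: Path) -> None:
    contigs: dict[str, int] = {}
    for a in arms:
        contigs[a.chrom] = max(contigs.get(a.chrom, 0), a.end)
    f = VcfFieldNames()
    vcf_dir = out_dir / "vcf"
    vcf_dir.mkdir(parents=True, exist_ok=True)
    header = cohort_io.vcf_header(contigs, f)
    for sid in clinical["sample_id"]:
        sub = variants[variants["sample_id"] == sid].sort_values(["chrom", "pos"])
        with pysam.VariantFile(str(vcf_dir / f"{sid}.vcf"), "w", header=header) as vcf:
            for r in sub.itertuples():
                rec = vcf.new_record(contig=r.chrom, start=r.pos - 1,
                                     alleles=(r.ref, r.alt))
                rec.info[f.mapq] = float(r.mq)
                rec.info[f.baseq] = float(r.bq)
                if r.pop_af is not None and not pd.isna(r.pop_af):
                    rec.info[f.popaf] = float(r.pop_af)
                rec.info[f.gene] = r.gene
                rec.info[f.consequence] = r.consequence
                rec.samples[f.tumor_sample][f.ad] = tuple(r.ad_t)
                rec.samples[f.tumor_sample][f.adf] = tuple(r.adf)
                rec.samples[f.tumor_sample][f.adr] = tuple(r.adr)
                rec.samples[f.tumor_sample][f.dp] = int(sum(r.ad_t))
                rec.samples[f.normal_sample][f.ad] = tuple(r.ad_n)
                rec.samples[f.normal_sample][f.adf] = (r.ad_n[0] // 2, r.ad_n[1] // 2)
                rec.samples[f.normal_sample][f.adr] = (
                    r.ad_n[0] - r.ad_n[0] // 2, r.ad_n[1] - r.ad_n[1] // 2)
                rec.samples[f.normal_sample][f.dp] = int(sum(r.ad_n))
                vcf.write(rec)


def _gen_methylation(clinical: pd.DataFrame, genes: Sequence[GeneAnnotation],
                     geneset: WntGeneSet, cfg: SimulationConfig,
                     rng: np.random.Generator):
    """Promoter betas with the reciprocal activator/repressor pattern planted."""
    def beta_params(mean: float, sd: float) -> tuple[float, float]:
        common = mean * (1 - mean) / (sd * sd) - 1
        common = max(common, 0.5)
        return mean * common, (1 - mean) * common

    samples = list(clinical["sample_id"])
    genes_by_name = {g.gene: g for g in genes}
    meth_genes = sorted(geneset.role) + [f"GENE{i:04d}"
                                         for i in range(cfg.n_background_meth_genes)]
    probe_rows, beta_rows, index = [], [], []
    pid = 0
    for gene in meth_genes:
        g = genes_by_name[gene]
        role = geneset.role.get(gene)
        mean = {"activator": cfg.beta_mean_activator,
                "repressor": cfg.beta_mean_repressor}.get(role, cfg.beta_mean_background)
        a, b = beta_params(mean, cfg.beta_sd)
        width = g.promoter_end - g.promoter_start
        for k in range(cfg.probes_per_promoter):
            pid += 1
            pos = g.promoter_start + (k + 1) * width // (cfg.probes_per_promoter + 1)
            index.append(f"cg{pid:07d}")
            probe_rows.append({"probe": f"cg{pid:07d}", "gene": gene,
                               "chrom": g.chrom, "pos": pos,
                               "cross_hybridizing": False, "in_repeat": False})
            beta_rows.append(np.clip(rng.beta(a, b, size=len(samples)), 1e-4, 1 - 1e-4))
    # probes exercising each exclusion criterion
    a, b = beta_params(cfg.beta_mean_background, cfg.beta_sd)
    for flag in ("cross_hybridizing", "in_repeat"):
        for _ in range(5):
            pid += 1
            index.append(f"cg{pid:07d}")
            probe_rows.append({"probe": f"cg{pid:07d}", "gene": "NA", "chrom": "chr1",
                               "pos": int(rng.integers(1, 2_000_000)),
                               "cross_hybridizing": flag == "cross_hybridizing",
                               "in_repeat": flag == "in_repeat"})
            beta_rows.append(np.clip(rng.beta(a, b, size=len(samples)), 1e-4, 1 - 1e-4))
    for chrom in ("chrX", "chrY"):
        for _ in range(3):
            pid += 1
            index.append(f"cg{pid:07d}")
            probe_rows.append({"probe": f"cg{pid:07d}", "gene": "NA", "chrom": chrom,
                               "pos": int(rng.integers(1, 2_000_000)),
                               "cross_hybridizing": False, "in_repeat": False})
            beta_rows.append(np.clip(rng.beta(a, b, size=len(samples)), 1e-4, 1 - 1e-4))
    for _ in range(4):  # probes with planted missing values
        pid += 1
        index.append(f"cg{pid:07d}")
        probe_rows.append({"probe": f"cg{pid:07d}", "gene": "NA", "chrom": "chr2",
                           "pos": int(rng.integers(1, 2_000_000)),
                           "cross_hybridizing": False, "in_repeat": False})
        vals = np.clip(rng.beta(a, b, size=len(samples)), 1e-4, 1 - 1e-4)
        vals[rng.integers(0, len(samples))] = np.nan
        beta_rows.append(vals)
    betas = pd.DataFrame(np.round(np.array(beta_rows), 4), index=index, columns=samples)
    annot = pd.DataFrame(probe_rows).set_index("probe")
    return betas, annot


def _gen_expression(clinical: pd.DataFrame, fat_mutant: set[str],
                    cfg: SimulationConfig, rng: np.random.Generator):
    """Expression matrix (genes x samples incl. PGC/testis references) + groups."""
    from .methylation_expression import DEFAULT_MARKERS

    tumor_samples = list(clinical["sample_id"])
    ref_pgc = [f"PGC{i + 1:02d}" for i in range(cfg.n_reference_pgc)]
    ref_testis = [f"NT{i + 1:02d}" for i in range(cfg.n_reference_testis)]
    samples = tumor_samples + ref_pgc + ref_testis
    groups = {}
    for r in clinical.itertuples():
        groups[r.sample_id] = "type_I" if r.gct_type == "I" else "type_II"
    groups.update({s: "PGC" for s in ref_pgc})
    groups.update({s: "testis" for s in ref_testis})
    genes = list(DEFAULT_MARKERS) + ["FAT2", "FAT3"] + \
        [f"GENE{i:04d}" for i in range(cfg.n_background_expr_genes)]
    genes = list(dict.fromkeys(genes))
    mat = rng.normal(cfg.expr_base_mean, cfg.expr_sd, size=(len(genes), len(samples)))
    df = pd.DataFrame(np.round(mat, 3), index=genes, columns=samples)
    effect = {"type_I": cfg.marker_effect_type_i, "type_II": cfg.marker_effect_type_ii}
    for marker in DEFAULT_MARKERS:
        for s in samples:
            df.loc[marker, s] += effect.get(groups[s], 0.0)
    for s in fat_mutant:
        if s in df.columns:
            df.loc["CTNNB1", s] += cfg.ctnnb1_fat_effect
    return df.round(3), groups


# ----------------------------------------------------------------- top level

def generate_cohort(cfg: SimulationConfig, out_dir) -> GroundTruth:
    """Emit a full synthetic cohort to ``out_dir`` and return its ground truth."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    rng_clin, rng_cn, rng_var, rng_meth, rng_expr, rng_surv = \
        (np.random.default_rng(s) for s in ss.spawn(6))

    geneset = cohort_io.default_wnt_geneset()
    arms = default_arms(autosomes_only=True)
    genes = layout_genes(geneset, arms)

    clinical = _gen_clinical(cfg, rng_clin)
    profiles, cn_truth, loh_truth, planted_scores, loh_counts = _gen_cn_layer(
        clinical, geneset, genes, arms, cfg, rng_cn)
    variants = _gen_variants(clinical, genes, geneset, cfg, rng_var)
    betas, annot = _gen_methylation(clinical, genes, geneset, cfg, rng_meth)
    fat_mutant = set(variants.loc[
        variants["gene"].isin(["FAT2", "FAT3"])
        & (variants["failed_rules"] == "")
        & variants["consequence"].isin(["missense", "stop_gain", "splice_site",
                                        "frameshift", "inframe_indel"]),
        "sample_id"])
    expr, groups = _gen_expression(clinical, fat_mutant, cfg, rng_expr)
    clinical = assign_outcomes(clinical, cfg, rng_surv)

    # emit files
    samples = [cohort_io.Sample(
        sample_id=r.sample_id, age_years=r.age_years, sex=r.sex, site=r.site,
        histology=r.histology, gct_type=r.gct_type, relapse=r.relapse,
        survival_time=r.survival_time, event=r.event)
        for r in clinical.itertuples()]
    cohort_io.write_clinical(samples, out / "clinical.tsv")
    cohort_io.write_segments(profiles, out / "segments.seg")
    cohort_io.write_gene_beds(genes, out / "genes.bed", out / "promoters.bed")
    cohort_io.write_geneset(geneset, out / "geneset.tsv")
    arms_df = pd.DataFrame([{"chrom": a.chrom, "arm": a.arm, "start": a.start,
                             "end": a.end} for a in arms])
    arms_df.to_csv(out / "arms.tsv", sep="\t", index=False)
    _write_vcfs(variants, clinical, arms, out)
    cohort_io.write_matrix(betas, out / "methylation_betas.tsv")
    annot.to_csv(out / "probe_annotation.tsv", sep="\t")
    cohort_io.write_matrix(expr, out / "expression.tsv", float_format="%.3f")
    pd.DataFrame({"sample_id": list(groups), "group": list(groups.values())}) \
        .to_csv(out / "expression_groups.tsv", sep="\t", index=False)

    truth_samples = clinical.copy()
    truth_samples["planted_score"] = planted_scores
    truth_samples["planted_stratum"] = [
        stratify(s, cfg.burden_threshold) for s in planted_scores]
    truth_samples["loh_arm_count"] = loh_counts
    truth = GroundTruth(
        samples=truth_samples,
        variants=variants[["sample_id", "chrom", "pos", "ref", "alt", "gene",
                           "consequence", "failed_rules"]],
        gene_cn=cn_truth, arm_loh=loh_truth)
    truth.write(out)
    return truth
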