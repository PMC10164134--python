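"""End-to-end orchestration: simulate, analyze every layer, write results.

``run_all`` is deliberately deterministic: with a fixed seed two runs produce
byte-identical output trees, which makes the whole pipeline regression-
testable as a unit.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cn_burden, cohort_io, methylation_expression as me, somatic_filter as sf
from . import survival_outcomes as surv
from .config import PipelineConfig
from .synthetic_cohort import SimulationConfig, generate_cohort


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def analyze_cohort(cohort: cohort_io.Cohort, out_dir, config: PipelineConfig | None = None,
                   mutual_exclusivity_seed: int = 0) -> dict:
    """Run every analysis stage on an assembled cohort; write tables and a summary."""
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    clinical = cohort.clinical_frame()

    # --- somatic filtering and mutation summaries
    all_calls = [c for calls in (cohort.variant_layer or {}).values() for c in calls]
    report = sf.filter_somatic(all_calls, cfg.filter)
    report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False,
                             float_format="%.4f")
    nonsilent = {}
    for c in report.passing:
        if sf.is_protein_altering(c.consequence):
            nonsilent[c.sample_id] = nonsilent.get(c.sample_id, 0) + 1
    counts = clinical[["sample_id", "histology"]].copy()
    counts["n_nonsilent"] = counts["sample_id"].map(nonsilent).fillna(0).astype(int)
    rate_summary = sf.rate_summary_by_group(counts, cfg.target_mb)
    rate_summary.to_csv(out / "mutation_rate_by_histology.tsv", sep="\t",
                        float_format="%.4f")
    summary["mean_nonsilent_per_mb"] = float(
        (counts["n_nonsilent"] / cfg.target_mb).mean())
    summary["n_variants_in"] = len(all_calls)
    summary["n_variants_pass"] = len(report.passing)

    mat = sf.mutation_matrix(report)
    mat.astype(int).to_csv(out / "mutation_matrix.tsv", sep="\t")
    me_genes = [g for g in ("KIT", "KRAS", "NRAS") if g in mat.columns]
    if len(me_genes) >= 2 and len(mat):
        res = sf.mutual_exclusivity(mat, me_genes, n_perm=999,
                                    seed=mutual_exclusivity_seed)
        summary["mutual_exclusivity"] = {
            "genes": list(res.genes), "observed_cooccurrence": res.observed_cooccurrence,
            "p_value": res.p_value}
    if cohort.expression_layer is not None and "CTNNB1" in cohort.expression_layer.index:
        fat_cols = [g for g in ("FAT2", "FAT3") if g in mat.columns]
        if fat_cols and len(mat):
            mutated = mat[fat_cols].any(axis=1)
            expr = cohort.expression_layer.loc["CTNNB1"].reindex(mutated.index).dropna()
            mutated = mutated.reindex(expr.index)
            if mutated.any() and (~mutated).any():
                r = sf.expression_by_mutation_status(expr, mutated)
                summary["ctnnb1_by_fat_mutation"] = {
                    "p_value": r.p_value, "median_mutated": r.median_a,
                    "median_wildtype": r.median_b}

    # --- copy number: gene states, burden, strata
    states_by_sample = {}
    for sid, profile in (cohort.cn_layer or {}).items():
        states_by_sample[sid] = cn_burden.assign_gene_cn(
            profile, cohort.genes, cfg.cn, cohort.arms)
    burden = cn_burden.burden_table(states_by_sample, cohort.geneset,
                                    cfg.outcome.burden_threshold,
                                    cfg.outcome.focal_only).sort_values("sample_id")
    burden.to_csv(out / "burden.tsv", sep="\t", index=False)
    strata = dict(zip(burden["sample_id"], burden["stratum"]))
    summary["stratum_sizes"] = {
        s: int((burden["stratum"] == s).sum()) for s in cn_burden.STRATA}
    try:
        inst = cn_burden.instability_control(states_by_sample, strata)
        summary["instability_control"] = {
            "mean_altered_cn_rich": inst.mean_altered_rich,
            "mean_altered_cn_poor": inst.mean_altered_poor,
            "p_value": inst.p_value}
    except ValueError:
        pass

    # --- arm-level LOH by age
    arm_calls = {sid: cn_burden.call_arm_loh(p, cohort.arms, cfg.cn.loh_min_arm_fraction)
                 for sid, p in (cohort.cn_layer or {}).items()}
    loh_mat = pd.DataFrame({sid: {c.arm: int(c.loh) for c in calls}
                            for sid, calls in arm_calls.items()}).T.sort_index()
    loh_mat.to_csv(out / "arm_loh_matrix.tsv", sep="\t")
    ages = dict(zip(clinical["sample_id"], clinical["age_years"]))
    try:
        loh_res = cn_burden.loh_age_comparison(arm_calls, ages,
                                               cfg.outcome.age_cut_years)
        summary["loh_by_age"] = {
            "median_younger": loh_res.median_younger,
            "median_older": loh_res.median_older, "p_value": loh_res.p_value}
    except (ValueError, KeyError):
        pass

    # --- methylation
    if cohort.methylation_layer is not None:
        filt = me.filter_probes(cohort.methylation_layer)
        gene_betas = me.promoter_beta_by_gene(filt.matrix, cohort.genes)
        cohort_io.write_matrix(gene_betas, out / "promoter_beta_by_gene.tsv")
        rec = me.reciprocal_pattern_test(gene_betas, cohort.geneset)
        summary["probe_filter_removed"] = filt.removed
        summary["reciprocal_methylation"] = {
            "activator_mean": rec.activator_mean, "repressor_mean": rec.repressor_mean,
            "direction": rec.direction, "p_value": rec.p_value}

    # --- marker expression
    if cohort.expression_layer is not None and cohort.expression_groups:
        table, missing = me.marker_expression_comparison(
            cohort.expression_layer, cohort.expression_groups, welch=cfg.outcome.welch)
        table.to_csv(out / "marker_expression.tsv", sep="\t", index=False,
                     float_format="%.5g")
        summary["markers_missing"] = missing

    # --- outcomes
    outcome_df = clinical.dropna(subset=["survival_time", "event"]).copy()
    outcome_df["stratum"] = outcome_df["sample_id"].map(strata)
    rel = surv.relapse_by_stratum(
        clinical.set_index("sample_id")["relapse"],
        pd.Series(strata, name="stratum"))
    rel.table.to_csv(out / "relapse_by_stratum.tsv", sep="\t", index=False,
                     float_format="%.4f")
    rel.pairwise.to_csv(out / "relapse_pairwise_tests.tsv", sep="\t", index=False,
                        float_format="%.6g")
    summary["relapse_by_stratum"] = {
        r["stratum"]: r["proportion"] for _, r in rel.table.iterrows()}
    pw = rel.pairwise.set_index(["stratum_a", "stratum_b"])
    if ("none", "cn_rich") in pw.index:
        summary["relapse_rich_vs_none"] = {
            "t_p": float(pw.loc[("none", "cn_rich"), "t_p"]),
            "fisher_p": float(pw.loc[("none", "cn_rich"), "fisher_p"])}

    two = outcome_df[outcome_df["stratum"].isin(["none", "cn_rich"])]
    if two["stratum"].nunique() == 2 and two["event"].astype(bool).any():
        lr = surv.logrank_test(two["survival_time"], two["event"].astype(bool),
                               two["stratum"])
        summary["logrank_rich_vs_none"] = {"statistic": lr.statistic,
                                           "p_value": lr.p_value}
    rich_rest = outcome_df.assign(
        g=np.where(outcome_df["stratum"] == "cn_rich", "cn_rich", "rest"))
    if rich_rest["g"].nunique() == 2 and rich_rest["event"].astype(bool).any():
        lr2 = surv.logrank_test(rich_rest["survival_time"],
                                rich_rest["event"].astype(bool), rich_rest["g"])
        summary["logrank_rich_vs_rest"] = {"statistic": lr2.statistic,
                                           "p_value": lr2.p_value}

    scores = burden.set_index("sample_id")["score"]
    sens = cn_burden.threshold_sensitivity(
        scores, clinical[["sample_id", "relapse", "survival_time", "event"]],
        cfg.outcome.sensitivity_thresholds)
    sens.to_csv(out / "threshold_sensitivity.tsv", sep="\t", index=False,
                float_format="%.6g")

    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def run_all(out_dir, seed: int = 0, n_samples: int = 114,
            sim_config: SimulationConfig | None = None,
            config: PipelineConfig | None = None) -> dict:
    """Simulate a cohort, re-read it from disk, and run every analysis stage."""
    out = Path(out_dir)
    sim = sim_config or SimulationConfig()
    sim.seed = seed
    sim.n_samples = n_samples
    generate_cohort(sim, out / "input")
    cohort = cohort_io.load_cohort(out / "input")
    return analyze_cohort(cohort, out / "results", config,
                          mutual_exclusivity_seed=seed)
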