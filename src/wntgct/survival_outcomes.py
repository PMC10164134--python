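"""Outcome statistics: Kaplan-Meier, log-rank, relapse tables and Cox models.

Estimation is delegated to lifelines (product-limit estimator, log-rank test,
Cox partial likelihood with Efron tie handling); this module fixes the
conventions used throughout the pipeline — which contrasts are computed, the
median tie rule for expression dichotomization, and the reporting surface.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "KMCurve", "km_estimate", "LogrankResult", "logrank_test",
    "relapse_by_stratum", "RelapseByStratum", "CoxResult",
    "cox_median_dichotomized", "plot_km",
]


@dataclass
class KMCurve:
    """Product-limit survival curve: S starts at 1 and steps only at event times."""

    times: np.ndarray       # distinct observed times (events and censorings), ascending
    survival: np.ndarray    # S(t) just after each time
    at_risk: np.ndarray     # risk-set size just before each time

    def survival_at(self, t: float) -> float:
        """S(t) with right-continuous step convention; S(t)=1 before the first time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate for one group.

    Censored observations reduce the risk set without producing a step.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("no records")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tab = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    obs_times = tab.index.to_numpy(dtype=float)
    return KMCurve(
        times=obs_times,
        survival=np.array([surv.loc[x] for x in tab.index], dtype=float),
        at_risk=tab["at_risk"].to_numpy(dtype=float),
    )


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    events_a: int
    events_b: int


def logrank_test(times, events, groups) -> LogrankResult:
    """Standard two-group log-rank test; tied events contribute jointly."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if labels.size != 2:
        raise ValueError(f"expected exactly two groups, got {labels.tolist()}")
    ma, mb = g == labels[0], g == labels[1]
    if ma.sum() == 0 or mb.sum() == 0:
        raise ValueError("both groups must be non-empty")
    if e.sum() == 0:
        raise ValueError("no events: log-rank test undefined")
    res = _ll_logrank(t[ma], t[mb], event_observed_A=e[ma], event_observed_B=e[mb])
    return LogrankResult(float(res.test_statistic), float(res.p_value),
                         int(ma.sum()), int(mb.sum()),
                         int(e[ma].sum()), int(e[mb].sum()))


@dataclass
class RelapseByStratum:
    table: pd.DataFrame      # stratum, n, n_relapse, proportion
    pairwise: pd.DataFrame   # stratum_a, stratum_b, t_p, fisher_p
    omitted: tuple[str, ...]


def relapse_by_stratum(relapse: pd.Series, strata: pd.Series,
                       order: tuple[str, ...] = ("none", "cn_poor", "cn_rich")
                       ) -> RelapseByStratum:
    """Relapse proportion per burden stratum with pairwise tests.

    The primary pairwise p-value is a two-sided Welch t-test on the 0/1
    relapse indicators; Fisher's exact test on the 2x2 table is reported
    alongside as the natural exact test for binary proportions. Samples with
    missing relapse are dropped; empty strata are omitted and flagged.
    """
    df = pd.DataFrame({"relapse": relapse, "stratum": strata}).dropna(subset=["relapse"])
    rows, omitted = [], []
    groups: dict[str, np.ndarray] = {}
    for name in order:
        vals = df.loc[df["stratum"] == name, "relapse"].astype(float).to_numpy()
        if vals.size == 0:
            omitted.append(name)
            continue
        groups[name] = vals
        rows.append({"stratum": name, "n": vals.size,
                     "n_relapse": int(vals.sum()),
                     "proportion": float(vals.mean())})
    pw = []
    for a, b in combinations(groups, 2):
        va, vb = groups[a], groups[b]
        if np.ptp(np.concatenate([va, vb])) == 0:
            t_p = 1.0
        else:
            t_p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        table = [[int(va.sum()), int(va.size - va.sum())],
                 [int(vb.sum()), int(vb.size - vb.sum())]]
        fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        pw.append({"stratum_a": a, "stratum_b": b, "t_p": t_p, "fisher_p": fisher_p})
    return RelapseByStratum(pd.DataFrame(rows), pd.DataFrame(pw), tuple(omitted))


@dataclass
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_over: int
    n_under: int
    n_events: int


def cox_median_dichotomized(expr: pd.Series, times, events,
                            tie_under: bool = True) -> CoxResult:
    """Cox association between median-dichotomized expression and survival.

    Samples strictly above the within-cohort median are "over-expressed"
    (``tie_under=True`` sends median ties to the under-expressed group; with
    ``tie_under=False`` ties go over). The binary covariate is fit by Cox
    partial likelihood (Efron ties); HR, Wald 95% CI and p are reported for
    over- vs under-expressed.
    """
    x = np.asarray(expr, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if np.ptp(x) == 0:
        raise ValueError("degenerate expression vector: all values equal")
    med = float(np.median(x))
    over = x > med if tie_under else x >= med
    if over.sum() < 2 or (~over).sum() < 2:
        raise ValueError("median dichotomization leaves a group with <2 samples")
    if e.sum() == 0:
        raise ValueError("no events")
    df = pd.DataFrame({"time": t, "event": e.astype(int), "over": over.astype(int)})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["over"])
    se = float(cph.standard_errors_["over"])
    p = float(cph.summary.loc["over", "p"])
    z = stats.norm.ppf(0.975)
    return CoxResult(
        hazard_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        p_value=p,
        n_over=int(over.sum()), n_under=int((~over).sum()),
        n_events=int(e.sum()),
    )


def plot_km(records: pd.DataFrame, group_col: str, out_path,
            time_col: str = "survival_time", event_col: str = "event") -> None:
    """Write a Kaplan-Meier plot with one curve per group label."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, sub in records.groupby(group_col, sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], event_observed=sub[event_col].astype(bool),
                label=f"{name} (n={len(sub)})")
        kmf.plot_survival_function(ax=ax, ci_show=False)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
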