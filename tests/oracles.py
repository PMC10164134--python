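"""Independent reference implementations used only to verify the package.

Each oracle is coded from the definition of the quantity, without reusing
the package's code paths, so agreement is a genuine cross-check.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def brute_force_filter(call, th) -> set[str]:
    """Rule-by-rule somatic filter, written independently of the package.

    Returns the set of violated rule identifiers for one call.
    """
    bad = set()
    # tumor VAF at least the minimum and a clean matched normal
    if not (call.tumor_vaf >= th.tumor_vaf_min):
        bad.add("R1_vaf")
    if call.normal_alt > th.normal_alt_max:
        bad.add("R1_vaf")
    # both strands supported and strictly more than the alt-read floor
    total_alt = call.alt_fwd + call.alt_rev
    if not (call.alt_fwd >= th.min_alt_per_strand and
            call.alt_rev >= th.min_alt_per_strand and
            total_alt > th.min_alt_total):
        bad.add("R2_strand_reads")
    # site qualities
    if not (call.mapping_quality >= th.mapq_min and call.base_quality >= th.baseq_min):
        bad.add("R3_quality")
    # depth in both tissues
    if not (call.tumor_depth >= th.min_depth and call.normal_depth >= th.min_depth):
        bad.add("R4_depth")
    # population frequency: only an annotated common variant fails
    if call.pop_af is not None and call.pop_af > th.popaf_max:
        bad.add("R5_popaf")
    return bad


def product_limit(times, events):
    """Kaplan-Meier product-limit estimate coded directly from its definition.

    Returns (distinct_times, survival_after_each_time).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    distinct = np.unique(times)
    s = 1.0
    surv = []
    n_at_risk = len(times)
    for t in distinct:
        here = times == t
        d = int(events[here].sum())      # deaths at t
        if n_at_risk > 0 and d > 0:
            s *= 1.0 - d / n_at_risk
        surv.append(s)
        n_at_risk -= int(here.sum())     # deaths and censorings leave the risk set
    return distinct, np.array(surv)


def exact_mannwhitney_u_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of rank configurations per U value (no ties), by recursion.

    ``c[n1][u]`` counting extended over sample sizes: classic recurrence
    N(u; n1, n2) = N(u - n2; n1 - 1, n2) + N(u; n1, n2 - 1).
    """
    max_u = n1 * n2
    # dp[i][j][u] reduced to two dimensions over u with iterative build
    prev = [np.zeros(max_u + 1) for _ in range(n2 + 1)]
    for j in range(n2 + 1):
        prev[j][0] = 1.0  # n1 = 0
    for i in range(1, n1 + 1):
        cur = [np.zeros(max_u + 1) for _ in range(n2 + 1)]
        cur[0][0] = 1.0
        for j in range(1, n2 + 1):
            cur[j] = cur[j - 1].copy()
            shifted = np.zeros(max_u + 1)
            shifted[j:] = prev[j][:max_u + 1 - j]
            cur[j] += shifted
        prev = cur
    return prev[n2]


def exact_mannwhitney_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p-value by enumerating the U distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u = sum((xi > yj) for xi in x for yj in y)
    counts = exact_mannwhitney_u_counts(len(x), len(y))
    total = counts.sum()
    p_le = counts[: u + 1].sum() / total
    p_ge = counts[u:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def fisher_2x2_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for [[a, b], [c, d]] by hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


def percentile_linear(values, q: float) -> float:
    """Percentile with linear interpolation, coded from the definition."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 1:
        return float(v[0])
    h = (len(v) - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))


def permutation_exclusivity_p(cols: np.ndarray, n_perm: int, seed: int) -> float:
    """Re-implementation of the column-permutation co-occurrence test."""
    observed = int((cols.sum(axis=1) >= 2).sum())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        permuted = np.empty_like(cols)
        for j in range(cols.shape[1]):
            permuted[:, j] = rng.permutation(cols[:, j])
        if int((permuted.sum(axis=1) >= 2).sum()) <= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)
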