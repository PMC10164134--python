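"""Gene CN states, direction-aware burden, stratification and arm-level LOH."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wntgct.annotations import ArmDefinition, GeneAnnotation
from wntgct.cn_burden import (ArmLohCall, GeneCNState, Segment, SegmentProfile,
                              WntGeneSet, assign_gene_cn, call_arm_loh,
                              instability_control, loh_age_comparison, stratify,
                              threshold_sensitivity, wnt_burden_score)
from wntgct.config import CopyNumberOptions

ARM = ArmDefinition("chr1", "p", 0, 60_000_000)
ARMS = [ARM, ArmDefinition("chr1", "q", 60_000_000, 120_000_000)]


def gene(name="G1", chrom="chr1", start=10_000_000, end=10_100_000):
    return GeneAnnotation(name, chrom, start, end, "+", start - 1500, start + 500)


def profile(segs, sid="S1"):
    return SegmentProfile(sid, segs)


class TestAssignGeneCN:
    def test_focal_gain_inside_small_segment(self):
        p = profile([Segment("chr1", 0, 9_500_000, 0.0),
                     Segment("chr1", 9_500_000, 11_500_000, 0.8),   # 2 Mb on a 60 Mb arm
                     Segment("chr1", 11_500_000, 60_000_000, 0.0)])
        (state,) = assign_gene_cn(p, [gene()], arms=ARMS)
        assert state.state == "gain" and state.focal

    def test_whole_arm_loss_is_broad(self):
        p = profile([Segment("chr1", 0, 60_000_000, -0.5)])
        (state,) = assign_gene_cn(p, [gene()], arms=ARMS)
        assert state.state == "loss" and not state.focal

    def test_length_weighted_mean_across_straddled_segments(self):
        # 40% of the gene at +0.8, 60% at 0.0 -> weighted mean 0.32 >= 0.3 -> gain
        g = gene(start=10_000_000, end=10_100_000)
        p = profile([Segment("chr1", 0, 10_040_000, 0.8),
                     Segment("chr1", 10_040_000, 60_000_000, 0.0)])
        (state,) = assign_gene_cn(p, [g], arms=ARMS)
        assert state.weighted_log2 == pytest.approx(0.32)
        assert state.state == "gain"

    def test_uncovered_gene_is_neutral_and_flagged(self):
        p = profile([Segment("chr2", 0, 1_000_000, 0.8)])
        (state,) = assign_gene_cn(p, [gene()], arms=ARMS)
        assert state.state == "neutral" and state.uncovered

    def test_invariant_to_splitting_a_segment_into_abutting_halves(self):
        whole = profile([Segment("chr1", 9_000_000, 12_000_000, 0.8),
                         Segment("chr1", 12_000_000, 60_000_000, 0.0)])
        split = profile([Segment("chr1", 9_000_000, 10_050_000, 0.8),
                         Segment("chr1", 10_050_000, 12_000_000, 0.8),
                         Segment("chr1", 12_000_000, 60_000_000, 0.0)])
        a = assign_gene_cn(whole, [gene()], arms=ARMS)[0]
        b = assign_gene_cn(split, [gene()], arms=ARMS)[0]
        assert (a.state, a.focal) == (b.state, b.focal)
        assert a.weighted_log2 == pytest.approx(b.weighted_log2)

    def test_max_magnitude_aggregation_option(self):
        g = gene(start=10_000_000, end=10_100_000)
        p = profile([Segment("chr1", 0, 10_040_000, 0.8),
                     Segment("chr1", 10_040_000, 60_000_000, 0.0)])
        opts = CopyNumberOptions(aggregation="max_magnitude")
        (state,) = assign_gene_cn(p, [g], opts, arms=ARMS)
        assert state.weighted_log2 == pytest.approx(0.8)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            assign_gene_cn(profile([Segment("chr1", 0, 10, 0.0)]), [gene()],
                           CopyNumberOptions(gain_log2=-0.1), arms=ARMS)


GENESET = WntGeneSet({"FZD7": "activator", "LRP6": "activator",
                      "CTNNB1": "activator", "APC": "repressor",
                      "BTRC": "repressor"})


def state(gene, st_, focal=True, sid="S1"):
    return GeneCNState(sid, gene, st_, focal if st_ != "neutral" else False)


class TestBurdenScore:
    def test_all_neutral_scores_zero(self):
        states = [state(g, "neutral") for g in GENESET.role]
        assert wnt_burden_score(states, GENESET) == 0

    def test_direction_awareness(self):
        # activator gains and repressor loss count; activator loss does not
        states = [state("FZD7", "gain"), state("LRP6", "gain"),
                  state("APC", "loss"), state("CTNNB1", "loss")]
        assert wnt_burden_score(states, GENESET) == 3

    def test_wrong_direction_only_scores_zero(self):
        states = [state("FZD7", "loss"), state("APC", "gain")]
        assert wnt_burden_score(states, GENESET) == 0

    def test_broad_alterations_excluded_when_focal_only(self):
        states = [state("FZD7", "gain", focal=False)]
        assert wnt_burden_score(states, GENESET, focal_only=True) == 0
        assert wnt_burden_score(states, GENESET, focal_only=False) == 1

    def test_invariant_to_order_and_non_wnt_genes(self):
        states = [state("FZD7", "gain"), state("APC", "loss"),
                  state("GENE0001", "gain"), state("GENE0002", "loss")]
        assert wnt_burden_score(states, GENESET) == \
            wnt_burden_score(states[::-1], GENESET) == 2

    def test_additive_over_disjoint_subsets_and_bounded(self):
        a = [state("FZD7", "gain"), state("LRP6", "gain")]
        b = [state("APC", "loss")]
        total = wnt_burden_score(a + b, GENESET)
        assert total == wnt_burden_score(a, GENESET) + wnt_burden_score(b, GENESET)
        assert total <= len(GENESET)

    def test_mixed_sample_states_rejected(self):
        with pytest.raises(ValueError):
            wnt_burden_score([state("FZD7", "gain", sid="S1"),
                              state("APC", "loss", sid="S2")], GENESET)

    def test_direction_flip_symmetry(self):
        """Swapping every role and flipping every alteration keeps the score."""
        states = [state("FZD7", "gain"), state("LRP6", "loss"),
                  state("APC", "loss"), state("BTRC", "gain")]
        flipped_set = WntGeneSet({g: ("repressor" if r == "activator" else "activator")
                                  for g, r in GENESET.role.items()})
        flip = {"gain": "loss", "loss": "gain"}
        flipped_states = [state(s.gene, flip[s.state]) for s in states]
        assert wnt_burden_score(states, GENESET) == \
            wnt_burden_score(flipped_states, flipped_set)


@pytest.mark.parametrize("t", [3, 5, 7, 9])
def test_stratify_boundaries_exact(t):
    assert stratify(0, t) == "none"
    assert stratify(1, t) == "cn_poor"
    assert stratify(t, t) == "cn_poor"
    assert stratify(t + 1, t) == "cn_rich"


def test_stratify_rejects_bad_input():
    with pytest.raises(ValueError):
        stratify(-1, 5)
    with pytest.raises(ValueError):
        stratify(2, 0)


@settings(max_examples=50, derandomize=True)
@given(score=st.integers(0, 20), t=st.integers(1, 10))
def test_stratify_consistency_property(score, t):
    s = stratify(score, t)
    assert s == ("none" if score == 0 else "cn_poor" if score <= t else "cn_rich")


class TestThresholdSensitivity:
    @staticmethod
    def _outcomes(n, rng):
        return pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "relapse": rng.random(n) < 0.2,
            "survival_time": rng.exponential(50, n).round(2) + 0.1,
            "event": rng.random(n) < 0.5,
        })

    def test_cn_rich_size_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        scores = pd.Series(rng.integers(0, 12, size=60),
                           index=[f"S{i}" for i in range(60)])
        out = threshold_sensitivity(scores, self._outcomes(60, rng), (3, 5, 7, 9))
        assert list(out["threshold"]) == [3, 5, 7, 9]
        assert (out["n_cn_rich"].diff().dropna() <= 0).all()

    def test_all_zero_scores_flagged(self):
        rng = np.random.default_rng(6)
        scores = pd.Series(0, index=[f"S{i}" for i in range(20)])
        out = threshold_sensitivity(scores, self._outcomes(20, rng), (3, 5))
        assert out["flagged"].all()
        assert out["logrank_p_rich_vs_none"].isna().all()


class TestInstabilityControl:
    def test_identical_profiles_give_zero_difference(self):
        states = {f"S{i}": [state("GENE0001", "gain", sid=f"S{i}"),
                            state("GENE0002", "loss", sid=f"S{i}")]
                  for i in range(8)}
        strata = {f"S{i}": ("cn_rich" if i < 4 else "cn_poor") for i in range(8)}
        res = instability_control(states, strata)
        assert res.difference == 0.0
        assert res.p_value == 1.0

    def test_small_group_rejected(self):
        states = {"S1": [], "S2": [], "S3": []}
        strata = {"S1": "cn_rich", "S2": "cn_poor", "S3": "cn_poor"}
        with pytest.raises(ValueError):
            instability_control(states, strata)

    @staticmethod
    def _replicate(rng, n_per_group, bg_mean_rich, bg_mean_poor,
                   wnt_rich=8, wnt_poor=3, shape=3.0):
        """Count-level emulation of the generator: planted WNT delta plus
        overdispersed (gamma-Poisson) background alteration counts."""
        states, strata = {}, {}
        for grp, bg_mean, wnt in (("cn_rich", bg_mean_rich, wnt_rich),
                                  ("cn_poor", bg_mean_poor, wnt_poor)):
            for i in range(n_per_group):
                sid = f"{grp}{i}"
                n_bg = int(rng.poisson(rng.gamma(shape, bg_mean / shape)))
                sts = [state(f"BG{j}", "gain" if j % 2 else "loss", sid=sid)
                       for j in range(n_bg)]
                sts += [state(f"WNT{j}", "gain", sid=sid) for j in range(wnt)]
                states[sid] = sts
                strata[sid] = grp
        return states, strata

    def test_equal_background_rate_is_usually_non_significant(self):
        """With equal background instability the planted WNT delta alone
        should not trip the genome-wide count control."""
        rng = np.random.default_rng(77)
        n_rep = 400
        non_sig = sum(
            instability_control(*self._replicate(rng, 38, 100, 100)).p_value >= 0.05
            for _ in range(n_rep))
        assert non_sig / n_rep >= 0.90

    def test_doubled_background_rate_is_detected(self):
        rng = np.random.default_rng(78)
        sig = sum(
            instability_control(*self._replicate(rng, 38, 200, 100)).p_value < 0.05
            for _ in range(100))
        assert sig >= 90


class TestArmLoh:
    def test_threshold_application(self):
        # LOH over 90% of the p arm
        p = profile([Segment("chr1", 0, 54_000_000, 0.0, loh=True),
                     Segment("chr1", 54_000_000, 120_000_000, 0.0, loh=False)])
        calls = {c.arm: c for c in call_arm_loh(p, ARMS, 0.7)}
        assert calls["chr1p"].loh
        assert not calls["chr1q"].loh

    def test_half_coverage_below_threshold(self):
        p = profile([Segment("chr1", 0, 30_000_000, 0.0, loh=True),
                     Segment("chr1", 30_000_000, 120_000_000, 0.0, loh=False)])
        calls = {c.arm: c for c in call_arm_loh(p, ARMS, 0.7)}
        assert not calls["chr1p"].loh

    def test_fragmented_coverage_summing_to_threshold_is_inclusive(self):
        # two LOH fragments summing to exactly 0.7 * 60 Mb
        p = profile([Segment("chr1", 0, 20_000_000, 0.0, loh=True),
                     Segment("chr1", 20_000_000, 30_000_000, 0.0, loh=False),
                     Segment("chr1", 30_000_000, 52_000_000, 0.0, loh=True),
                     Segment("chr1", 52_000_000, 120_000_000, 0.0, loh=False)])
        calls = {c.arm: c for c in call_arm_loh(p, ARMS, 0.7)}
        assert calls["chr1p"].covered_fraction == pytest.approx(0.7)
        assert calls["chr1p"].loh

    def test_uncovered_arm_flagged_false(self):
        p = profile([Segment("chr1", 0, 60_000_000, 0.0, loh=True)])
        calls = {c.arm: c for c in call_arm_loh(p, ARMS, 0.7)}
        assert calls["chr1q"].uncovered and not calls["chr1q"].loh


class TestLohAgeComparison:
    @staticmethod
    def _calls(n_loh):
        return [ArmLohCall(f"a{i}", i < n_loh, 1.0, False) for i in range(20)]

    def test_identical_zero_counts_give_p_one(self):
        calls = {f"S{i}": self._calls(0) for i in range(10)}
        ages = {f"S{i}": (2.0 if i < 5 else 15.0) for i in range(10)}
        res = loh_age_comparison(calls, ages)
        assert res.p_value == 1.0

    def test_age_exactly_at_cut_goes_to_older_group(self):
        calls = {"A": self._calls(0), "B": self._calls(5), "C": self._calls(5)}
        ages = {"A": 2.0, "B": 6.0, "C": 10.0}
        res = loh_age_comparison(calls, ages, age_cut=6.0)
        assert len(res.counts_younger) == 1 and len(res.counts_older) == 2

    def test_empty_group_raises(self):
        calls = {"A": self._calls(1)}
        with pytest.raises(ValueError):
            loh_age_comparison(calls, {"A": 2.0})
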