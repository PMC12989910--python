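"""Arm-level means, calls, concordance and correlation."""

import numpy as np
import pandas as pd
import pytest

from offtarget_cnv.arms import (
    arm_fraction_events,
    arm_weighted_means,
    cohort_summary,
    correlate_profiles,
    per_sample_concordance,
)
from offtarget_cnv.config import AnalysisConfig
from offtarget_cnv.genome import arm_by_name, comparable_arms
from offtarget_cnv.simulate import TruthProfile, expected_ratio_bins, array_bins, SimParams


def _profile(rows):
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "log2"])


class TestArmWeightedMeans:
    def test_weighted_mean_arithmetic(self):
        # 1 Mb at 1.0 and 3 Mb at 0.0 on 1p -> mean 0.25, neutral
        prof = _profile(
            [("chr1", 0, 1_000_000, 1.0), ("chr1", 1_000_000, 4_000_000, 0.0)]
        )
        out = arm_weighted_means(prof)
        row = out[out["arm"] == "1p"].iloc[0]
        assert row["mean_log2"] == pytest.approx(0.25)
        assert row["call"] == "neutral"

    def test_threshold_boundary_is_inclusive(self):
        prof = _profile([("chr1", 0, 1_000_000, 0.5)])
        out = arm_weighted_means(prof)
        assert out[out["arm"] == "1p"].iloc[0]["call"] == "gain"
        prof = _profile([("chr1", 0, 1_000_000, -0.5)])
        out = arm_weighted_means(prof)
        assert out[out["arm"] == "1p"].iloc[0]["call"] == "loss"

    def test_matches_summation_oracle(self, rng):
        rows = []
        for arm in comparable_arms():
            starts = arm.span.start + np.sort(
                rng.choice(arm.length - 1000, size=50, replace=False)
            )
            for s in starts:
                rows.append((arm.chrom, int(s), int(s) + 1000, float(rng.normal())))
        prof = _profile(rows)
        out = arm_weighted_means(prof)
        for arm in comparable_arms():
            sub = [r for r in rows if r[0] == arm.chrom
                   and r[1] >= arm.span.start and r[2] <= arm.span.end]
            oracle = sum((e - s) * v for _, s, e, v in sub) / sum(e - s for _, s, e, v in sub)
            got = out.loc[out["arm"] == arm.name, "mean_log2"].iloc[0]
            assert got == pytest.approx(oracle, abs=1e-9)

    def test_centromere_straddling_bin_splits_pro_rata(self):
        arm_p = arm_by_name("1p")
        cen = arm_p.span.end
        # one bin exactly centred on the centromere
        prof = _profile([("chr1", cen - 1000, cen + 1000, 1.0),
                         ("chr1", 0, 1000, 0.0),
                         ("chr1", cen + 2000, cen + 3000, 0.0)])
        out = arm_weighted_means(prof)
        p = out[out["arm"] == "1p"].iloc[0]["mean_log2"]
        q = out[out["arm"] == "1q"].iloc[0]["mean_log2"]
        assert p == pytest.approx(0.5)  # 1000 bp at 1.0, 1000 bp at 0.0
        assert q == pytest.approx(0.5)

    def test_threshold_monotonicity(self, rng):
        rows = []
        for arm in comparable_arms():
            rows.append((arm.chrom, arm.span.start, arm.span.end, float(rng.normal(0, 0.6))))
        prof = _profile(rows)
        n_calls = []
        for thr in (0.3, 0.5, 0.8, 1.2):
            out = arm_weighted_means(prof, config=AnalysisConfig(arm_call_threshold=thr))
            n_calls.append(int((out["call"] != "neutral").sum()))
        assert all(b <= a for a, b in zip(n_calls, n_calls[1:]))

    def test_empty_profile_is_fatal(self):
        with pytest.raises(ValueError, match="empty"):
            arm_weighted_means(_profile([]))

    def test_purity_attenuation_flips_call_at_threshold(self):
        """Noise-free single-copy events flip to neutral exactly when the
        attenuated mixture crosses +-0.5."""
        arm = arm_by_name("2q")
        bins = array_bins(SimParams())
        for cn, sign in ((3, 1), (1, -1)):
            for purity in np.linspace(0.3, 0.95, 14):
                truth = TruthProfile("S", "x", float(purity), 5.0, ((arm.span, cn),))
                ratio = expected_ratio_bins(
                    truth,
                    bins["chromosome"].to_numpy(),
                    bins["start"].to_numpy(),
                    bins["end"].to_numpy(),
                )
                prof = bins[["chromosome", "start", "end"]].copy()
                prof["log2"] = np.log2(ratio)
                out = arm_weighted_means(prof)
                call = out[out["arm"] == "2q"].iloc[0]["call"]
                mixture = np.log2(purity * cn / 2 + 1 - purity)
                expected = (
                    ("gain" if sign > 0 else "loss")
                    if abs(mixture) >= 0.5
                    else "neutral"
                )
                assert call == expected


class TestArmFractionEvents:
    def test_coverage_rule(self):
        arm = arm_by_name("4p")
        span = arm.length
        seg = pd.DataFrame(
            {
                "chromosome": ["chr4", "chr4"],
                "start": [arm.span.start, arm.span.start],
                "end": [arm.span.start + int(0.6 * span), arm.span.start],
                "num_bins": [10, 10],
                "seg_mean": [0.6, 0.0],
                "weight": [1.0, 1.0],
            }
        ).iloc[:1]
        out = arm_fraction_events(seg)
        assert out[out["arm"] == "4p"].iloc[0]["gained"]

    def test_focal_high_segment_is_not_an_arm_event(self):
        arm = arm_by_name("4p")
        seg = pd.DataFrame(
            {
                "chromosome": ["chr4"],
                "start": [arm.span.start],
                "end": [arm.span.start + int(0.4 * arm.length)],
                "num_bins": [10],
                "seg_mean": [2.0],
                "weight": [1.0],
            }
        )
        out = arm_fraction_events(seg)
        row = out[out["arm"] == "4p"].iloc[0]
        assert not row["gained"] and not row["lost"]

    def test_matches_coverage_summation_oracle(self, rng):
        cfg = AnalysisConfig()
        rows = []
        for arm in comparable_arms()[:10]:
            cursor = arm.span.start
            while cursor < arm.span.end:
                length = int(rng.uniform(0.05, 0.3) * arm.length)
                end = min(cursor + length, arm.span.end)
                rows.append((arm.chrom, cursor, end, 1, float(rng.normal(0, 0.7)), 1.0))
                cursor = end
        seg = pd.DataFrame(
            rows, columns=["chromosome", "start", "end", "num_bins", "seg_mean", "weight"]
        )
        out = arm_fraction_events(seg, config=cfg)
        for arm in comparable_arms()[:10]:
            sub = [r for r in rows if r[0] == arm.chrom
                   and r[1] < arm.span.end and r[2] > arm.span.start]
            gain_cov = sum(
                min(e, arm.span.end) - max(s, arm.span.start)
                for _, s, e, _, m, _ in sub
                if m >= cfg.seg_class_threshold
            )
            loss_cov = sum(
                min(e, arm.span.end) - max(s, arm.span.start)
                for _, s, e, _, m, _ in sub
                if m <= -cfg.seg_class_threshold
            )
            row = out[out["arm"] == arm.name].iloc[0]
            assert row["gained"] == (gain_cov / arm.length >= 0.5)
            assert row["lost"] == (loss_cov / arm.length >= 0.5)


def _arm_calls(calls):
    arms = [a.name for a in comparable_arms()]
    return pd.DataFrame(
        {
            "arm": arms,
            "chromosome": [a.chrom for a in comparable_arms()],
            "mean_log2": 0.0,
            "n_bins": 10,
            "call": [calls.get(a, "neutral") for a in arms],
        }
    )


class TestConcordance:
    def test_identical_profiles_give_one(self):
        a = _arm_calls({"1p": "loss", "19q": "loss"})
        res = per_sample_concordance(a, a)
        assert res.concordance == 1.0 and res.n_arms == 39

    def test_single_discordant_arm(self):
        a = _arm_calls({"1p": "loss"})
        b = _arm_calls({})
        res = per_sample_concordance(a, b)
        assert res.concordance == pytest.approx(38 / 39)
        assert res.discordant_arms == ("1p",)

    def test_symmetry(self, rng):
        calls = ["gain", "loss", "neutral"]
        a = _arm_calls({f"{i}q": rng.choice(calls) for i in range(1, 13)})
        b = _arm_calls({f"{i}q": rng.choice(calls) for i in range(1, 13)})
        assert (
            per_sample_concordance(a, b).concordance
            == per_sample_concordance(b, a).concordance
        )


class TestCorrelation:
    def test_self_correlation_is_one(self, rng):
        bins = array_bins(SimParams())
        prof = bins[["chromosome", "start", "end"]].copy()
        prof["log2"] = rng.normal(0, 0.3, len(bins))
        out = correlate_profiles(prof, prof)
        genome = out[out["scope"] == "genome"].iloc[0]
        assert genome["r"] == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, rng):
        bins = array_bins(SimParams())
        prof = bins[["chromosome", "start", "end"]].copy()
        prof["log2"] = rng.normal(0, 0.3, len(bins))
        neg = prof.copy()
        neg["log2"] = -neg["log2"]
        out = correlate_profiles(prof, neg)
        assert out[out["scope"] == "genome"].iloc[0]["r"] == pytest.approx(-1.0)

    def test_too_few_pairs_not_computable(self):
        prof = _profile([("chr1", 0, 1000, 0.1), ("chr1", 1000, 2000, 0.2)])
        out = correlate_profiles(prof, prof)
        assert np.isnan(out[out["scope"] == "1p"].iloc[0]["r"])


class TestCohortSummary:
    def test_flat_sample_has_no_events(self):
        profiles = {"S1": _arm_calls({})}
        out = cohort_summary(profiles)
        assert out.iloc[0]["n_gain"] == 0 and out.iloc[0]["n_loss"] == 0

    def test_counts(self):
        profiles = {
            "S1": _arm_calls({"1q": "gain", "2q": "gain", "3q": "gain",
                              "4q": "loss", "5q": "loss"})
        }
        out = cohort_summary(profiles)
        assert out.iloc[0]["n_gain"] == 3 and out.iloc[0]["n_loss"] == 2
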