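"""Synthetic cohort generator: scenario composition, purity mixture model,
distributional properties of the simulated platforms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from offtarget_cnv.coverage import count_reads_in_bins
from offtarget_cnv.genome import GenomicInterval, arm_by_name
from offtarget_cnv.simulate import (
    EventCollisionError,
    SamplePrescription,
    CohortSpec,
    FocalPrescription,
    SimParams,
    TruthProfile,
    expected_log2,
    make_cohort_spec,
    sample_truth,
    simulate_array_profile,
    simulate_ngs_counts,
    simulate_reads,
    truth_frame,
)


class TestCohortSpecs:
    def test_evaluation60_composition(self):
        spec = make_cohort_spec("evaluation60")
        assert len(spec.samples) == 60
        entities = pd.Series([s.entity for s in spec.samples]).value_counts()
        assert entities["glioblastoma"] == 25
        assert entities["oligodendroglioma"] == 15
        assert entities["ependymoma"] + entities["spinal_ependymoma"] == 9
        assert entities["medulloblastoma"] == 6
        assert entities["choroid_plexus"] == 5

    def test_evaluation60_focal_amplification_table(self):
        spec = make_cohort_spec("evaluation60")
        amps = [
            f.gene
            for s in spec.samples
            for f in s.focal_events
            if f.kind == "amplification"
        ]
        counts = pd.Series(amps).value_counts()
        assert counts["EGFR"] == 10
        assert counts["MDM4"] == 4
        assert counts["FGFR3"] == counts["TERT"] == 1
        assert counts["MYCN"] == 1
        assert counts["PDGFRA"] == 2  # one glioblastoma + one oligodendroglioma
        assert len(amps) == 19
        homdels = [
            (s.entity, f.gene)
            for s in spec.samples
            for f in s.focal_events
            if f.kind == "homozygous_deletion"
        ]
        assert sum(1 for e, g in homdels if e == "glioblastoma" and g == "CDKN2A") == 17
        assert ("glioblastoma", "PTEN") in homdels
        assert ("oligodendroglioma", "CDKN2A") in homdels

    def test_meningioma58_alteration_table(self):
        spec = make_cohort_spec("meningioma58")
        assert len(spec.samples) == 58
        grades = pd.Series([s.histological_grade for s in spec.samples]).value_counts()
        assert grades[1] == 37 and grades[2] == 20 and grades[3] == 1
        has_1p22q = [
            s
            for s in spec.samples
            if {("1p", "loss"), ("22q", "loss")} <= set(s.arm_events)
        ]
        assert sum(1 for s in has_1p22q if s.histological_grade == 1) == 8
        assert sum(1 for s in has_1p22q if s.histological_grade == 2) == 16

    def test_pilocytic6_has_one_whole_chr7_gain(self):
        spec = make_cohort_spec("pilocytic6")
        assert len(spec.samples) == 6
        whole7 = [
            s
            for s in spec.samples
            if set(s.arm_events) == {("7p", "gain"), ("7q", "gain")}
        ]
        assert len(whole7) == 1 and not whole7[0].focal_events

    def test_unknown_scenario_is_fatal(self):
        with pytest.raises(ValueError):
            make_cohort_spec("nope")


class TestTruthRealisation:
    def test_cohort_mean_purity_matches_study(self):
        spec = make_cohort_spec("evaluation60")
        means = []
        for seed in range(10):
            truths = sample_truth(spec, np.random.default_rng(seed))
            means.append(np.mean([t.purity for t in truths]))
        assert abs(np.mean(means) - 0.72) < 0.05
        all_p = [
            t.purity
            for seed in range(3)
            for t in sample_truth(spec, np.random.default_rng(seed))
        ]
        assert min(all_p) >= 0.20 and max(all_p) <= 0.95

    def test_prescribed_arms_realised_as_single_copy_events(self, rng):
        spec = CohortSpec(
            "custom",
            (
                SamplePrescription(
                    "S1", "glioblastoma",
                    arm_events=(("7p", "gain"), ("7q", "gain"),
                                ("10p", "loss"), ("10q", "loss")),
                ),
            ),
        )
        truth = sample_truth(spec, rng)[0]
        by_span = {str(iv): cn for iv, cn in truth.events}
        for arm_name, cn in [("7p", 3), ("7q", 3), ("10p", 1), ("10q", 1)]:
            arm = arm_by_name(arm_name)
            assert by_span[str(arm.span)] == cn

    def test_overlapping_prescriptions_collide(self, rng):
        spec = CohortSpec(
            "custom",
            (
                SamplePrescription(
                    "S1", "x",
                    focal_events=(
                        FocalPrescription("CDKN2A", "homozygous_deletion"),
                        FocalPrescription("CDKN2B", "homozygous_deletion"),
                    ),
                ),
            ),
        )
        with pytest.raises(EventCollisionError):
            sample_truth(spec, rng)

    def test_same_seed_reproduces_truth_tables(self):
        spec = make_cohort_spec("evaluation60")
        a = truth_frame(sample_truth(spec, np.random.default_rng(7)))
        b = truth_frame(sample_truth(spec, np.random.default_rng(7)))
        pd.testing.assert_frame_equal(a, b)


class TestExpectedLog2:
    @pytest.mark.parametrize(
        "purity,cn,expected",
        [(1.0, 4, 1.0), (1.0, 2, 0.0), (0.72, 3, np.log2(1.36))],
    )
    def test_mixture_values(self, purity, cn, expected):
        iv = GenomicInterval("chr1", 0, 1000)
        truth = TruthProfile("S", "x", purity, 5.0, ((iv, cn),))
        assert expected_log2(truth, iv) == pytest.approx(expected, abs=1e-9)

    def test_zero_mixture_is_floored(self):
        iv = GenomicInterval("chr1", 0, 1000)
        truth = TruthProfile("S", "x", 1.0, 5.0, ((iv, 0),))
        assert expected_log2(truth, iv) == -8.0

    def test_breakpoint_spanning_interval_is_fatal(self):
        truth = TruthProfile(
            "S", "x", 0.8, 5.0, ((GenomicInterval("chr1", 0, 1000), 3),)
        )
        with pytest.raises(ValueError, match="breakpoint"):
            expected_log2(truth, GenomicInterval("chr1", 500, 1500))

    def test_purity_monotonicity(self):
        iv = GenomicInterval("chr1", 0, 1000)
        purities = np.linspace(0.1, 1.0, 10)
        gains = [
            expected_log2(TruthProfile("S", "x", p, 5.0, ((iv, 3),)), iv)
            for p in purities
        ]
        losses = [
            expected_log2(TruthProfile("S", "x", p, 5.0, ((iv, 1),)), iv)
            for p in purities
        ]
        assert np.all(np.diff(gains) > 0)
        assert np.all(np.diff(losses) < 0)


def _flat_truth(purity=1.0, din=5.0):
    return TruthProfile("S", "x", purity, din, ())


class TestNgsSimulator:
    def test_flat_counts_are_poisson_by_length(self, toy_bins):
        params = SimParams(gc_strength=0.0, library_log_sd=0.0,
                           offtarget_noise_sd=0.0, total_reads_median=50_000_000)
        cov = simulate_ngs_counts(_flat_truth(), toy_bins, params, np.random.default_rng(3))
        anti = (toy_bins["bin_type"] == "antitarget").to_numpy()
        counts = cov.count[anti]
        length = (toy_bins["end"] - toy_bins["start"]).to_numpy()[anti]
        expected = counts.sum() * length / length.sum()
        # chi-square goodness of fit against the length-proportional model
        chi2 = ((counts - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=len(counts) - 1)
        assert p > 0.01

    def test_doubling_reads_doubles_mean_counts(self, toy_bins):
        params1 = SimParams(library_log_sd=0.0)
        params2 = SimParams(library_log_sd=0.0, read_scale=params1.read_scale * 2)
        m = []
        for params in (params1, params2):
            rng = np.random.default_rng(11)
            tot = [
                simulate_ngs_counts(_flat_truth(din=5), toy_bins, params, rng).count.sum()
                for _ in range(40)
            ]
            m.append(np.mean(tot))
        assert m[1] / m[0] == pytest.approx(2.0, rel=0.05)

    def test_din_anticorrelates_with_offtarget_reads(self, toy_bins):
        params = SimParams()
        rng = np.random.default_rng(5)
        dins, off = [], []
        for _ in range(60):
            din = float(rng.uniform(2, 8))
            cov = simulate_ngs_counts(_flat_truth(din=din), toy_bins, params, rng)
            dins.append(din)
            off.append(cov.totals(toy_bins)[2])
        r = stats.pearsonr(dins, off)[0]
        assert r < 0


class TestReadSimulator:
    def test_reads_stay_in_bounds_and_are_conserved(self, toy_bins, toy_genome, rng):
        reads = simulate_reads(_flat_truth(), toy_bins, SimParams(), rng, 1000)
        assert len(reads) == 1000
        for chrom, grp in reads.groupby("chromosome"):
            assert grp["start"].between(0, toy_genome[chrom] - 1).all()
        cov = count_reads_in_bins(reads, toy_bins)
        assert cov.count.sum() + cov.unassigned_reads == 1000
        assert cov.unassigned_reads == 0  # placements always start inside a bin

    def test_seed_determinism(self, toy_bins):
        a = simulate_reads(_flat_truth(), toy_bins, SimParams(), np.random.default_rng(9), 500)
        b = simulate_reads(_flat_truth(), toy_bins, SimParams(), np.random.default_rng(9), 500)
        pd.testing.assert_frame_equal(a, b)

    def test_desk_scale_guard(self, toy_bins, rng):
        with pytest.raises(ValueError, match="capped"):
            simulate_reads(_flat_truth(), toy_bins, SimParams(), rng, 2_000_000)


class TestArraySimulator:
    def test_flat_noise_free_profile_is_zero(self, rng):
        params = SimParams(array_noise_sd=0.0, array_arm_wave_sd=0.0)
        prof = simulate_array_profile(_flat_truth(), params, rng)
        assert np.allclose(prof["log2"], 0.0)

    def test_whole_arm_gain_mean_matches_mixture(self):
        arm = arm_by_name("2p")
        truth = TruthProfile("S", "x", 0.72, 5.0, ((arm.span, 3),))
        params = SimParams()
        prof = simulate_array_profile(truth, params, np.random.default_rng(21))
        sel = (prof["chromosome"] == "chr2") & (prof["end"] <= arm.span.end)
        got = prof.loc[sel, "log2"].mean()
        # ~930 bins: bin noise averages out, the arm wave (sd 0.05) dominates
        assert got == pytest.approx(np.log2(1.36), abs=3 * 0.05)

    def test_seed_determinism(self):
        truth = _flat_truth()
        a = simulate_array_profile(truth, SimParams(), np.random.default_rng(2))
        b = simulate_array_profile(truth, SimParams(), np.random.default_rng(2))
        c = simulate_array_profile(truth, SimParams(), np.random.default_rng(3))
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a["log2"], c["log2"])
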