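"""End-to-end study workflows shared by the CLI, the test-suite and the
reproduction script.

Each function runs the full chain on a synthetic cohort: truth ->
simulated coverage -> normalisation + pooled flat reference -> ratio
profile -> (segmentation ->) arm calls / focal events / rule engines.
Problem sizes are desk-scale: libraries are a few-percent read-count
replica of the study's sequencing depth, which preserves arm-level and
high-amplitude focal precision while keeping runtimes in minutes (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arms import arm_weighted_means, per_sample_concordance
from .config import AnalysisConfig
from .coverage import CoverageProfile, annotate_gc_simulated, build_bins
from .focal import call_focal_events
from .genome import CHROM_LENGTHS, gene_table
from .normalize import Reference, RatioProfile, build_reference, normalize_sample, to_ratio_profile
from .rules import (
    MeningiomaProfile,
    braf_fusion_indicator,
    count_upgrades,
    integrate_meningioma_grade,
)
from .segment import segment_cbs
from .simulate import (
    CohortSpec,
    SimParams,
    flat_truth,
    make_cohort_spec,
    sample_truth,
    simulate_array_profile,
    simulate_ngs_counts,
)
from .tables import read_bed

__all__ = [
    "default_panel",
    "build_study_bins",
    "pooled_flat_reference",
    "SampleCall",
    "call_sample",
    "concordance_study",
    "focal_recovery_study",
    "meningioma_profiles_from_spec",
    "meningioma_upgrade_study",
    "pilocytic_indicator_study",
]

N_REFERENCE_SAMPLES = 8


def default_panel():
    """The packaged 31-gene capture design (synthetic, hg19)."""
    from importlib import resources

    path = resources.files("offtarget_cnv") / "data" / "panel_hg19.bed"
    return read_bed(path)


def build_study_bins(
    config: AnalysisConfig | None = None,
    gc_seed: int = 7,
    genome: dict[str, int] | None = None,
) -> pd.DataFrame:
    """hg19 target/antitarget bins with simulated GC annotation."""
    config = config or AnalysisConfig()
    genome = CHROM_LENGTHS if genome is None else genome
    panel = [(iv, label) for iv, label in default_panel() if iv.chrom in genome]
    bins = build_bins(genome, panel, config)
    return annotate_gc_simulated(bins, np.random.default_rng(gc_seed))


def pooled_flat_reference(
    bins: pd.DataFrame,
    params: SimParams,
    config: AnalysisConfig,
    rng: np.random.Generator,
    n_samples: int = N_REFERENCE_SAMPLES,
) -> Reference:
    """Simulate flat-profile samples and pool them into a reference."""
    norms, counts = [], []
    for i in range(n_samples):
        cov = simulate_ngs_counts(flat_truth(f"FLAT_{i + 1}", rng), bins, params, rng)
        norms.append(normalize_sample(cov, bins, config))
        counts.append(cov.count)
    return build_reference(norms, counts, bins, config)


@dataclass
class SampleCall:
    """Everything the pipeline derives for one sample."""

    ratio: RatioProfile
    arm_profile: pd.DataFrame
    segments: pd.DataFrame | None = None
    focal_events: pd.DataFrame | None = None
    arm_baselines: dict[str, float] = field(default_factory=dict)


def call_sample(
    coverage: CoverageProfile,
    reference: Reference,
    bins: pd.DataFrame,
    config: AnalysisConfig,
    segment: bool = True,
    purity: float | None = None,
) -> SampleCall:
    """Normalise, reference-correct and (optionally) segment one sample.

    Tumour profiles are not GC-corrected individually (the pooled
    reference cancels the design-shared GC bias; per-sample rolling
    medians would erode signal in aneuploid genomes, see docs/methods.md).
    """
    norm = normalize_sample(coverage, bins, config, gc_correct=False)
    ratio = to_ratio_profile(
        norm, reference, bins, config,
        sample_id=coverage.sample_id, depth=coverage.depth(bins),
    )
    frame = ratio.frame()
    arm_profile = arm_weighted_means(frame, config=config)
    all_arms = arm_weighted_means(frame, config=config, comparable_only=False)
    baselines = dict(zip(all_arms["arm"], all_arms["mean_log2"]))
    result = SampleCall(ratio, arm_profile, arm_baselines=baselines)
    if segment:
        result.segments = segment_cbs(ratio, config)
        result.focal_events = call_focal_events(
            result.segments, baselines, gene_table(), config, purity=purity
        )
    return result


# ---------------------------------------------------------------------------
# studies


def concordance_study(
    seed: int,
    n_seeds: int = 10,
    scenario: str = "evaluation60",
    params: SimParams | None = None,
    config: AnalysisConfig | None = None,
) -> dict:
    """Cross-platform arm-call concordance on paired synthetic cohorts.

    For each seed: simulate the cohort's truth once, derive NGS bin
    counts (with a fresh pooled flat reference) and array bin profiles
    from that shared truth, classify the 39 comparable arms at +-0.5 on
    both sides, and average per-sample concordance.
    """
    params = params or SimParams()
    config = config or AnalysisConfig()
    spec = make_cohort_spec(scenario)
    bins = build_study_bins(config, gc_seed=seed + 1)
    per_sample: list[float] = []
    per_seed: list[float] = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 1000 * (s + 1))
        truths = sample_truth(spec, rng)
        reference = pooled_flat_reference(bins, params, config, rng)
        seed_vals = []
        for truth in truths:
            cov = simulate_ngs_counts(truth, bins, params, rng)
            call = call_sample(cov, reference, bins, config, segment=False)
            array = simulate_array_profile(truth, params, rng)
            arm_array = arm_weighted_means(array, config=config)
            res = per_sample_concordance(call.arm_profile, arm_array, truth.sample_id)
            if res is not None:
                seed_vals.append(res.concordance)
        per_sample.extend(seed_vals)
        per_seed.append(float(np.mean(seed_vals)))
    return {
        "mean_concordance": float(np.mean(per_sample)),
        "per_seed": per_seed,
        "n_samples": len(spec.samples),
        "n_seeds": n_seeds,
    }


def cohort_expected_recovery_study(
    seed: int,
    params: SimParams | None = None,
    config: AnalysisConfig | None = None,
    purity: float | None = 1.0,
) -> dict:
    """Called arm events versus the attenuation-aware truth expectation.

    Purity attenuates single-copy events towards zero, so the recoverable
    event count is the number of arms whose noise-free mixture log2
    crosses the +-0.5 threshold (computed from each sample's truth
    profile), not the number of implanted events.  By default purities
    are pinned to 1.0, which puts every implanted single-copy event at
    +-0.585/-1.0 -- clear of the threshold, so the expectation equals the
    implanted count and recovery is a sharp test.  At cohort purities the
    comparison is dominated by threshold-edge arms, where the pipeline's
    small negative bias at desk-scale counts deflates gain calls (see
    docs/methods.md).
    """
    import dataclasses

    from .normalize import weighted_median

    params = params or SimParams(read_scale=0.1)
    oracle_params = SimParams(array_noise_sd=0.0, array_arm_wave_sd=0.0)
    config = config or AnalysisConfig()
    spec = make_cohort_spec("evaluation60")
    if purity is not None:
        spec = CohortSpec(
            spec.name,
            tuple(dataclasses.replace(s, purity=purity) for s in spec.samples),
        )
    bins = build_study_bins(config, gc_seed=seed + 1)
    rng = np.random.default_rng(seed + 40_000)
    truths = sample_truth(spec, rng)
    reference = pooled_flat_reference(bins, params, config, rng)
    n_called = 0
    n_expected = 0
    for truth in truths:
        cov = simulate_ngs_counts(truth, bins, params, rng)
        call = call_sample(cov, reference, bins, config, segment=False)
        n_called += int((call.arm_profile["call"] != "neutral").sum())
        # noise-free oracle on the same classification rule, including the
        # pipeline's convention of centring on the sample's weighted median
        # (depth-based profiles are relative; heavily aneuploid genomes
        # shift their own baseline)
        noisefree = simulate_array_profile(truth, oracle_params, np.random.default_rng(0))
        length = (noisefree["end"] - noisefree["start"]).to_numpy().astype(float)
        autosomal = ~noisefree["chromosome"].isin(["chrX", "chrY"]).to_numpy()
        center = weighted_median(
            noisefree["log2"].to_numpy()[autosomal], length[autosomal]
        )
        noisefree = noisefree.assign(log2=noisefree["log2"] - center)
        expected = arm_weighted_means(noisefree, config=config)
        n_expected += int((expected["call"] != "neutral").sum())
    return {"n_called": n_called, "n_expected": n_expected, "n_samples": len(truths)}


def _implanted_amplifications(spec: CohortSpec) -> dict[str, list[str]]:
    """sample id -> gene symbols prescribed as focal amplifications."""
    out: dict[str, list[str]] = {}
    for presc in spec.samples:
        amps = [f.gene for f in presc.focal_events if f.kind == "amplification"]
        if amps:
            out[presc.sample_id] = amps
    return out


def focal_recovery_study(
    seed: int,
    params: SimParams | None = None,
    config: AnalysisConfig | None = None,
) -> dict:
    """Recovery of the prescribed focal amplifications by the full pipeline.

    Runs normalisation, reference correction, CBS and focal calling on
    every cohort sample carrying an implanted amplification, and counts
    implanted events overlapped by an amplification call.  Segmentation
    runs on 250 kb antitarget bins (a desk-scale choice documented in the
    methods note).
    """
    params = params or SimParams()
    if config is None:
        config = AnalysisConfig(antitarget_avg_size=250_000)
    spec = make_cohort_spec("evaluation60")
    wanted = _implanted_amplifications(spec)
    bins = build_study_bins(config, gc_seed=seed + 1)
    rng = np.random.default_rng(seed + 20_000)
    truths = {t.sample_id: t for t in sample_truth(spec, rng)}
    reference = pooled_flat_reference(bins, params, config, rng)
    genes = {g.symbol: g for g in gene_table()}
    n_implanted = 0
    n_recovered = 0
    details = []
    for sample_id, amp_genes in wanted.items():
        truth = truths[sample_id]
        cov = simulate_ngs_counts(truth, bins, params, rng)
        call = call_sample(cov, reference, bins, config, purity=truth.purity)
        events = call.focal_events
        amps = events[events["class"].isin(["amplification", "high_level_amplification"])]
        for gene_symbol in amp_genes:
            n_implanted += 1
            locus = genes[gene_symbol].locus
            hit = (
                (amps["chromosome"] == locus.chrom)
                & (amps["start"] < locus.end)
                & (amps["end"] > locus.start)
            ).any()
            n_recovered += bool(hit)
            details.append((sample_id, gene_symbol, bool(hit)))
    return {
        "n_implanted": n_implanted,
        "n_recovered": n_recovered,
        "details": details,
    }


def meningioma_profiles_from_spec(spec: CohortSpec | None = None) -> list[MeningiomaProfile]:
    """The deterministic alteration table of the 58-meningioma cohort."""
    spec = spec or make_cohort_spec("meningioma58")
    profiles = []
    for presc in spec.samples:
        losses = frozenset(a for a, d in presc.arm_events if d == "loss")
        gains = frozenset(a for a, d in presc.arm_events if d == "gain")
        homdel = any(
            f.gene in ("CDKN2A", "CDKN2B") and f.kind == "homozygous_deletion"
            for f in presc.focal_events
        )
        profiles.append(
            MeningiomaProfile(
                presc.sample_id,
                presc.histological_grade or 1,
                tertp_mutant=presc.tertp_mutant,
                cdkn2ab_homdel=homdel,
                arm_losses=losses,
                arm_gains=gains,
            )
        )
    return profiles


def meningioma_upgrade_study() -> dict:
    """Integrated-vs-histological grading over the 58-meningioma table."""
    profiles = meningioma_profiles_from_spec()
    calls = [integrate_meningioma_grade(p) for p in profiles]
    upgraded, total = count_upgrades(calls)
    return {
        "n_upgraded": upgraded,
        "n_samples": total,
        "upgraded_samples": [c.sample_id for c in calls if c.upgraded],
        "n_high_risk": sum(c.high_risk for c in calls),
    }


def pilocytic_indicator_study(
    seed: int,
    params: SimParams | None = None,
    config: AnalysisConfig | None = None,
) -> dict:
    """Focal-7q fusion indicators across the six pilocytic chr7 patterns.

    Simulated at a tenth of the study's 16.85M-read median (single-copy
    focal events need the per-bin precision of deeper off-target
    coverage; see docs/methods.md).
    """
    params = params or SimParams(total_reads_median=16_850_000.0, read_scale=0.1)
    config = config or AnalysisConfig()
    spec = make_cohort_spec("pilocytic6")
    bins = build_study_bins(config, gc_seed=seed + 1)
    rng = np.random.default_rng(seed + 30_000)
    truths = sample_truth(spec, rng)
    reference = pooled_flat_reference(bins, params, config, rng)
    indicators = {}
    for truth in truths:
        cov = simulate_ngs_counts(truth, bins, params, rng)
        call = call_sample(cov, reference, bins, config, purity=truth.purity)
        ind = braf_fusion_indicator(call.segments, call.arm_baselines, config)
        indicators[truth.sample_id] = (ind.indicator, ind.fusion_family)
    n_flagged = sum(1 for ind, _ in indicators.values() if ind != "none")
    return {
        "n_flagged": n_flagged,
        "n_samples": len(truths),
        "indicators": indicators,
    }
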