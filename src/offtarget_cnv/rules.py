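"""Deterministic clinical rule engines.

Meningioma integrated grading applies the current molecular criteria on
top of histology: TERT promoter mutation or homozygous CDKN2A/B deletion
forces CNS WHO grade 3; co-deletion of 1p and 22q supports grade 2.  A
separate high-risk flag marks profiles with whole-arm losses on at least
two of chromosomes 6, 10, 14 and 18 (a recurrence-risk pattern; counted
per chromosome, either arm qualifies, and it never changes the grade by
itself).

The BRAF-fusion indicator reads focal 7q copy-number footprints: a small
gain over 7q34 suggests a KIAA1549::BRAF-like tandem duplication, a
small loss on 7q a FAM131B::BRAF-like deletion.  A whole-chromosome-7
gain is not focal evidence.  The indicator is advisory -- it should
prompt fusion analysis, never assert a fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import AnalysisConfig
from .genome import BAND_7Q34, arm_by_name

__all__ = [
    "MeningiomaProfile",
    "GradeCall",
    "FusionIndicator",
    "integrate_meningioma_grade",
    "braf_fusion_indicator",
    "count_upgrades",
]

#: chromosomes whose whole-arm losses feed the recurrence-risk pattern.
HIGH_RISK_CHROMS = {
    "6": ("6p", "6q"),
    "10": ("10p", "10q"),
    "14": ("14q",),  # 14p is acrocentric, never called
    "18": ("18p", "18q"),
}


@dataclass(frozen=True)
class MeningiomaProfile:
    sample_id: str
    histological_grade: int
    tertp_mutant: bool = False
    cdkn2ab_homdel: bool = False
    arm_losses: frozenset[str] = frozenset()
    arm_gains: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.histological_grade not in (1, 2, 3):
            raise ValueError("histological grade must be 1, 2 or 3")


@dataclass(frozen=True)
class GradeCall:
    sample_id: str
    histological_grade: int
    integrated_grade: int
    reasons: tuple[str, ...]
    high_risk: bool

    @property
    def upgraded(self) -> bool:
        return self.integrated_grade > self.histological_grade


@dataclass(frozen=True)
class FusionIndicator:
    indicator: str  # focal_gain_7q34 | focal_loss_7q | none
    fusion_family: str  # KIAA1549::BRAF-like | FAM131B::BRAF-like | none
    segment: tuple[str, int, int, float] | None = None  # (chrom, start, end, rel log2)


def integrate_meningioma_grade(profile: MeningiomaProfile) -> GradeCall:
    """Integrated CNS WHO grade from histology plus molecular criteria."""
    reasons: list[str] = []
    grade = profile.histological_grade
    if profile.tertp_mutant:
        reasons.append("TERT promoter mutation")
    if profile.cdkn2ab_homdel:
        reasons.append("CDKN2A/B homozygous deletion")
    if reasons:
        grade = 3
    elif {"1p", "22q"} <= profile.arm_losses:
        if grade < 2:
            grade = 2
        reasons.append("1p/22q co-deletion")
    n_risk_chroms = sum(
        1
        for arms in HIGH_RISK_CHROMS.values()
        if any(a in profile.arm_losses for a in arms)
    )
    return GradeCall(
        profile.sample_id,
        profile.histological_grade,
        grade,
        tuple(reasons),
        high_risk=n_risk_chroms >= 2,
    )


def braf_fusion_indicator(
    segments: pd.DataFrame,
    arm_baselines: dict[str, float],
    config: AnalysisConfig | None = None,
) -> FusionIndicator:
    """Focal 7q copy-number footprint suggestive of a BRAF fusion.

    A qualifying segment spans at most ``fusion_indicator_max_span`` and
    deviates from the 7q baseline by at least
    ``fusion_indicator_log2_min``: a gain overlapping the 7q34 band
    implies a KIAA1549::BRAF-like duplication, a loss anywhere on 7q a
    FAM131B::BRAF-like deletion.  At most one family is reported (the
    strongest qualifying deviation wins).
    """
    config = config or AnalysisConfig()
    chr7 = segments[segments["chromosome"] == "chr7"]
    if chr7.empty:
        import warnings

        warnings.warn("no chr7 segments; fusion indicator is 'none'")
        return FusionIndicator("none", "none")
    q_span = arm_by_name("7q").span
    baseline = arm_baselines.get("7q", 0.0)
    band_lo, band_hi = BAND_7Q34
    best: tuple[float, FusionIndicator] | None = None
    for seg in chr7.itertuples(index=False):
        span = seg.end - seg.start
        if span > config.fusion_indicator_max_span:
            continue
        if getattr(seg, "num_bins", config.fusion_min_bins) < config.fusion_min_bins:
            continue  # single-bin flukes are not fusion evidence
        on_q = seg.end > q_span.start and seg.start < q_span.end
        if not on_q:
            continue
        rel = seg.seg_mean - baseline
        cand: FusionIndicator | None = None
        if rel >= config.fusion_indicator_log2_min and seg.end > band_lo and seg.start < band_hi:
            cand = FusionIndicator(
                "focal_gain_7q34",
                "KIAA1549::BRAF-like",
                (seg.chromosome, int(seg.start), int(seg.end), float(rel)),
            )
        elif rel <= -config.fusion_indicator_log2_min:
            cand = FusionIndicator(
                "focal_loss_7q",
                "FAM131B::BRAF-like",
                (seg.chromosome, int(seg.start), int(seg.end), float(rel)),
            )
        if cand is not None and (best is None or abs(rel) > best[0]):
            best = (abs(rel), cand)
    return best[1] if best else FusionIndicator("none", "none")


def count_upgrades(grade_calls: list[GradeCall]) -> tuple[int, int]:
    """(number of samples upgraded beyond histology, cohort size)."""
    if not grade_calls:
        raise ValueError("empty cohort")
    return sum(1 for c in grade_calls if c.upgraded), len(grade_calls)
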