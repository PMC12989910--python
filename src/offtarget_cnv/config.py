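"""Analysis configuration.

One flat dataclass holds every tunable threshold of the calling pipeline,
with the defaults used throughout: arm calls at |log2| >= 0.5 on
length-weighted arm means, arm events at >= 50% arm coverage by altered
segments, focal amplifications at >= 1.0 log2 above the arm baseline
(high-level at absolute >= 2.0), homozygous deletions at <= -1.3 with an
ambiguity band (-1.3, -0.8], and CBS at alpha 0.01 with 1000 seeded
permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    #: |log2| threshold for three-class arm calls on length-weighted means.
    arm_call_threshold: float = 0.5
    #: fraction of an arm that altered segments must cover for an arm event.
    arm_fraction_threshold: float = 0.5
    #: |log2| threshold classifying a segment as altered for the >=50% rule.
    seg_class_threshold: float = 0.5
    #: maximum span of a focal event (bp).
    focal_max_span: int = 10_000_000
    #: focal amplification: log2 above the arm baseline.
    amp_log2_min: float = 1.0
    #: high-level amplification: absolute segment log2.
    high_amp_log2_min: float = 2.0
    #: homozygous deletion: absolute segment log2 at or below this.
    homdel_log2_max: float = -1.3
    #: (lo, hi]: deletions in this log2 band are flagged ambiguous.
    homdel_ambiguous_range: tuple[float, float] = (-1.3, -0.8)
    #: BRAF-fusion indicator: log2 offset from the 7q baseline.
    fusion_indicator_log2_min: float = 0.4
    #: BRAF-fusion indicator: maximum focal span (bp).
    fusion_indicator_max_span: int = 5_000_000
    #: BRAF-fusion indicator: minimum supporting bins per segment.
    fusion_min_bins: int = 3
    #: average width of antitarget (off-target) bins (bp).
    antitarget_avg_size: int = 100_000
    #: margin around capture targets excluded from antitarget bins (bp).
    antitarget_margin: int = 5_000
    #: CBS permutation test level.
    cbs_alpha: float = 0.01
    #: number of permutations per CBS split test.
    cbs_nperm: int = 1000
    #: reference mask: minimum pooled read count per bin.
    ref_min_pooled_reads: int = 10
    #: reference mask: maximum per-bin spread (log2).
    ref_max_spread: float = 1.0
    #: variance floor added to spread^2 when weighting ratio bins.
    weight_floor: float = 0.01
    #: rolling-median window (bins) for GC bias correction; must be odd.
    gc_window: int = 101
    #: seed for the CBS permutation stream.
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "arm_call_threshold": self.arm_call_threshold,
            "arm_fraction_threshold": self.arm_fraction_threshold,
            "seg_class_threshold": self.seg_class_threshold,
            "focal_max_span": self.focal_max_span,
            "amp_log2_min": self.amp_log2_min,
            "high_amp_log2_min": self.high_amp_log2_min,
            "fusion_indicator_log2_min": self.fusion_indicator_log2_min,
            "fusion_indicator_max_span": self.fusion_indicator_max_span,
            "cbs_alpha": self.cbs_alpha,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        lo, hi = self.homdel_ambiguous_range
        if not (lo < hi < 0):
            raise ValueError("homdel_ambiguous_range must satisfy lo < hi < 0")
        if self.homdel_log2_max >= 0:
            raise ValueError("homdel_log2_max must be negative")
        if self.antitarget_avg_size < 10_000:
            raise ValueError("antitarget_avg_size must be >= 10 kb")
        if self.cbs_nperm < 100:
            raise ValueError("cbs_nperm must be >= 100")
        if self.gc_window % 2 == 0:
            raise ValueError("gc_window must be odd")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "homdel_ambiguous_range" in raw:
            raw["homdel_ambiguous_range"] = tuple(raw["homdel_ambiguous_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["homdel_ambiguous_range"] = list(self.homdel_ambiguous_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
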