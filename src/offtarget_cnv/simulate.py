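"""Truth-annotated synthetic cohorts emulating the study design.

The generator produces three coupled artefacts per sample:

* a :class:`TruthProfile` -- tumour purity, DNA integrity (DIN) and a set
  of disjoint integer-copy-number events (whole-arm single-copy events,
  focal amplifications at CN 20-50, homozygous deletions at CN 0);
* NGS bin counts -- Poisson reads allocated to target/antitarget bins in
  proportion to bin length x copy ratio x a GC capture bias, with the
  off-target fraction driven by DIN (lower-integrity FFPE DNA yields more
  off-target reads);
* an array-style bin profile -- fixed 100 kb bins carrying the same
  purity-attenuated log2 signal plus arm-level waves and per-bin noise.

Both platforms read the observed log2 off the same purity mixture,
``log2(p * CN/2 + (1 - p))``, which is what makes cross-platform arm
calls agree even at low purity.

Cohort scenarios
----------------
``evaluation60``
    60 CNS tumours: 25 IDH-wildtype glioblastomas (+7/-10, EGFR/MDM4/
    FGFR3/TERT/PDGFRA amplifications, CDKN2A/B and PTEN homozygous
    deletions), 15 oligodendrogliomas (1p/19q co-deletion), 9 ependymal
    tumours (one MYCN-amplified spinal ependymoma), 6 medulloblastomas
    and 5 choroid plexus tumours, with per-entity mean arm-event burdens
    17.6 / 9.5 / 8.9 / 8 / 5.2 (choroid plexus / glioblastoma /
    ependymoma / medulloblastoma / oligodendroglioma).
``meningioma58``
    37 grade-1 (8 with 1p+22q co-deletion, 2 of those with the
    chromosome-6/10/14/18 loss pattern), 20 grade-2 (16 with 1p+22q, one
    with CDKN2A/B homozygous deletion, 14 with the 6/10/14/18 pattern)
    and one grade-3 meningioma (TERT promoter mutant plus CDKN2A/B
    homozygous deletion).
``pilocytic6``
    six high-purity pilocytic astrocytomas: four with a ~2 Mb focal gain
    at 7q34, one with whole-chromosome-7 gain and no focal event, one
    with a ~2 Mb focal loss on distal 7q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageProfile
from .genome import (
    CHROM_LENGTHS,
    GenomicInterval,
    arm_by_name,
    arm_table_hg19,
    chrom_sort_key,
    comparable_arms,
    gene_by_symbol,
)

__all__ = [
    "SimParams",
    "FocalPrescription",
    "SamplePrescription",
    "CohortSpec",
    "TruthProfile",
    "EventCollisionError",
    "SCENARIOS",
    "make_cohort_spec",
    "sample_truth",
    "flat_truth",
    "expected_log2",
    "expected_ratio_bins",
    "simulate_ngs_counts",
    "simulate_reads",
    "simulate_array_profile",
    "truth_frame",
]

#: log2 floor reported when the purity mixture reaches zero copies.
LOG2_FLOOR = -8.0

#: scaled-Beta purity model: mean 0.72 on the range [0.20, 0.95].
PURITY_RANGE = (0.20, 0.95)
PURITY_BETA = (3.5, 1.54)
DIN_RANGE = (2.0, 8.0)


class EventCollisionError(ValueError):
    """Two same-level event prescriptions overlap the same locus."""


@dataclass
class SimParams:
    """Knobs of the NGS/array simulators with study-calibrated defaults.

    ``total_reads_median`` x ``read_scale`` sets the per-sample library
    size (desk scale: 2% of the study's 24M-read median, realised as
    Poisson bin counts); per-sample sizes are log-normal around it.  The
    DIN model ``f = clamp(intercept - slope * DIN + N(0, sd), 0.30, 0.95)``
    is calibrated so the cohort-level DIN/off-target-count correlation is
    about -0.4.
    """

    total_reads_median: float = 24_000_000.0
    read_scale: float = 0.02
    library_log_sd: float = 0.45
    offtarget_intercept: float = 0.95
    offtarget_slope: float = 0.04
    offtarget_noise_sd: float = 0.05
    gc_strength: float = 0.6
    gc_center: float = 0.42
    array_bin_size: int = 100_000
    array_noise_sd: float = 0.15
    array_arm_wave_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in ("offtarget_noise_sd", "array_noise_sd", "array_arm_wave_sd",
                     "library_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.array_bin_size <= 0 or self.read_scale <= 0:
            raise ValueError("array_bin_size and read_scale must be positive")

    @property
    def library_median(self) -> float:
        return self.total_reads_median * self.read_scale


@dataclass(frozen=True)
class FocalPrescription:
    """A focal event anchored at a gene locus."""

    gene: str
    kind: str  # amplification | homozygous_deletion | single_copy_gain | single_copy_loss
    span_range: tuple[int, int] = (500_000, 2_000_000)
    cn_range: tuple[int, int] | None = None  # default depends on kind

    def draw_cn(self, rng: np.random.Generator) -> int:
        if self.cn_range is not None:
            lo, hi = self.cn_range
            return int(rng.integers(lo, hi + 1))
        return {
            "amplification": int(rng.integers(20, 51)),
            "homozygous_deletion": 0,
            "single_copy_gain": 3,
            "single_copy_loss": 1,
        }[self.kind]


@dataclass(frozen=True)
class SamplePrescription:
    sample_id: str
    entity: str
    histological_grade: int | None = None
    purity: float | None = None  # None -> scaled-Beta draw
    din: float | None = None  # None -> uniform [2, 8]
    arm_events: tuple[tuple[str, str], ...] = ()  # (arm name, gain|loss)
    focal_events: tuple[FocalPrescription, ...] = ()
    extra_arm_mean: float = 0.0
    extra_arm_kind: str = "both"  # both | loss | gain
    excluded_arms: frozenset[str] = frozenset()
    tertp_mutant: bool = False


@dataclass(frozen=True)
class CohortSpec:
    name: str
    samples: tuple[SamplePrescription, ...]


@dataclass(frozen=True)
class TruthProfile:
    """Realised truth for one sample: disjoint (interval, copy-number) events."""

    sample_id: str
    entity: str
    purity: float
    din: float
    events: tuple[tuple[GenomicInterval, int], ...]
    histological_grade: int | None = None
    tertp_mutant: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError("purity must be in (0, 1]")
        for iv, cn in self.events:
            if cn < 0:
                raise ValueError("copy number must be non-negative")
            iv.validate_against(CHROM_LENGTHS)


# ---------------------------------------------------------------------------
# cohort scenario construction


def _gbm_prescriptions() -> list[SamplePrescription]:
    out = []
    for i in range(25):
        if i < 22:
            arms = (("7p", "gain"), ("7q", "gain"), ("10p", "loss"), ("10q", "loss"))
        elif i < 24:  # isolated 7q gains
            arms = (("7q", "gain"),)
        else:  # isolated 10q loss
            arms = (("10q", "loss"),)
        focal: list[FocalPrescription] = []
        if i < 10:
            focal.append(FocalPrescription("EGFR", "amplification"))
        if i < 4:
            focal.append(FocalPrescription("MDM4", "amplification"))
        if i == 10:
            focal.append(FocalPrescription("FGFR3", "amplification"))
        if i == 11:
            focal.append(FocalPrescription("TERT", "amplification"))
        if i == 12:
            focal.append(FocalPrescription("PDGFRA", "amplification"))
        if i < 17:
            focal.append(
                FocalPrescription("CDKN2A", "homozygous_deletion", (1_000_000, 2_000_000))
            )
        if i == 7:
            focal.append(
                FocalPrescription("PTEN", "homozygous_deletion", (1_000_000, 2_000_000))
            )
        out.append(
            SamplePrescription(
                f"GBM_{i + 1:02d}", "glioblastoma",
                arm_events=arms, focal_events=tuple(focal),
                extra_arm_mean=5.86,
            )
        )
    return out


def _oligo_prescriptions() -> list[SamplePrescription]:
    out = []
    for i in range(15):
        focal: list[FocalPrescription] = []
        if i == 8:
            focal.append(FocalPrescription("PDGFRA", "amplification"))
        if i == 9:
            focal.append(
                FocalPrescription("CDKN2A", "homozygous_deletion", (1_000_000, 2_000_000))
            )
        extra_mean = 46 / 6 if i < 6 else 0.0
        out.append(
            SamplePrescription(
                f"ODG_{i + 1:02d}", "oligodendroglioma",
                arm_events=(("1p", "loss"), ("19q", "loss"))
                + ((("4q", "gain"),) if i in (6, 7) else ()),
                focal_events=tuple(focal),
                extra_arm_mean=extra_mean, extra_arm_kind="loss",
            )
        )
    return out


def make_cohort_spec(scenario: str) -> CohortSpec:
    """Deterministic cohort prescription for a named scenario."""
    if scenario == "evaluation60":
        samples = _gbm_prescriptions() + _oligo_prescriptions()
        for i in range(9):
            focal = (FocalPrescription("MYCN", "amplification"),) if i == 0 else ()
            samples.append(
                SamplePrescription(
                    f"EPN_{i + 1:02d}",
                    "spinal_ependymoma" if i == 0 else "ependymoma",
                    focal_events=focal,
                    extra_arm_mean=0.0 if i == 8 else 8.9 * 9 / 8,
                )
            )
        for i in range(6):
            samples.append(
                SamplePrescription(
                    f"MB_{i + 1:02d}", "medulloblastoma",
                    extra_arm_mean=0.0 if i == 5 else 8.0 * 6 / 5,
                )
            )
        for i in range(5):
            samples.append(
                SamplePrescription(
                    f"CPT_{i + 1:02d}", "choroid_plexus", extra_arm_mean=17.6
                )
            )
        return CohortSpec("evaluation60", tuple(samples))

    if scenario == "meningioma58":
        no_1p22q = frozenset({"1p", "22q"})
        highrisk_pairs = [("6q", "14q"), ("10q", "18q"), ("6q", "10q"),
                         ("14q", "18q"), ("6q", "18q"), ("10q", "14q")]
        samples = []
        for i in range(37):
            arms: tuple[tuple[str, str], ...] = ()
            if i < 8:
                arms = (("1p", "loss"), ("22q", "loss"))
            if i < 2:  # two 1p/22q carriers with the 6/10/14/18 pattern
                a, b = highrisk_pairs[i]
                arms = arms + ((a, "loss"), (b, "loss"))
            samples.append(
                SamplePrescription(
                    f"MEN_{i + 1:02d}", "meningioma", histological_grade=1,
                    arm_events=arms, extra_arm_mean=2.92, extra_arm_kind="loss",
                    excluded_arms=no_1p22q,
                )
            )
        for i in range(20):
            arms = (("1p", "loss"), ("22q", "loss")) if i < 16 else ()
            if i < 14:
                a, b = highrisk_pairs[i % len(highrisk_pairs)]
                arms = arms + tuple(
                    (x, "loss") for x in (a, b) if (x, "loss") not in arms
                )
            focal = (
                (FocalPrescription("CDKN2A", "homozygous_deletion", (1_000_000, 2_000_000)),)
                if i == 0
                else ()
            )
            samples.append(
                SamplePrescription(
                    f"MEN_{i + 38:02d}", "meningioma", histological_grade=2,
                    arm_events=arms, focal_events=focal,
                    extra_arm_mean=5.05, extra_arm_kind="loss",
                    excluded_arms=no_1p22q,
                )
            )
        samples.append(
            SamplePrescription(
                "MEN_58", "meningioma", histological_grade=3,
                arm_events=(("1p", "loss"), ("22q", "loss"),
                            ("6q", "loss"), ("14q", "loss"), ("18q", "loss")),
                focal_events=(
                    FocalPrescription("CDKN2A", "homozygous_deletion", (1_000_000, 2_000_000)),
                ),
                extra_arm_mean=1.0, extra_arm_kind="loss",
                excluded_arms=no_1p22q, tertp_mutant=True,
            )
        )
        return CohortSpec("meningioma58", tuple(samples))

    if scenario == "pilocytic6":
        samples = []
        for i in range(4):
            samples.append(
                SamplePrescription(
                    f"PA_{i + 1}", "pilocytic", purity=0.9,
                    focal_events=(
                        FocalPrescription(
                            "KIAA1549", "single_copy_gain", (1_800_000, 2_200_000)
                        ),
                    ),
                )
            )
        samples.append(
            SamplePrescription(
                "PA_5", "pilocytic", purity=0.9,
                arm_events=(("7p", "gain"), ("7q", "gain")),
            )
        )
        samples.append(
            SamplePrescription(
                "PA_6", "pilocytic", purity=0.9,
                focal_events=(
                    FocalPrescription(
                        "FAM131B", "single_copy_loss", (1_800_000, 2_200_000)
                    ),
                ),
            )
        )
        return CohortSpec("pilocytic6", tuple(samples))

    raise ValueError(f"unknown scenario {scenario!r}")


SCENARIOS = ("evaluation60", "meningioma58", "pilocytic6")


# ---------------------------------------------------------------------------
# truth realisation


def _draw_purity(rng: np.random.Generator) -> float:
    lo, hi = PURITY_RANGE
    return lo + (hi - lo) * rng.beta(*PURITY_BETA)


def _place_focal(presc: FocalPrescription, rng: np.random.Generator) -> GenomicInterval:
    gene = gene_by_symbol(presc.gene)
    lo, hi = presc.span_range
    span = int(rng.uniform(lo, hi))
    span = max(span, gene.locus.length + 2)
    slack = span - gene.locus.length
    start = gene.locus.start - int(rng.uniform(0, slack))
    start = max(0, start)
    end = min(start + span, CHROM_LENGTHS[gene.locus.chrom])
    return GenomicInterval(gene.locus.chrom, start, end)


def _resolve_events(
    arm_level: list[tuple[GenomicInterval, int]],
    focal_level: list[tuple[GenomicInterval, int]],
    sample_id: str,
) -> tuple[tuple[GenomicInterval, int], ...]:
    """Layer focal events over arm events; reject same-level overlaps."""
    for level, name in ((arm_level, "arm"), (focal_level, "focal")):
        ordered = sorted(level, key=lambda ev: (chrom_sort_key(ev[0].chrom), ev[0].start))
        for (a, _), (b, _) in zip(ordered, ordered[1:]):
            if a.overlap(b):
                raise EventCollisionError(
                    f"{sample_id}: overlapping {name} prescriptions at {a} / {b}"
                )
    events: list[tuple[GenomicInterval, int]] = []
    focal_by_chrom: dict[str, list[tuple[GenomicInterval, int]]] = {}
    for iv, cn in focal_level:
        focal_by_chrom.setdefault(iv.chrom, []).append((iv, cn))
    for iv, cn in arm_level:
        cuts = sorted(
            (f for f in focal_by_chrom.get(iv.chrom, []) if f[0].overlap(iv)),
            key=lambda f: f[0].start,
        )
        cursor = iv.start
        for fiv, _ in cuts:
            if fiv.start > cursor:
                events.append((GenomicInterval(iv.chrom, cursor, min(fiv.start, iv.end)), cn))
            cursor = max(cursor, min(fiv.end, iv.end))
        if cursor < iv.end:
            events.append((GenomicInterval(iv.chrom, cursor, iv.end), cn))
    events.extend(focal_level)
    events.sort(key=lambda ev: (chrom_sort_key(ev[0].chrom), ev[0].start))
    return tuple(events)


def sample_truth(
    spec: CohortSpec, rng: np.random.Generator
) -> list[TruthProfile]:
    """Realise a cohort spec into concrete truth profiles.

    Whole-arm gains become CN 3, losses CN 1; focal amplifications draw
    CN 20-50 and homozygous deletions CN 0.  Extra (unprescribed) arm
    events are drawn uniformly from unused comparable arms.
    """
    profiles = []
    comp_names = [a.name for a in comparable_arms()]
    for presc in spec.samples:
        purity = presc.purity if presc.purity is not None else _draw_purity(rng)
        din = presc.din if presc.din is not None else float(rng.uniform(*DIN_RANGE))
        arm_level: list[tuple[GenomicInterval, int]] = []
        used_arms: set[str] = set()
        for arm_name, direction in presc.arm_events:
            if arm_name in used_arms:
                raise EventCollisionError(
                    f"{presc.sample_id}: arm {arm_name} prescribed twice"
                )
            arm = arm_by_name(arm_name)
            arm_level.append((arm.span, 3 if direction == "gain" else 1))
            used_arms.add(arm_name)
        n_extra = int(rng.poisson(presc.extra_arm_mean)) if presc.extra_arm_mean else 0
        pool = [a for a in comp_names if a not in used_arms and a not in presc.excluded_arms]
        n_extra = min(n_extra, len(pool))
        if n_extra:
            chosen = rng.choice(len(pool), size=n_extra, replace=False)
            for j in chosen:
                arm = arm_by_name(pool[j])
                if presc.extra_arm_kind == "loss":
                    cn = 1
                elif presc.extra_arm_kind == "gain":
                    cn = 3
                else:
                    cn = 3 if rng.random() < 0.5 else 1
                arm_level.append((arm.span, cn))
        focal_level = [
            (_place_focal(f, rng), f.draw_cn(rng)) for f in presc.focal_events
        ]
        profiles.append(
            TruthProfile(
                presc.sample_id,
                presc.entity,
                purity,
                din,
                _resolve_events(arm_level, focal_level, presc.sample_id),
                histological_grade=presc.histological_grade,
                tertp_mutant=presc.tertp_mutant,
            )
        )
    return profiles


def flat_truth(sample_id: str, rng: np.random.Generator) -> TruthProfile:
    """A copy-neutral sample, as used for the pooled reference."""
    return TruthProfile(sample_id, "flat_reference", 1.0, float(rng.uniform(*DIN_RANGE)), ())


# ---------------------------------------------------------------------------
# expected signal


def _mixture_ratio(purity: float, cn: int) -> float:
    return purity * cn / 2.0 + (1.0 - purity)


def expected_log2(truth: TruthProfile, interval: GenomicInterval) -> float:
    """Purity-attenuated expected log2 over a constant-copy-number interval.

    ``log2(p * CN/2 + (1 - p))``, floored at -8 when the mixture is zero.
    Raises if *interval* spans a copy-number breakpoint (callers split).
    """
    cn = None
    for iv, event_cn in truth.events:
        ov = iv.overlap(interval)
        if ov == interval.length:
            cn = event_cn
            break
        if ov > 0:
            raise ValueError(
                f"{interval} spans a copy-number breakpoint at {iv}; split it"
            )
    if cn is None:
        cn = 2
    ratio = _mixture_ratio(truth.purity, cn)
    if ratio <= 2.0**LOG2_FLOOR:
        return LOG2_FLOOR
    return math.log2(ratio)


def expected_ratio_bins(
    truth: TruthProfile,
    chrom: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
) -> np.ndarray:
    """Per-bin linear-scale copy ratio, overlap-weighted across breakpoints."""
    length = (end - start).astype(float)
    acc = np.zeros(len(start), dtype=float)
    covered = np.zeros(len(start), dtype=float)
    for iv, cn in truth.events:
        sel = chrom == iv.chrom
        if not sel.any():
            continue
        ov = np.clip(
            np.minimum(end[sel], iv.end) - np.maximum(start[sel], iv.start), 0, None
        ).astype(float)
        acc[sel] += ov * _mixture_ratio(truth.purity, cn)
        covered[sel] += ov
    return (acc + (length - covered) * 1.0) / length


# ---------------------------------------------------------------------------
# platform simulators


def _draw_offtarget_fraction(din: float, params: SimParams, rng: np.random.Generator) -> float:
    f = (
        params.offtarget_intercept
        - params.offtarget_slope * din
        + rng.normal(0.0, params.offtarget_noise_sd)
    )
    return float(np.clip(f, 0.30, 0.95))


def _bin_intensity(
    truth: TruthProfile, bins: pd.DataFrame, params: SimParams
) -> np.ndarray:
    if bins["gc"].isna().any():
        raise ValueError("bins lack GC annotation")
    chrom = bins["chromosome"].to_numpy()
    start = bins["start"].to_numpy()
    end = bins["end"].to_numpy()
    ratio = expected_ratio_bins(truth, chrom, start, end)
    gc = bins["gc"].to_numpy()
    length = (end - start).astype(float)
    return length * ratio * np.exp(params.gc_strength * (gc - params.gc_center))


def simulate_ngs_counts(
    truth: TruthProfile,
    bins: pd.DataFrame,
    params: SimParams,
    rng: np.random.Generator,
) -> CoverageProfile:
    """Draw per-bin Poisson read counts for one sample.

    The library size is log-normal around the desk-scaled median; the
    DIN-driven off-target fraction splits it between the target and
    antitarget streams, and within each stream reads land proportional to
    bin length x copy ratio x GC bias.
    """
    is_target = (bins["bin_type"] == "target").to_numpy()
    if not is_target.any() or is_target.all():
        raise ValueError("bins must include both target and antitarget bins")
    intensity = _bin_intensity(truth, bins, params)
    total = float(rng.lognormal(math.log(params.library_median), params.library_log_sd))
    f_off = _draw_offtarget_fraction(truth.din, params, rng)
    counts = np.zeros(len(bins), dtype=np.int64)
    for mask, n_reads in ((is_target, total * (1 - f_off)), (~is_target, total * f_off)):
        lam = n_reads * intensity[mask] / intensity[mask].sum()
        counts[mask] = rng.poisson(lam)
    return CoverageProfile(truth.sample_id, counts, truth.din)


def simulate_reads(
    truth: TruthProfile,
    bins: pd.DataFrame,
    params: SimParams,
    rng: np.random.Generator,
    n_reads: int,
) -> pd.DataFrame:
    """Place individual read starts (chrom, start) under the bin intensity.

    Desk-scale only: refuses more than 1e6 reads -- at larger sizes use
    :func:`simulate_ngs_counts`, which realises the same model as counts.
    """
    if n_reads > 1_000_000:
        raise ValueError(
            "simulate_reads is capped at 1e6 reads; use simulate_ngs_counts "
            "for full-size libraries"
        )
    intensity = _bin_intensity(truth, bins, params)
    p = intensity / intensity.sum()
    bin_idx = rng.choice(len(bins), size=n_reads, p=p)
    start = bins["start"].to_numpy()[bin_idx]
    end = bins["end"].to_numpy()[bin_idx]
    pos = start + (rng.random(n_reads) * (end - start)).astype(np.int64)
    df = pd.DataFrame(
        {"chromosome": bins["chromosome"].to_numpy()[bin_idx], "start": pos}
    )
    return df.sort_values(
        by=["chromosome", "start"],
        key=lambda c: c.map(chrom_sort_key) if c.name == "chromosome" else c,
        kind="stable",
    ).reset_index(drop=True)


def array_bins(
    params: SimParams | None = None, genome: dict[str, int] | None = None
) -> pd.DataFrame:
    """Fixed-width genome bins in the array (.igv) layout."""
    params = params or SimParams()
    genome = CHROM_LENGTHS if genome is None else genome
    rows = []
    size = params.array_bin_size
    for chrom in sorted(genome, key=chrom_sort_key):
        length = genome[chrom]
        n = length // size
        starts = size * np.arange(n)
        ends = starts + size
        if n:
            ends[-1] = length  # absorb the sub-bin remainder
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e)))
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end"])
    df.insert(3, "feature", [f"bin_{i}" for i in range(len(df))])
    return df


def simulate_array_profile(
    truth: TruthProfile,
    params: SimParams,
    rng: np.random.Generator,
    bins: pd.DataFrame | None = None,
    arm_table=None,
) -> pd.DataFrame:
    """Array-style bin log2 values: mixture signal + arm wave + bin noise."""
    bins = array_bins(params) if bins is None else bins
    arm_table = arm_table_hg19() if arm_table is None else arm_table
    ratio = expected_ratio_bins(
        truth,
        bins["chromosome"].to_numpy(),
        bins["start"].to_numpy(),
        bins["end"].to_numpy(),
    )
    log2 = np.log2(np.maximum(ratio, 2.0**LOG2_FLOOR))
    mid = (bins["start"].to_numpy() + bins["end"].to_numpy()) // 2
    chrom = bins["chromosome"].to_numpy()
    wave = np.zeros(len(bins))
    for arm in arm_table:
        sel = (chrom == arm.chrom) & (mid >= arm.span.start) & (mid < arm.span.end)
        if sel.any():
            wave[sel] = rng.normal(0.0, params.array_arm_wave_sd)
    values = log2 + wave + rng.normal(0.0, params.array_noise_sd, size=len(bins))
    out = bins[["chromosome", "start", "end", "feature"]].copy()
    out["log2"] = values
    return out


def truth_frame(profiles: list[TruthProfile]) -> pd.DataFrame:
    """Flatten truth profiles into the ``truth`` table dialect."""
    rows = []
    for t in profiles:
        grade = t.histological_grade if t.histological_grade is not None else ""
        base = (t.sample_id, t.entity, grade, t.purity, t.din, int(t.tertp_mutant))
        if not t.events:
            rows.append(base + ("", 0, 1, 2))
        for iv, cn in t.events:
            rows.append(base + (iv.chrom, iv.start, iv.end, cn))
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "entity", "histological_grade", "purity", "din",
            "tertp_mutant", "chromosome", "start", "end", "copy_number",
        ],
    )
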