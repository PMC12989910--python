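"""Chromosome-arm statistics and cross-platform comparison.

Arm-level calls use length-weighted mean log2 per comparable arm with a
three-class {gain, loss, neutral} decision at +-0.5 (inclusive
boundaries); an alternative segment-based rule flags an arm when altered
segments cover at least half of it.  Per-sample concordance between two
platforms is the fraction of shared arms with identical class, and
profile correlation pairs bins across grids by maximal overlap.  Sex
chromosomes are excluded from every comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .genome import ChromArm, arm_table_hg19

__all__ = [
    "arm_weighted_means",
    "arm_fraction_events",
    "per_sample_concordance",
    "correlate_profiles",
    "cohort_summary",
    "ConcordanceResult",
]

ARM_COLUMNS = ["arm", "chromosome", "mean_log2", "n_bins", "call"]


def _classify(mean: np.ndarray, threshold: float) -> np.ndarray:
    call = np.where(mean >= threshold, "gain", np.where(mean <= -threshold, "loss", "neutral"))
    return call.astype(object)


def arm_weighted_means(
    profile: pd.DataFrame,
    arm_table: tuple[ChromArm, ...] | None = None,
    config: AnalysisConfig | None = None,
    comparable_only: bool = True,
) -> pd.DataFrame:
    """Length-weighted mean log2 and three-class call per arm.

    *profile* needs ``chromosome, start, end, log2`` columns (a .cnr or
    .igv-derived frame).  Bins straddling the centromere contribute
    pro-rata to both arms.  Arms without bins are omitted.
    """
    if profile.empty:
        raise ValueError("empty bin profile")
    arm_table = arm_table_hg19() if arm_table is None else arm_table
    config = config or AnalysisConfig()
    chrom = profile["chromosome"].to_numpy()
    start = profile["start"].to_numpy()
    end = profile["end"].to_numpy()
    log2 = profile["log2"].to_numpy(dtype=float)
    rows = []
    for arm in arm_table:
        if comparable_only and not arm.comparable:
            continue
        sel = chrom == arm.chrom
        if not sel.any():
            continue
        ov = np.clip(
            np.minimum(end[sel], arm.span.end) - np.maximum(start[sel], arm.span.start),
            0,
            None,
        ).astype(float)
        inside = ov > 0
        if not inside.any():
            continue
        mean = float(np.sum(ov * log2[sel]) / np.sum(ov))
        rows.append((arm.name, arm.chrom, mean, int(inside.sum())))
    out = pd.DataFrame(rows, columns=ARM_COLUMNS[:4])
    out["call"] = _classify(out["mean_log2"].to_numpy(), config.arm_call_threshold)
    return out


def arm_fraction_events(
    segments: pd.DataFrame,
    arm_table: tuple[ChromArm, ...] | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Arm gain/loss flags by the >= 50%-of-arm segment-coverage rule.

    An arm is flagged gained (lost) when segments with mean >= +threshold
    (<= -threshold) cover at least ``arm_fraction_threshold`` of its
    length.
    """
    arm_table = arm_table_hg19() if arm_table is None else arm_table
    config = config or AnalysisConfig()
    chrom = segments["chromosome"].to_numpy()
    start = segments["start"].to_numpy()
    end = segments["end"].to_numpy()
    mean = segments["seg_mean"].to_numpy(dtype=float)
    rows = []
    for arm in arm_table:
        if not arm.comparable:
            continue
        sel = chrom == arm.chrom
        ov = np.clip(
            np.minimum(end[sel], arm.span.end) - np.maximum(start[sel], arm.span.start),
            0,
            None,
        ).astype(float)
        m = mean[sel]
        gain_frac = float(ov[m >= config.seg_class_threshold].sum() / arm.length)
        loss_frac = float(ov[m <= -config.seg_class_threshold].sum() / arm.length)
        rows.append(
            (
                arm.name,
                arm.chrom,
                gain_frac >= config.arm_fraction_threshold,
                loss_frac >= config.arm_fraction_threshold,
                gain_frac,
                loss_frac,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["arm", "chromosome", "gained", "lost", "gain_fraction", "loss_fraction"],
    )


@dataclass
class ConcordanceResult:
    sample_id: str
    concordance: float
    n_arms: int
    discordant_arms: tuple[str, ...]


def per_sample_concordance(
    arm_profile_a: pd.DataFrame,
    arm_profile_b: pd.DataFrame,
    sample_id: str = "sample",
) -> ConcordanceResult | None:
    """Fraction of shared arms with identical three-class call.

    Neutral-neutral agreement counts (every arm is classified before
    comparison).  Returns ``None`` when the profiles share no arms.
    """
    merged = arm_profile_a.merge(arm_profile_b, on="arm", suffixes=("_a", "_b"))
    if merged.empty:
        return None
    agree = (merged["call_a"] == merged["call_b"]).to_numpy()
    discordant = tuple(merged.loc[~agree, "arm"])
    return ConcordanceResult(
        sample_id, float(agree.mean()), len(merged), discordant
    )


def _pair_values(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pair each bin of *a* with the maximal-overlap bin of *b*."""
    rows = []
    for chrom in a["chromosome"].unique():
        sa = a[a["chromosome"] == chrom]
        sb = b[b["chromosome"] == chrom]
        if sb.empty:
            continue
        b_start = sb["start"].to_numpy()
        b_end = sb["end"].to_numpy()
        b_val = sb["log2"].to_numpy(dtype=float)
        a_start = sa["start"].to_numpy()
        a_end = sa["end"].to_numpy()
        a_val = sa["log2"].to_numpy(dtype=float)
        # candidate: bin whose start precedes a's midpoint, and its right
        # neighbour; keep whichever overlaps more.
        mid = (a_start + a_end) // 2
        j = np.clip(np.searchsorted(b_start, mid, side="right") - 1, 0, len(sb) - 1)
        jn = np.clip(j + 1, 0, len(sb) - 1)

        def overlap(idx):
            return np.clip(
                np.minimum(a_end, b_end[idx]) - np.maximum(a_start, b_start[idx]),
                0,
                None,
            )

        ov_j, ov_jn = overlap(j), overlap(jn)
        pick = np.where(ov_jn > ov_j, jn, j)
        ov = np.maximum(ov_j, ov_jn)
        ok = ov > 0
        for am, bm, c in zip(a_val[ok], b_val[pick[ok]], mid[ok]):
            rows.append((chrom, c, am, bm))
    return pd.DataFrame(rows, columns=["chromosome", "mid", "value_a", "value_b"])


def correlate_profiles(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    arm_table: tuple[ChromArm, ...] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of paired bin values, genome-wide and per arm.

    Autosomal comparable arms only; scopes with fewer than 3 pairs are
    reported as not computable (NaN r and p).
    """
    arm_table = arm_table_hg19() if arm_table is None else arm_table
    comparable = [a for a in arm_table if a.comparable]
    paired = _pair_values(profile_a, profile_b)
    rows = []

    def add(scope: str, sub: pd.DataFrame) -> None:
        if len(sub) < 3 or sub["value_a"].std() == 0 or sub["value_b"].std() == 0:
            rows.append((scope, np.nan, np.nan, len(sub)))
            return
        r, p = stats.pearsonr(sub["value_a"], sub["value_b"])
        rows.append((scope, float(r), float(p), len(sub)))

    keep = np.zeros(len(paired), dtype=bool)
    for arm in comparable:
        sel = (
            (paired["chromosome"] == arm.chrom)
            & (paired["mid"] >= arm.span.start)
            & (paired["mid"] < arm.span.end)
        ).to_numpy()
        keep |= sel
        add(arm.name, paired[sel])
    add("genome", paired[keep])
    return pd.DataFrame(rows, columns=["scope", "r", "p", "n"])


def cohort_summary(
    arm_profiles: dict[str, pd.DataFrame],
    entities: dict[str, str] | None = None,
    expected_calls: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Per-sample gain/loss counts, with optional truth-based recovery.

    *expected_calls* maps sample id to an arm frame with a ``call``
    column derived from noise-free truth; when given, per-sample
    sensitivity/specificity of the three-class calls is reported.
    """
    rows = []
    for sample_id, prof in arm_profiles.items():
        calls = prof["call"].to_numpy()
        n_gain = int((calls == "gain").sum())
        n_loss = int((calls == "loss").sum())
        row: dict = {
            "sample": sample_id,
            "entity": (entities or {}).get(sample_id, ""),
            "n_gain": n_gain,
            "n_loss": n_loss,
        }
        if expected_calls and sample_id in expected_calls:
            merged = prof.merge(
                expected_calls[sample_id], on="arm", suffixes=("", "_true")
            )
            truth = merged["call_true"].to_numpy()
            called = merged["call"].to_numpy()
            altered = truth != "neutral"
            row["sensitivity"] = (
                float((called[altered] == truth[altered]).mean()) if altered.any() else np.nan
            )
            row["specificity"] = (
                float((called[~altered] == "neutral").mean()) if (~altered).any() else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
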