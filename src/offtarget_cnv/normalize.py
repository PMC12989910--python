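"""Coverage normalisation, GC bias correction and the pooled reference.

The two capture streams differ by orders of magnitude in efficiency, so
target and antitarget bins are normalised separately (log2 of observed
over length-proportional expected counts, median-centred) and only then
merged.  A rolling median across GC-ordered bins removes residual GC
bias; a pooled reference built from flat-profile samples cancels
whatever systematic structure survives and provides the per-bin spread
used to weight downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .coverage import CoverageProfile
from .genome import AUTOSOMES

__all__ = [
    "weighted_median",
    "normalize_log2",
    "correct_gc_bias",
    "normalize_sample",
    "Reference",
    "build_reference",
    "RatioProfile",
    "to_ratio_profile",
]


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Smallest value v with cumulative weight(x <= v) >= half the total."""
    order = np.argsort(values, kind="stable")
    cw = np.cumsum(weights[order])
    idx = int(np.searchsorted(cw, 0.5 * cw[-1]))
    return float(values[order][min(idx, len(values) - 1)])


def normalize_log2(
    coverage: CoverageProfile | np.ndarray,
    bins: pd.DataFrame,
) -> np.ndarray:
    """Per-bin log2 of observed over length-expected counts, per stream.

    Within each bin type the expected count is the stream total spread
    proportional to bin length; a 0.5 pseudocount keeps empty bins
    finite, and each stream is centred so its length-weighted median
    (autosomal bins) is zero before the streams are merged.
    """
    counts = coverage.count if isinstance(coverage, CoverageProfile) else np.asarray(coverage)
    if len(counts) != len(bins):
        raise ValueError("coverage is not aligned to the bin table")
    if counts.sum() == 0:
        raise ValueError("all-zero coverage")
    length = (bins["end"] - bins["start"]).to_numpy().astype(float)
    bin_type = bins["bin_type"].to_numpy()
    autosomal = bins["chromosome"].isin(AUTOSOMES).to_numpy()
    out = np.zeros(len(bins), dtype=float)
    for stream in ("target", "antitarget"):
        sel = bin_type == stream
        if not sel.any():
            continue
        c = counts[sel].astype(float)
        expected = c.sum() * length[sel] / length[sel].sum()
        log2 = np.log2((c + 0.5) / (expected + 0.5))
        auto_rel = autosomal[sel]
        center_on = auto_rel if auto_rel.any() else np.ones(len(log2), dtype=bool)
        center = weighted_median(log2[center_on], length[sel][center_on])
        out[sel] = log2 - center
    return out


def correct_gc_bias(
    log2: np.ndarray, gc: np.ndarray, window: int = 101
) -> np.ndarray:
    """Subtract a rolling median of log2 across GC-ordered bins.

    Bins are ordered by GC, the windowed median trend is removed, and the
    original order is restored; edge windows are truncated.  If there are
    fewer bins than the window, the window shrinks (with a warning).
    """
    log2 = np.asarray(log2, dtype=float)
    gc = np.asarray(gc, dtype=float)
    n = len(log2)
    if np.isnan(gc).any():
        raise ValueError("GC must be annotated on all bins")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if n < window:
        window = max(1, n if n % 2 else n - 1)
        warnings.warn(f"fewer bins than GC window; shrunk to {window}")
    order = np.argsort(gc, kind="stable")
    trend = (
        pd.Series(log2[order])
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    corrected = np.empty(n, dtype=float)
    corrected[order] = log2[order] - trend
    return corrected


def normalize_sample(
    coverage: CoverageProfile,
    bins: pd.DataFrame,
    config: AnalysisConfig | None = None,
    gc_correct: bool = True,
) -> np.ndarray:
    """Normalise (and optionally GC-correct) one sample, per stream.

    Rolling-median GC correction is unconditionally safe on copy-neutral
    profiles and is applied to every reference-pool sample; for tumour
    samples the trend estimate absorbs copy-number signal in heavily
    aneuploid genomes (altered bins shift the windowed medians), so the
    calling pipeline leaves tumour profiles uncorrected and lets the
    pooled reference cancel the design-shared GC bias instead.
    """
    config = config or AnalysisConfig()
    log2 = normalize_log2(coverage, bins)
    if not gc_correct:
        return log2
    gc = bins["gc"].to_numpy()
    bin_type = bins["bin_type"].to_numpy()
    out = log2.copy()
    for stream in ("target", "antitarget"):
        sel = bin_type == stream
        if sel.sum() >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[sel] = correct_gc_bias(log2[sel], gc[sel], config.gc_window)
    return out


@dataclass
class Reference:
    """Pooled reference: per-bin expected log2, spread and mask."""

    log2: np.ndarray
    spread: np.ndarray
    mask: np.ndarray  # True -> bin excluded downstream
    n_samples: int = 0

    def __post_init__(self) -> None:
        if not (len(self.log2) == len(self.spread) == len(self.mask)):
            raise ValueError("reference arrays are not aligned")

    def frame(self, bins: pd.DataFrame) -> pd.DataFrame:
        """Reference in the .cnn layout (masked bins keep their row)."""
        out = bins[["chromosome", "start", "end", "gene"]].copy()
        out["log2"] = self.log2
        out["depth"] = 0.0
        out["spread"] = self.spread
        return out


def build_reference(
    normalized_log2: list[np.ndarray],
    counts: list[np.ndarray],
    bins: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> Reference:
    """Pool >= 2 flat-profile samples into a per-bin reference.

    Expected log2 is the across-pool mean; spread is 1.4826 x the median
    absolute deviation.  Bins with fewer than ``ref_min_pooled_reads``
    pooled reads or spread above ``ref_max_spread`` are masked.
    """
    config = config or AnalysisConfig()
    if len(normalized_log2) < 2:
        raise ValueError("a pooled reference needs at least 2 samples")
    stack = np.vstack(normalized_log2)
    if stack.shape[1] != len(bins):
        raise ValueError("profiles are not aligned to the bin table")
    expected = stack.mean(axis=0)
    med = np.median(stack, axis=0)
    spread = 1.4826 * np.median(np.abs(stack - med), axis=0)
    pooled_counts = np.sum(np.vstack(counts), axis=0)
    mask = (pooled_counts < config.ref_min_pooled_reads) | (spread > config.ref_max_spread)
    return Reference(expected, spread, mask, n_samples=len(normalized_log2))


@dataclass
class RatioProfile:
    """Per-bin log2 copy ratios with weights (.cnr model), masked bins dropped."""

    sample_id: str
    bins: pd.DataFrame  # unmasked bin rows, index reset
    log2: np.ndarray
    weight: np.ndarray
    depth: np.ndarray | None = None

    def frame(self) -> pd.DataFrame:
        out = self.bins[["chromosome", "start", "end", "gene"]].copy()
        out["log2"] = self.log2
        out["depth"] = self.depth if self.depth is not None else 0.0
        out["weight"] = self.weight
        return out


def to_ratio_profile(
    sample_log2: np.ndarray,
    reference: Reference,
    bins: pd.DataFrame,
    config: AnalysisConfig | None = None,
    sample_id: str = "sample",
    depth: np.ndarray | None = None,
) -> RatioProfile:
    """Subtract the reference and weight bins by inverse reference variance.

    Weight = 1 / (spread^2 + w0), rescaled to a maximum of 1; the merged
    profile is re-centred so the length-weighted median of autosomal bins
    is zero.
    """
    config = config or AnalysisConfig()
    if len(sample_log2) != len(bins) or len(reference.log2) != len(bins):
        raise ValueError("sample, reference and bins are not aligned")
    keep = ~reference.mask
    ratio = (np.asarray(sample_log2) - reference.log2)[keep]
    weight = 1.0 / (reference.spread[keep] ** 2 + config.weight_floor)
    weight = weight / weight.max()
    kept_bins = bins.loc[keep].reset_index(drop=True)
    autosomal = kept_bins["chromosome"].isin(AUTOSOMES).to_numpy()
    if autosomal.any():
        length = (kept_bins["end"] - kept_bins["start"]).to_numpy().astype(float)
        ratio = ratio - weighted_median(ratio[autosomal], length[autosomal])
    return RatioProfile(
        sample_id,
        kept_bins,
        ratio,
        weight,
        depth=np.asarray(depth)[keep] if depth is not None else None,
    )
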