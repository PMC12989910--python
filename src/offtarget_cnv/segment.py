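"""Circular binary segmentation with a seeded permutation test.

Per chromosome the bin sequence is treated as a circle; the candidate
split is the arc (i, j] maximising a weighted two-sample statistic

    T(i, j) = |mean_in - mean_out| / sqrt(1/W_in + 1/W_out)

between the bins inside and outside the arc (W = sum of bin weights; a
wrapping arc is the complement of a non-wrapping one and scores
identically, so linear slices of every length cover all circular
partitions).  The split is accepted when T exceeds the
(1 - alpha) empirical quantile of the same maximised statistic under
random permutations of the (value, weight) pairs, then the procedure
recurses on the resulting pieces.  Adjacent segments whose means are
statistically indistinguishable -- gap z-score below 3 x the robust
(MAD-based) bin-residual sigma in the weighted metric -- are merged at
the end.

For tractability at genome scale the maximisation -- identically for the
observed data and for every permutation, which keeps the test exact --
runs over a restricted arc-length grid: every length up to 32 bins (and
the mirror-image lengths near n, where the outside group is small), then
a 1.25x geometric grid.  Sequences of 64 bins or fewer are searched
exhaustively, and accepted splits on longer sequences are refined by an
exhaustive search between the neighbouring grid lengths, so reported
breakpoints match the brute-force argmax.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .normalize import RatioProfile

__all__ = ["segment_cbs", "max_arc_stat", "SEGMENT_COLUMNS"]

SEGMENT_COLUMNS = ["chromosome", "start", "end", "num_bins", "seg_mean", "weight"]

#: below this many bins the arc search is exhaustive.
_EXACT_N = 64
_GRID_DENSE = 32
_GRID_FACTOR = 1.25
_PERM_BLOCK = 250


def _arc_lengths(n: int) -> np.ndarray:
    """Arc lengths searched for an n-bin sequence.

    Linear slices of every length 1..n-1 cover all circular partitions: a
    wrapping arc is the complement of a non-wrapping one and yields the
    same two-sample statistic.
    """
    kmax = n - 1
    if n <= _EXACT_N:
        return np.arange(1, max(kmax, 1) + 1)
    ks = list(range(1, _GRID_DENSE + 1))
    k = _GRID_DENSE
    while k < kmax:
        k = max(k + 1, int(k * _GRID_FACTOR))
        ks.append(min(k, kmax))
    # mirror the dense small-arc lengths at the complement end, where the
    # outside group is small
    ks.extend(range(max(n - _GRID_DENSE, 1), kmax + 1))
    return np.unique(ks)


def _stat_for_k(S: np.ndarray, W: np.ndarray, k: int) -> np.ndarray:
    """T(i, i+k) for all start offsets i; S, W are zero-padded cumsums."""
    total, wtot = S[..., -1:], W[..., -1:]
    sum_in = S[..., k:] - S[..., :-k]
    w_in = W[..., k:] - W[..., :-k]
    w_out = wtot - w_in
    valid = (w_in > 0) & (w_out > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = sum_in / w_in - (total - sum_in) / w_out
        t = np.abs(diff) / np.sqrt(1.0 / w_in + 1.0 / w_out)
    t[~valid] = 0.0
    return t


def max_arc_stat(
    values: np.ndarray,
    weights: np.ndarray,
    ks: np.ndarray | None = None,
) -> tuple[float, int, int]:
    """Best arc (i, j] by the weighted two-sample statistic.

    Returns ``(stat, i, j)`` with the arc covering bins ``i..j-1``.
    With *ks* omitted the search covers every arc length up to n - 1.
    """
    n = len(values)
    if ks is None:
        ks = np.arange(1, n)
    S = np.concatenate([[0.0], np.cumsum(weights * values)])
    W = np.concatenate([[0.0], np.cumsum(weights)])
    best = (0.0, 0, min(1, n))
    for k in ks:
        t = _stat_for_k(S, W, int(k))
        i = int(np.argmax(t))
        if t[i] > best[0]:
            best = (float(t[i]), i, i + int(k))
    return best


def _refine_split(
    values: np.ndarray, weights: np.ndarray, k_best: int, ks: np.ndarray
) -> tuple[float, int, int]:
    """Exhaustive re-search between the grid lengths flanking k_best."""
    n = len(values)
    pos = int(np.searchsorted(ks, k_best))
    lo = int(ks[pos - 1]) + 1 if pos > 0 else 1
    hi = int(ks[pos + 1]) - 1 if pos + 1 < len(ks) else n - 1
    local = np.arange(max(1, lo - 1), min(n - 1, hi + 1) + 1)
    return max_arc_stat(values, weights, local)


def _perm_max_stats(
    values: np.ndarray,
    weights: np.ndarray,
    ks: np.ndarray,
    nperm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Max arc statistic for each of *nperm* joint (value, weight) permutations."""
    n = len(values)
    idx = rng.permuted(np.tile(np.arange(n), (nperm, 1)), axis=1)
    v, w = values[idx], weights[idx]
    zeros = np.zeros((nperm, 1))
    S = np.concatenate([zeros, np.cumsum(w * v, axis=1)], axis=1)
    W = np.concatenate([zeros, np.cumsum(w, axis=1)], axis=1)
    out = np.zeros(nperm)
    for k in ks:
        t = _stat_for_k(S, W, int(k))
        np.maximum(out, t.max(axis=1), out=out)
    return out


def _split_significant(
    values: np.ndarray,
    weights: np.ndarray,
    observed: float,
    ks: np.ndarray,
    config: AnalysisConfig,
    rng: np.random.Generator,
) -> bool:
    """Permutation test with early futility stopping.

    Significance requires fewer than ceil(alpha * nperm) permutation maxima
    at or above the observed statistic; once that many exceedances have
    accumulated the outcome is settled and remaining permutations are
    skipped (the decision is identical to running all of them).
    """
    threshold = int(np.ceil(config.cbs_alpha * config.cbs_nperm))
    exceed = 0
    done = 0
    while done < config.cbs_nperm:
        block = min(_PERM_BLOCK, config.cbs_nperm - done)
        stats = _perm_max_stats(values, weights, ks, block, rng)
        exceed += int((stats >= observed).sum())
        done += block
        if exceed >= threshold:
            return False
    return True


def _segment_bounds(
    values: np.ndarray,
    weights: np.ndarray,
    config: AnalysisConfig,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome; returns half-open bin index ranges."""
    n = len(values)
    out: list[tuple[int, int]] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        m = hi - lo
        if m < 4:
            out.append((lo, hi))
            continue
        v, w = values[lo:hi], weights[lo:hi]
        ks = _arc_lengths(m)
        stat, i, j = max_arc_stat(v, w, ks)
        if stat <= 0 or not _split_significant(v, w, stat, ks, config, rng):
            out.append((lo, hi))
            continue
        if m > _EXACT_N:
            _, i, j = _refine_split(v, w, j - i, ks)
        cuts = [c for c in (i, j) if 0 < c < m]
        if not cuts:
            out.append((lo, hi))
            continue
        edges = [0] + cuts + [m]
        for a, b in zip(edges, edges[1:]):
            stack.append((lo + a, lo + b))
    return sorted(out)


#: z-score below which adjacent segment means are considered one level.
_MERGE_Z = 3.0


def _merge_adjacent(
    bounds: list[tuple[int, int]],
    values: np.ndarray,
    weights: np.ndarray,
    sigma_w: float,
) -> list[tuple[int, int]]:
    """Merge neighbouring segments whose means are statistically one level.

    The gap between adjacent segments is scored in the same weighted
    metric as the split statistic, z = |m1 - m2| / sqrt(1/W1 + 1/W2), and
    compared against ``_MERGE_Z`` x the robust per-unit-weight residual
    sigma -- i.e. the merge test scales with the segments' standard
    errors, so broad segments merge on tiny mean differences while short
    high-amplitude events are never absorbed.
    """

    def wstats(lo: int, hi: int) -> tuple[float, float]:
        w = weights[lo:hi]
        return float(np.sum(w * values[lo:hi]) / np.sum(w)), float(np.sum(w))

    bounds = sorted(bounds)
    while len(bounds) > 1:
        stats = [wstats(lo, hi) for lo, hi in bounds]
        zs = [
            abs(stats[i + 1][0] - stats[i][0])
            / np.sqrt(1.0 / stats[i][1] + 1.0 / stats[i + 1][1])
            for i in range(len(stats) - 1)
        ]
        i = int(np.argmin(zs))
        if zs[i] >= _MERGE_Z * sigma_w:
            break
        bounds[i] = (bounds[i][0], bounds[i + 1][1])
        del bounds[i + 1]
    return bounds


def segment_cbs(
    ratio: RatioProfile | pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Segment a ratio profile chromosome by chromosome.

    Returns a frame with ``chromosome, start, end, num_bins, seg_mean,
    weight`` (weight = summed bin weights); every bin belongs to exactly
    one segment.  Deterministic for a fixed ``config.rng_seed``.
    """
    config = config or AnalysisConfig()
    if isinstance(ratio, RatioProfile):
        frame = ratio.frame()
    else:
        frame = ratio.copy()
        if "weight" not in frame.columns:
            frame["weight"] = 1.0
    rng = np.random.default_rng(config.rng_seed)
    rows = []
    for chrom in frame["chromosome"].unique():
        sub = frame[frame["chromosome"] == chrom]
        values = sub["log2"].to_numpy(dtype=float)
        weights = np.maximum(sub["weight"].to_numpy(dtype=float), 1e-9)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        bounds = _segment_bounds(values, weights, config, rng)
        # robust per-unit-weight residual sigma for the merge step
        seg_mean_per_bin = np.empty(len(values))
        for lo, hi in bounds:
            w = weights[lo:hi]
            seg_mean_per_bin[lo:hi] = np.sum(w * values[lo:hi]) / np.sum(w)
        resid = np.sqrt(weights) * (values - seg_mean_per_bin)
        sigma_w = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
        bounds = _merge_adjacent(bounds, values, weights, sigma_w)
        for lo, hi in bounds:
            w = weights[lo:hi]
            rows.append(
                (
                    chrom,
                    int(starts[lo]),
                    int(ends[hi - 1]),
                    hi - lo,
                    float(np.sum(w * values[lo:hi]) / np.sum(w)),
                    float(np.sum(w)),
                )
            )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
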