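"""Genome binning and read counting.

The bin table is the central in-memory container: a pandas DataFrame with
columns ``chromosome, start, end, gene, bin_type, gc``, sorted in genome
order.  Target bins are the capture-panel intervals verbatim (the panel is
tiny, < 0.2 Mb, so sub-splitting buys nothing); antitarget bins tile the
rest of each chromosome, clear of a safety margin around every target, in
roughly equal-width windows.  Off-target reads falling into antitarget
bins carry the genome-wide copy-number signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .genome import CHROM_LENGTHS, GenomicInterval, chrom_sort_key

__all__ = [
    "BIN_COLUMNS",
    "CoverageProfile",
    "build_bins",
    "count_reads_in_bins",
    "annotate_gc_simulated",
    "read_coverage_table",
    "write_coverage_table",
]

BIN_COLUMNS = ["chromosome", "start", "end", "gene", "bin_type", "gc"]

#: nominal read length used to express counts as mean depth.
READ_LENGTH = 150


@dataclass
class CoverageProfile:
    """Per-bin read counts for one sample, aligned to a bin table."""

    sample_id: str
    count: np.ndarray
    din: float
    unassigned_reads: int = 0

    def __post_init__(self) -> None:
        self.count = np.asarray(self.count, dtype=np.int64)
        if (self.count < 0).any():
            raise ValueError("negative bin counts")

    def totals(self, bins: pd.DataFrame) -> tuple[int, int, int]:
        """(total, on-target, off-target) assigned read counts."""
        on = int(self.count[(bins["bin_type"] == "target").to_numpy()].sum())
        off = int(self.count[(bins["bin_type"] == "antitarget").to_numpy()].sum())
        return on + off, on, off

    def depth(self, bins: pd.DataFrame) -> np.ndarray:
        """Mean per-base depth per bin for a nominal 150 bp read."""
        length = (bins["end"] - bins["start"]).to_numpy()
        return self.count * READ_LENGTH / length


def _merge_padded(intervals: list[tuple[int, int]], margin: int, chrom_len: int):
    """Merge margin-padded intervals, clipped to the chromosome."""
    padded = sorted(
        (max(0, s - margin), min(chrom_len, e + margin)) for s, e in intervals
    )
    merged: list[list[int]] = []
    for s, e in padded:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def build_bins(
    genome: dict[str, int] | None,
    panel: list[tuple[GenomicInterval, str]],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Build the target/antitarget bin table for *genome* (default hg19).

    Antitarget bins: each chromosome minus the margin-padded panel is cut,
    per contiguous accessible region, into ``floor(region/avg)`` windows of
    width ``antitarget_avg_size``; the last window absorbs the remainder,
    and regions shorter than one window are dropped.  GC content is left
    NaN until annotated.
    """
    config = config or AnalysisConfig()
    genome = CHROM_LENGTHS if genome is None else genome
    if not panel:
        raise ValueError("empty panel")
    total_panel = sum(iv.length for iv, _ in panel)
    if total_panel > 1_000_000:
        warnings.warn(
            f"panel spans {total_panel} bp; expected a small (<1 Mb) design"
        )
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv, label in panel:
        if iv.chrom not in genome:
            raise ValueError(f"panel chromosome {iv.chrom!r} absent from genome")
        iv.validate_against(genome)
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    rows: list[tuple] = []
    # target bins: panel intervals verbatim
    for iv, label in sorted(panel, key=lambda r: (chrom_sort_key(r[0].chrom), r[0].start)):
        rows.append((iv.chrom, iv.start, iv.end, label, "target"))
    # antitarget bins
    avg = config.antitarget_avg_size
    for chrom in sorted(genome, key=chrom_sort_key):
        chrom_len = genome[chrom]
        blocked = _merge_padded(by_chrom.get(chrom, []), config.antitarget_margin, chrom_len)
        cursor = 0
        regions = []
        for s, e in blocked:
            if s > cursor:
                regions.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < chrom_len:
            regions.append((cursor, chrom_len))
        for rs, re_ in regions:
            nfull = (re_ - rs) // avg
            if nfull == 0:
                continue
            starts = rs + avg * np.arange(nfull)
            ends = starts + avg
            ends[-1] = re_  # last bin absorbs the remainder
            for s, e in zip(starts, ends):
                rows.append((chrom, int(s), int(e), "Antitarget", "antitarget"))

    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "gene", "bin_type"])
    df["gc"] = np.nan
    df = df.sort_values(
        by=["chromosome", "start"],
        key=lambda col: col.map(chrom_sort_key) if col.name == "chromosome" else col,
        kind="stable",
    ).reset_index(drop=True)
    return df


def annotate_gc_simulated(
    bins: pd.DataFrame,
    rng: np.random.Generator,
    mean: float = 0.41,
    sd: float = 0.05,
) -> pd.DataFrame:
    """Draw per-bin GC fractions from a Beta matched to *mean*/*sd*.

    GC is treated throughout as an input annotation of the capture design;
    simulating it avoids any dependence on a genome FASTA.  The draw is a
    property of the bin table (one draw per design), not of samples.
    """
    kappa = mean * (1 - mean) / sd**2 - 1
    a, b = mean * kappa, (1 - mean) * kappa
    bins = bins.copy()
    bins["gc"] = rng.beta(a, b, size=len(bins))
    return bins


def count_reads_in_bins(
    reads: pd.DataFrame | list[tuple[str, int]],
    bins: pd.DataFrame,
    sample_id: str = "sample",
    din: float = float("nan"),
) -> CoverageProfile:
    """Assign each read to the unique bin containing its start position.

    Reads starting in no bin (target margins, sub-window leftovers) are
    counted as unassigned, never dropped silently:
    assigned + unassigned == number of input reads.
    """
    if isinstance(reads, list):
        reads = pd.DataFrame(reads, columns=["chromosome", "start"])
    counts = np.zeros(len(bins), dtype=np.int64)
    unassigned = 0
    bin_chrom = bins["chromosome"].to_numpy()
    bin_start = bins["start"].to_numpy()
    bin_end = bins["end"].to_numpy()
    for chrom, grp in reads.groupby("chromosome", sort=False):
        sel = np.flatnonzero(bin_chrom == chrom)
        pos = grp["start"].to_numpy()
        if sel.size == 0:
            unassigned += len(pos)
            continue
        starts, ends = bin_start[sel], bin_end[sel]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        unassigned += int((~ok).sum())
        if ok.any():
            np.add.at(counts, sel[idx[ok]], 1)
    return CoverageProfile(sample_id, counts, din, unassigned)


def write_coverage_table(
    profile: CoverageProfile, bins: pd.DataFrame, path
) -> None:
    """Persist one sample's bin counts with its metadata as '#' header lines."""
    with open(path, "w") as fh:
        fh.write(f"# sample\t{profile.sample_id}\n")
        fh.write(f"# din\t{profile.din:.3f}\n")
        fh.write(f"# unassigned\t{profile.unassigned_reads}\n")
        out = bins[["chromosome", "start", "end", "gene", "bin_type", "gc"]].copy()
        out["count"] = profile.count
        out.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_coverage_table(path) -> tuple[CoverageProfile, pd.DataFrame]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            parts = line[1:].strip().split("\t")
            meta[parts[0]] = parts[1] if len(parts) > 1 else ""
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    bins = df[["chromosome", "start", "end", "gene", "bin_type", "gc"]]
    profile = CoverageProfile(
        meta.get("sample", "sample"),
        df["count"].to_numpy(),
        float(meta.get("din", "nan")),
        int(meta.get("unassigned", 0)),
    )
    return profile, bins
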