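"""Readers and writers for the tabular formats the pipeline touches.

Dialects
--------
``cnn``
    pooled reference: chromosome, start, end, gene, log2, depth, spread
``cnr``
    per-bin copy ratios: chromosome, start, end, gene, log2, depth, weight
``seg``
    segments: sample, chromosome, start, end, num_bins, seg_mean
    (written 1-based inclusive, the IGV convention; everything else is
    0-based half-open)
``igv``
    array-style bin profiles: chromosome, start, end, feature plus one
    value column per sample
``truth``
    simulator truth: sample, entity, histological_grade, purity, din,
    tertp_mutant, chromosome, start, end, copy_number (one row per
    constant-copy-number event; a sample without events appears once with
    an empty chromosome field)

All log2-like floats are written with 6 decimal places, so write/read
round-trips agree to 1e-6.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .genome import CHROM_LENGTHS, GenomicInterval

__all__ = [
    "DIALECT_COLUMNS",
    "read_bed",
    "write_bed",
    "write_profile_table",
    "read_profile_table",
]

DIALECT_COLUMNS: dict[str, list[str]] = {
    "cnn": ["chromosome", "start", "end", "gene", "log2", "depth", "spread"],
    "cnr": ["chromosome", "start", "end", "gene", "log2", "depth", "weight"],
    "seg": ["sample", "chromosome", "start", "end", "num_bins", "seg_mean"],
    "igv": ["chromosome", "start", "end", "feature"],  # + one column per sample
    "truth": [
        "sample", "entity", "histological_grade", "purity", "din",
        "tertp_mutant", "chromosome", "start", "end", "copy_number",
    ],
}

_INT_COLS = {"start", "end", "num_bins", "copy_number"}


def read_bed(
    path: str | Path,
    genome: dict[str, int] | None = None,
) -> list[tuple[GenomicInterval, str]]:
    """Parse a BED file into ``(interval, label)`` pairs, order preserved.

    Intervals are 0-based half-open.  Records with inverted coordinates or
    chromosomes absent from *genome* (default: hg19) are rejected with a
    warning rather than aborting the run.
    """
    genome = CHROM_LENGTHS if genome is None else genome
    path = Path(path)
    records: list[tuple[GenomicInterval, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                warnings.warn(f"{path}:{lineno}: fewer than 3 columns, skipped")
                continue
            chrom, start_s, end_s = fields[:3]
            label = fields[3] if len(fields) > 3 else "."
            try:
                start, end = int(start_s), int(end_s)
                iv = GenomicInterval(chrom, start, end)
                iv.validate_against(genome)
            except ValueError as exc:
                warnings.warn(f"{path}:{lineno}: rejected record ({exc})")
                continue
            records.append((iv, label))
    return records


def write_bed(records: list[tuple[GenomicInterval, str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for iv, label in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


def _check_schema(df: pd.DataFrame, dialect: str) -> None:
    if dialect not in DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    required = DIALECT_COLUMNS[dialect]
    if dialect == "igv":
        if list(df.columns[:4]) != required or df.shape[1] < 5:
            raise ValueError(
                f"igv schema mismatch: expected {required} + >=1 sample column, "
                f"found {list(df.columns)}"
            )
    elif list(df.columns) != required:
        raise ValueError(
            f"{dialect} schema mismatch: expected {required}, found {list(df.columns)}"
        )


def write_profile_table(df: pd.DataFrame, path: str | Path, dialect: str) -> None:
    """Write *df* as a tab-separated table in the given dialect.

    ``seg`` starts are shifted +1 on the way out (1-based inclusive); all
    other dialects are written as stored (0-based half-open).
    """
    _check_schema(df, dialect)
    out = df.copy()
    if dialect == "seg" and len(out):
        out["start"] = out["start"] + 1
    for col in out.columns:
        if col in _INT_COLS and len(out):
            out[col] = out[col].astype("int64")
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_profile_table(path: str | Path, dialect: str) -> pd.DataFrame:
    """Inverse of :func:`write_profile_table` (round-trip up to 1e-6 on floats)."""
    path = Path(path)
    header = pd.read_csv(path, sep="\t", nrows=0).columns.tolist()
    required = DIALECT_COLUMNS.get(dialect)
    if required is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "igv":
        if header[:4] != required or len(header) < 5:
            raise ValueError(
                f"header mismatch for igv: expected {required} + sample "
                f"columns, found {header}"
            )
    elif header != required:
        raise ValueError(
            f"header mismatch for {dialect}: expected {required}, found {header}"
        )
    df = pd.read_csv(path, sep="\t")
    if dialect == "seg" and len(df):
        df["start"] = df["start"] - 1
    if dialect == "truth":
        # samples without events carry empty interval fields
        df["chromosome"] = df["chromosome"].fillna("")
    return df
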