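"""hg19 coordinate model: chromosomes, arms and gene annotations.

All intervals in this package are 0-based, half-open (BED convention).
The only 1-based surface anywhere is the ``.seg`` writer in
:mod:`offtarget_cnv.tables`.

Chromosome-arm boundaries are shipped as a packaged fixture derived from
the UCSC ``cytoBand`` table for hg19 (the p/q split is the boundary
between the two pericentromeric ``acen`` bands).  Arm-level analyses use
the 39 "comparable" autosomal arms: all 44 autosomal arms minus the five
acrocentric p-arms (13p, 14p, 15p, 21p, 22p), whose short arms carry no
usable copy-number signal; sex-chromosome arms are never comparable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

__all__ = [
    "GenomicInterval",
    "ChromArm",
    "GeneAnnotation",
    "ConfigurationError",
    "CHROM_LENGTHS",
    "CHROMOSOMES",
    "AUTOSOMES",
    "BAND_7Q34",
    "arm_table_hg19",
    "comparable_arms",
    "arm_by_name",
    "gene_table",
    "gene_by_symbol",
    "chrom_sort_key",
]


class ConfigurationError(RuntimeError):
    """A packaged fixture or configuration file is missing or corrupt."""


#: hg19 chromosome lengths (GRCh37 primary assembly).
CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
    "chrX": 155_270_560,
    "chrY": 59_373_566,
}

CHROMOSOMES: tuple[str, ...] = tuple(CHROM_LENGTHS)
AUTOSOMES: tuple[str, ...] = CHROMOSOMES[:22]
_CHROM_INDEX = {c: i for i, c in enumerate(CHROMOSOMES)}

#: hg19 cytoband 7q34 (KIAA1549/BRAF region), used by the fusion indicator.
BAND_7Q34: tuple[int, int] = (138_200_000, 143_100_000)


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Sort key putting chr1..chr22, chrX, chrY in genome order."""
    return (_CHROM_INDEX.get(chrom, len(CHROMOSOMES)), chrom)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with *other* (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def validate_against(self, genome: dict[str, int]) -> None:
        """Raise ``ValueError`` unless the interval fits inside *genome*."""
        if self.chrom not in genome:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > genome[self.chrom]:
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end} exceeds chromosome "
                f"length {genome[self.chrom]}"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class ChromArm:
    """One chromosome arm; ``comparable`` marks arms used in arm-level calls."""

    chrom: str
    arm: str  # "p" or "q"
    span: GenomicInterval
    comparable: bool

    @property
    def name(self) -> str:
        """Short arm name, e.g. ``1p`` or ``22q``."""
        return f"{self.chrom[3:]}{self.arm}"

    @property
    def length(self) -> int:
        return self.span.length


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus; ``on_panel`` marks genes targeted by capture probes."""

    symbol: str
    locus: GenomicInterval
    on_panel: bool


def _data_text(name: str) -> str:
    try:
        ref = resources.files("offtarget_cnv") / "data" / name
        return ref.read_text()
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise ConfigurationError(f"packaged fixture {name!r} is missing") from exc


@lru_cache(maxsize=1)
def arm_table_hg19() -> tuple[ChromArm, ...]:
    """Chromosome arms for chr1-chr22, chrX, chrY from the packaged fixture.

    Arms tile each chromosome exactly (``p.end == q.start`` at the
    centromere boundary); acrocentric p-arms and sex-chromosome arms are
    flagged ``comparable=False``.
    """
    text = _data_text("hg19_arms.tsv")
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    expected_cols = {"chrom", "arm", "start", "end", "comparable"}
    if not rows or set(rows[0]) != expected_cols:
        raise ConfigurationError("hg19_arms.tsv has an unexpected layout")
    arms = []
    for row in rows:
        try:
            span = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
            arms.append(
                ChromArm(row["chrom"], row["arm"], span, row["comparable"] == "1")
            )
        except (KeyError, ValueError) as exc:
            raise ConfigurationError(f"corrupt arm fixture row: {row}") from exc
    # Fail loudly if the fixture does not tile the genome.
    by_chrom: dict[str, list[ChromArm]] = {}
    for a in arms:
        by_chrom.setdefault(a.chrom, []).append(a)
    for chrom, pair in by_chrom.items():
        if len(pair) != 2 or pair[0].arm != "p" or pair[1].arm != "q":
            raise ConfigurationError(f"{chrom}: expected exactly one p and one q arm")
        p, q = pair
        if p.span.start != 0 or p.span.end != q.span.start or q.span.end != CHROM_LENGTHS[chrom]:
            raise ConfigurationError(f"{chrom}: arms do not tile the chromosome")
    if set(by_chrom) != set(CHROMOSOMES):
        raise ConfigurationError("arm fixture does not cover chr1-chr22, chrX, chrY")
    return tuple(arms)


def comparable_arms() -> tuple[ChromArm, ...]:
    """The 39 autosomal arms used for arm-level classification."""
    return tuple(a for a in arm_table_hg19() if a.comparable)


def arm_by_name(name: str) -> ChromArm:
    for a in arm_table_hg19():
        if a.name == name:
            return a
    raise KeyError(f"unknown arm {name!r}")


@lru_cache(maxsize=1)
def gene_table() -> tuple[GeneAnnotation, ...]:
    """Curated hg19 gene loci: the diagnostic highlight list plus panel genes."""
    text = _data_text("genes_hg19.tsv")
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    genes = []
    for row in rows:
        try:
            locus = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
            locus.validate_against(CHROM_LENGTHS)
            genes.append(GeneAnnotation(row["symbol"], locus, row["on_panel"] == "1"))
        except (KeyError, ValueError) as exc:
            raise ConfigurationError(f"corrupt gene fixture row: {row}") from exc
    if not genes:
        raise ConfigurationError("gene fixture is empty")
    return tuple(genes)


def gene_by_symbol(symbol: str) -> GeneAnnotation:
    for g in gene_table():
        if g.symbol == symbol:
            return g
    raise KeyError(f"unknown gene {symbol!r}")
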