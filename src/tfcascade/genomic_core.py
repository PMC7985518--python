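"""Interval arithmetic, coordinate conventions and readers/writers for the
standard genomic formats consumed by the pipeline.

Conventions
-----------
* In-memory intervals are always **0-based, half-open** ``[start, end)``.
* BED files are read/written as-is (they share that convention).
* GTF files are 1-based inclusive and converted on read.
* A gene's TSS is its ``start`` on the ``+`` strand and ``end - 1`` on the
  ``-`` strand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "Gene",
    "REM",
    "DEGRecord",
    "ParseError",
    "read_bed",
    "write_bed",
    "read_gene_annotation",
    "write_gtf",
    "tss_window",
    "overlaps",
    "extract_sequence",
    "reverse_complement",
    "read_rem_table",
    "write_rem_table",
    "read_deg_table",
    "write_deg_table",
    "significant_genes",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        """Midpoint of the interval in bp (may be half-integral)."""
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Gene:
    """A gene locus with a strand-aware transcription start site."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    symbol: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid gene span [{self.start}, {self.end}) for {self.gene_id}"
            )

    @property
    def tss(self) -> int:
        """TSS position: ``start`` for '+' genes, ``end - 1`` for '-' genes."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def locus(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.gene_id)


@dataclass(frozen=True)
class REM:
    """A regulatory element linked to a target gene (EpiRegio-style)."""

    region: GenomicInterval
    rem_id: str
    linked_gene: str


@dataclass(frozen=True)
class DEGRecord:
    """One differential-expression call at one time point."""

    gene_id: str
    timepoint: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.padj <= 1.0:
            raise ValueError(f"padj must be in [0, 1], got {self.padj}")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+/BED6 file into a list of intervals.

    Track, browser and ``#`` comment lines are skipped.  Malformed data
    lines raise :class:`ParseError` naming the offending line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path} line {lineno}: expected >= 3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(
                        f"{path} line {lineno}: non-numeric score"
                    ) from exc
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name=name, score=score)
                )
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED; name/score columns included when present."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(repr(iv.score))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_annotation(path: str | Path) -> list[Gene]:
    """Read ``gene`` feature lines from a GTF file.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Records with an unknown strand are skipped with a warning; a missing
    ``gene_id`` attribute is a :class:`ParseError`.  If a ``gene_id``
    occurs more than once the first record wins.
    """
    genes: list[Gene] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path} line {lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from exc
            strand = fields[6]
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            if "gene_id" not in attrs:
                raise ParseError(f"{path} line {lineno}: missing gene_id attribute")
            if strand not in ("+", "-"):
                logger.warning(
                    "%s line %d: unknown strand %r for %s, record skipped",
                    path, lineno, strand, attrs["gene_id"],
                )
                continue
            if attrs["gene_id"] in seen:
                logger.warning(
                    "%s line %d: duplicate gene_id %s, keeping first record",
                    path, lineno, attrs["gene_id"],
                )
                continue
            seen.add(attrs["gene_id"])
            genes.append(
                Gene(
                    gene_id=attrs["gene_id"],
                    chrom=fields[0],
                    strand=strand,
                    start=start1 - 1,
                    end=end1,
                    symbol=attrs.get("gene_name"),
                )
            )
    return genes


def write_gtf(genes: Iterable[Gene], path: str | Path, source: str = "tfcascade") -> None:
    """Write genes as GTF ``gene`` feature lines (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            if g.symbol:
                attrs += f' gene_name "{g.symbol}";'
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        source,
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Window and overlap arithmetic
# ---------------------------------------------------------------------------

def tss_window(gene: Gene, half_width: int = 25_000) -> GenomicInterval:
    """Window of ``2 * half_width`` bp centred on the gene's TSS.

    The window is ``[max(0, tss - half_width), tss + half_width)`` and is
    clamped at the chromosome origin.
    """
    if half_width <= 0:
        raise ValueError(f"half_width must be > 0, got {half_width}")
    return GenomicInterval(
        gene.chrom,
        max(0, gene.tss - half_width),
        gene.tss + half_width,
        name=gene.gene_id,
    )


def overlaps(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> set[tuple[int, int]]:
    """All index pairs ``(i, j)`` with ``a[i]`` overlapping ``b[j]``.

    An overlap requires the same chromosome and an intersection of at
    least 1 bp under half-open semantics.
    """
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(b):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    pairs: set[tuple[int, int]] = set()
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            pairs.add((i, hit.data))
    return pairs


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def extract_sequence(fasta, interval: GenomicInterval) -> str:
    """Extract the uppercase sequence of ``interval`` from an indexed FASTA.

    ``fasta`` is a :class:`pyfaidx.Fasta` (or a path, opened on the fly).
    Soft-masked lowercase is promoted to uppercase.  Raises ``KeyError``
    for a missing chromosome and ``ValueError`` for out-of-bounds spans.
    """
    import pyfaidx

    if isinstance(fasta, (str, Path)):
        fasta = pyfaidx.Fasta(str(fasta))
    if interval.chrom not in fasta:
        raise KeyError(f"chromosome {interval.chrom!r} not in FASTA")
    chrom_len = len(fasta[interval.chrom])
    if interval.end > chrom_len:
        raise ValueError(
            f"interval [{interval.start}, {interval.end}) exceeds "
            f"{interval.chrom} length {chrom_len}"
        )
    return fasta[interval.chrom][interval.start : interval.end].seq.upper()


# ---------------------------------------------------------------------------
# Tabular REM / DEG tables
# ---------------------------------------------------------------------------

_REM_COLUMNS = ("chrom", "start", "end", "rem_id", "gene_id")


def read_rem_table(path: str | Path) -> list[REM]:
    """Read a tab-separated REM table: chrom, start, end, rem_id, gene_id.

    A header line (starting with ``#`` or with the literal column names)
    is optional.
    """
    rems: list[REM] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "chrom":  # header
                continue
            if len(fields) < 5:
                raise ParseError(
                    f"{path} line {lineno}: expected 5 columns {_REM_COLUMNS}"
                )
            try:
                region = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]), name=fields[3]
                )
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
            rems.append(REM(region=region, rem_id=fields[3], linked_gene=fields[4]))
    return rems


def write_rem_table(rems: Iterable[REM], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_REM_COLUMNS) + "\n")
        for rem in rems:
            fh.write(
                "\t".join(
                    [
                        rem.region.chrom,
                        str(rem.region.start),
                        str(rem.region.end),
                        rem.rem_id,
                        rem.linked_gene,
                    ]
                )
                + "\n"
            )


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table with columns
    ``gene_id``, ``log2fc``, ``padj`` (tab-separated, with header)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "log2fc", "padj"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad = df[(df["padj"] < 0) | (df["padj"] > 1)]
    if len(bad):
        raise ParseError(
            f"{path}: padj outside [0, 1] for genes {bad['gene_id'].tolist()[:5]}"
        )
    return df


def write_deg_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def significant_genes(deg: pd.DataFrame, padj_cutoff: float = 0.05) -> set[str]:
    """Gene ids significant at ``padj < padj_cutoff`` (strict inequality)."""
    return set(deg.loc[deg["padj"] < padj_cutoff, "gene_id"])
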