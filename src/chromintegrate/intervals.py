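"""Genomic interval algebra, genome annotation, and BED/TSV I/O.

Coordinates are 0-based half-open throughout (BED convention): an interval
``[start, end)`` covers bases ``start .. end-1``.  Two intervals overlap iff
they share at least one base (the 1-nt criterion), so ``[0,10)`` and
``[10,20)`` are adjacent, not overlapping.  Every downstream stage (peak
consensus, bivalency, enhancer classes, CpG assignment) uses this single
overlap definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "Gene",
    "GenomeAnnotation",
    "overlaps",
    "merge_union",
    "fraction_overlapping",
    "nearest_tss",
    "read_bed",
    "write_bed",
    "read_genes_tsv",
    "write_genes_tsv",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional score and q-value."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    qvalue: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.score is not None and self.score < 0:
            raise ValueError("score must be nonnegative")
        if self.qvalue is not None and not (0.0 <= self.qvalue <= 1.0):
            raise ValueError("qvalue must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class PeakSet:
    """An ordered collection of intervals (peaks/regions) with a label.

    Intervals are kept sorted by (chrom, start).  A PeakSet produced by
    :func:`merge_union` additionally contains no overlapping intervals.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = ""):
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self.label = label

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __repr__(self) -> str:
        return f"PeakSet({len(self)} intervals, label={self.label!r})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return [(i.chrom, i.start, i.end) for i in self.intervals] == [
            (i.chrom, i.start, i.end) for i in other.intervals
        ]

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees for overlap queries."""
        trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        return trees

    def total_span(self) -> int:
        """Total bp covered, counting overlapping regions once."""
        return sum(iv.length for iv in merge_union(self))


class Gene(NamedTuple):
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int
    tes: int
    tx_length: int


@dataclass
class GenomeAnnotation:
    """Chromosome sizes, gene models, CpG islands, and optional enhancer marks."""

    chrom_sizes: dict[str, int]
    genes: list[Gene] = field(default_factory=list)
    cpg_islands: PeakSet = field(default_factory=PeakSet)
    enhancer_marks: dict[str, PeakSet] | None = None

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise ValueError(f"gene {g.gene_id} on unknown chrom {g.chrom}")
            size = self.chrom_sizes[g.chrom]
            lo, hi = min(g.tss, g.tes), max(g.tss, g.tes)
            if lo < 0 or hi >= size:
                raise ValueError(f"gene {g.gene_id} outside chromosome bounds")
            if g.strand not in "+-":
                raise ValueError(f"gene {g.gene_id} has invalid strand {g.strand!r}")
            if g.tx_length <= 0:
                raise ValueError(f"gene {g.gene_id} has nonpositive length")

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    def gene_lengths(self) -> dict[str, int]:
        return {g.gene_id: g.tx_length for g in self.genes}


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff a and b share >= 1 base under half-open coordinates."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge_union(peaks: PeakSet, gap: int = 0) -> PeakSet:
    """Union of intervals; stretches separated by <= gap bp are joined.

    The result is the minimal sorted, non-overlapping cover of the input.
    Idempotent for any fixed gap.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    merged: list[GenomicInterval] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    for iv in peaks.intervals:  # already sorted
        if iv.chrom != cur_chrom or iv.start > cur_end + gap:
            if cur_chrom is not None:
                merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
        else:
            cur_end = max(cur_end, iv.end)
    if cur_chrom is not None:
        merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return PeakSet(merged, label=peaks.label)


def fraction_overlapping(a: PeakSet, b: PeakSet) -> tuple[int, int, float]:
    """(count, total, fraction) of intervals in `a` hitting >= 1 interval of `b`."""
    if len(a) == 0:
        raise ValueError("empty query set")
    trees = b.trees()
    count = 0
    for iv in a:
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            count += 1
    return count, len(a), count / len(a)


def overlap_flags(a: PeakSet, b: PeakSet) -> list[bool]:
    """Per-interval flag for `a`: does it overlap >= 1 interval of `b`?"""
    trees = b.trees()
    flags = []
    for iv in a:
        tree = trees.get(iv.chrom)
        flags.append(tree is not None and tree.overlaps(iv.start, iv.end))
    return flags


def nearest_tss(peak: GenomicInterval, ann: GenomeAnnotation) -> tuple[str, int]:
    """Nearest TSS to the peak midpoint on the same chromosome.

    Distance is |midpoint - TSS|; ties broken by lexicographically smaller
    gene id.
    """
    genes = ann.genes_on(peak.chrom)
    if not genes:
        raise ValueError(f"no TSS on chromosome {peak.chrom}")
    mid = peak.midpoint
    best = min(genes, key=lambda g: (abs(mid - g.tss), g.gene_id))
    return best.gene_id, abs(mid - best.tss)


# ---------------------------------------------------------------------------
# I/O: BED3+2 and gene-annotation TSV
# ---------------------------------------------------------------------------

def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """BED3+2 writer: chrom, start, end[, score, qvalue]; '.' for missing."""
    with open(path, "w") as fh:
        for iv in peaks:
            score = "." if iv.score is None else repr(iv.score)
            qval = "." if iv.qvalue is None else repr(iv.qvalue)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{score}\t{qval}\n")


def read_bed(path: str | Path, label: str = "") -> PeakSet:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            score = qvalue = None
            if len(parts) > 3 and parts[3] != ".":
                score = float(parts[3])
            if len(parts) > 4 and parts[4] != ".":
                qvalue = float(parts[4])
            intervals.append(GenomicInterval(chrom, start, end, score, qvalue))
    return PeakSet(intervals, label=label or str(path))


def write_genes_tsv(ann: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\ttes\ttx_length\n")
        for g in ann.genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tes}\t{g.tx_length}\n")


def read_genes_tsv(path: str | Path, chrom_sizes: dict[str, int]) -> GenomeAnnotation:
    genes = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("gene_id"), "unexpected gene table header"
        for line in fh:
            gid, chrom, strand, tss, tes, length = line.rstrip("\n").split("\t")
            genes.append(Gene(gid, chrom, strand, int(tss), int(tes), int(length)))
    return GenomeAnnotation(chrom_sizes=chrom_sizes, genes=genes)


def write_chrom_sizes(chrom_sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split("\t")
                sizes[chrom] = int(size)
    return sizes
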