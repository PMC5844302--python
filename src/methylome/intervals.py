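"""Genomic interval and gene-model primitives.

All coordinates are 0-based, half-open (BED convention). A CpG site is keyed
by the coordinate ``N`` of its plus-strand cytosine and spans ``[N, N+2)``.
Chromosome order is lexicographic; ties in interval sort are broken by
``(start, end, strand)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """One transcript model: TSS/TES are strand-resolved genomic positions.

    ``tss``/``tes`` are single base positions (0-based): for a plus-strand
    model ``tss = txStart`` and ``tes = txEnd - 1``; for a minus-strand model
    the two genomic edges swap roles.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        lo, hi = self.body_span()
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"exon chrom {ex.chrom} != gene chrom {self.chrom}")
            if ex.start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            if ex.start < lo or ex.end > hi:
                raise ValueError("exon outside gene body span")
            prev_end = ex.end

    def body_span(self) -> tuple[int, int]:
        """Genomic span of the gene body as [min, max+1)."""
        lo = min(self.tss, self.tes)
        hi = max(self.tss, self.tes) + 1
        return lo, hi

    def body_interval(self) -> GenomicInterval:
        lo, hi = self.body_span()
        return GenomicInterval(self.chrom, lo, hi, self.strand, self.gene_id)


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=GenomicInterval.sort_key)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, disjoint list (strand discarded)."""
    out: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def subtract_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases of ``a`` not covered by ``b`` (both merged first)."""
    a_merged = merge_intervals(a)
    b_merged = merge_intervals(b)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b_merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for iv in a_merged:
        cursor = iv.start
        for cut in by_chrom.get(iv.chrom, []):
            if cut.end <= cursor or cut.start >= iv.end:
                continue
            if cut.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, cut.start))
            cursor = max(cursor, cut.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in merge_intervals(intervals))


def overlaps_any(
    query: GenomicInterval, subjects: Sequence[GenomicInterval]
) -> bool:
    """True iff ``query`` shares >= 1 bp with any subject.

    ``subjects`` need not be merged; a linear scan over the query's
    chromosome is used (fine for the region counts handled here).
    """
    return any(query.overlaps(s) for s in subjects)


def clip_to_chrom(
    iv: GenomicInterval, chrom_lengths: dict[str, int]
) -> GenomicInterval | None:
    """Clip an interval to [0, chrom length); None if nothing remains."""
    limit = chrom_lengths.get(iv.chrom)
    if limit is None:
        return iv
    start = max(0, iv.start)
    end = min(iv.end, limit)
    if end <= start:
        return None
    return GenomicInterval(iv.chrom, start, end, iv.strand, iv.name)


def match_intervals(
    called: Sequence[GenomicInterval], truth: Sequence[GenomicInterval]
) -> tuple[int, int]:
    """Count interval matches by >= 1 bp overlap.

    Returns ``(n_truth_recovered, n_called_matching)`` — the inputs to
    sensitivity (recovered / truth) and precision (matching / called).
    """
    n_truth = sum(1 for t in truth if overlaps_any(t, called))
    n_called = sum(1 for c in called if overlaps_any(c, truth))
    return n_truth, n_called
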