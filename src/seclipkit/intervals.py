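"""Genomic interval primitives.

All coordinates in this package are 0-based half-open ([start, end)),
the BED convention. GFF3/GTF input is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        """True if the two intervals share >= 1 bp (same chrom; same strand if stranded)."""
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval", stranded: bool = True) -> int:
        if not self.overlaps(other, stranded=stranded):
            return 0
        return min(self.end, other.end) - max(self.start, other.start)

    def union_span(self, other: "GenomicInterval") -> "GenomicInterval":
        """Smallest interval covering both (must be same chrom/strand)."""
        if self.chrom != other.chrom or self.strand != other.strand:
            raise ValueError("cannot union intervals on different chrom/strand")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end), self.strand
        )


def merge_intervals(
    intervals: Iterable[GenomicInterval], min_gap: int = 0
) -> list[GenomicInterval]:
    """Merge same-chrom/strand intervals that overlap or lie within ``min_gap`` bp.

    Returns maximal merged intervals sorted by (chrom, strand, start).
    """
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    out: list[GenomicInterval] = []
    for (chrom, strand), ivs in sorted(by_key.items()):
        ivs.sort(key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + min_gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end, strand))
    return out


def total_length(intervals: Sequence[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


def subtract_span(
    intervals: Sequence[GenomicInterval], start: int, end: int
) -> list[GenomicInterval]:
    """Remove [start, end) from each interval, keeping the pieces outside it."""
    out = []
    for iv in intervals:
        if iv.end <= start or iv.start >= end:
            out.append(iv)
            continue
        if iv.start < start:
            out.append(GenomicInterval(iv.chrom, iv.start, start, iv.strand))
        if iv.end > end:
            out.append(GenomicInterval(iv.chrom, end, iv.end, iv.strand))
    return out
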