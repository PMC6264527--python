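"""Genomic interval primitives and base-level interval algebra.

All coordinates are 0-based half-open ``[start, end)``; GTF I/O converts
to and from the 1-based inclusive convention at the boundary.  Strand is
one of ``+``, ``-`` or ``.`` — the unstranded sentinel is legal only for
monoexonic assembly artifacts whose orientation the assembler could not
resolve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping (start, end) pairs into a disjoint sorted list."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def intersect_length(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> int:
    """Total overlap in bases between two disjoint sorted interval lists."""
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def union_length(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> int:
    merged = merge_intervals(list(a) + list(b))
    return sum(e - s for s, e in merged)


def total_length(a: Sequence[tuple[int, int]]) -> int:
    return sum(e - s for s, e in a)


def gaps_between(a: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Internal gaps (introns) of a disjoint sorted interval list."""
    return [(a[i][1], a[i + 1][0]) for i in range(len(a) - 1) if a[i][1] < a[i + 1][0]]
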