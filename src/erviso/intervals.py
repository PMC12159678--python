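"""Half-open interval arithmetic on genomic coordinates.

All coordinates are 0-based, half-open ``[start, end)``.  The algebra
functions operate on plain ``(start, end)`` integer tuples on a single
(implicit) chromosome; :class:`GenomicInterval` adds the chromosome and
strand for typed interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

Interval = tuple[int, int]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {sorted(_STRANDS)}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(intervals: Iterable[Interval], merge_bookended: bool = True) -> list[Interval]:
    """Sort and merge intervals; book-ended intervals coalesce by default."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and (s < merged[-1][1] or (merge_bookended and s == merged[-1][1])):
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def subtract_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Set difference ``union(a) \\ union(b)`` as a sorted disjoint list."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection ``union(a) ∩ union(b)`` as a sorted disjoint list."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def overlap_length(block: Interval, intervals: Sequence[Interval]) -> int:
    """Number of bases of ``block`` covered by the (merged) interval union."""
    s, e = block
    return sum(
        max(0, min(e, ie) - max(s, is_))
        for is_, ie in intervals
        if is_ < e and s < ie
    )
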