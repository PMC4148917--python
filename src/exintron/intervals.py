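"""Half-open interval algebra on a single chromosome.

All coordinates are 0-based half-open ``[start, end)``.  These primitives are
the counting substrate for the genomic partition (merged exons, non-overlapping
introns, intergenic space): merging treats *touching* intervals as contiguous so
feature lengths used as RPKM denominators are never split or double counted.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals; adjacent (touching) intervals are merged."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def subtract_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Set difference a \\ b; both inputs need not be merged."""
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
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def complement_intervals(a: Sequence[Interval], length: int) -> list[Interval]:
    """Complement of ``a`` within ``[0, length)``."""
    if length <= 0:
        raise ValueError(f"chromosome length must be > 0, got {length}")
    return subtract_intervals([(0, length)], a)


def intersect_length(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    a = merge_intervals(a)
    b = merge_intervals(b)
    i = j = 0
    total = 0
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


@dataclass(frozen=True)
class IntervalSet:
    """Sorted, pairwise-disjoint, non-adjacent intervals on one chromosome."""

    chrom: str
    intervals: tuple[Interval, ...]
    _starts: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        prev_end = None
        for s, e in self.intervals:
            if s >= e:
                raise ValueError(f"empty interval ({s}, {e}) on {self.chrom}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(
                    f"intervals not disjoint/non-adjacent at ({s}, {e}) on {self.chrom}"
                )
            prev_end = e
        object.__setattr__(self, "_starts", tuple(s for s, _ in self.intervals))

    @classmethod
    def from_raw(cls, chrom: str, intervals: Iterable[Interval]) -> "IntervalSet":
        return cls(chrom, tuple(merge_intervals(intervals)))

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def contains_interval(self, start: int, end: int) -> bool:
        """True iff [start, end) lies fully inside one member interval."""
        if start >= end:
            raise ValueError(f"empty query interval ({start}, {end})")
        i = bisect_right(self._starts, start) - 1
        return i >= 0 and self.intervals[i][1] >= end

    def overlaps_interval(self, start: int, end: int) -> bool:
        i = bisect_right(self._starts, start) - 1
        if i >= 0 and self.intervals[i][1] > start:
            return True
        i += 1
        return i < len(self.intervals) and self.intervals[i][0] < end

    def subtract(self, other: Sequence[Interval] | "IntervalSet") -> "IntervalSet":
        ivs = list(other.intervals) if isinstance(other, IntervalSet) else list(other)
        return IntervalSet(self.chrom, tuple(subtract_intervals(self.intervals, ivs)))
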