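"""Interval algebra over genomic region sets.

ChIP experiments report binding regions as half-open genomic intervals.
Combining several experiments requires per-chromosome merging, k-way
consensus intersection ("regions where every study sees binding") and
union ("regions supported by any study").  All coordinates are 0-based
half-open internally; 1-based positions appear only at the MAP-file
boundary (see :func:`contains`).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """A labeled half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class IntervalSet:
    """Intervals grouped by chromosome, kept sorted by start.

    The set may hold overlapping intervals as loaded; :func:`merge_intervals`
    returns a coalesced copy in which intervals are pairwise disjoint and
    non-adjacent (book-ended intervals are merged, since with half-open
    coordinates adjacency means contiguous coverage).
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def chromosomes(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self, chrom: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.chrom == chrom]

    def covered_bases(self) -> int:
        """Total bases covered at least once (merge-aware)."""
        return sum(len(iv) for iv in merge_intervals(self).intervals)


def read_bed(path: str | Path, source: str = "") -> IntervalSet:
    """Read a BED3+ file into an :class:`IntervalSet`.

    Only the first three columns (chrom, start, end) are used; coordinates
    are 0-based half-open as in BED.  Blank lines and ``track``/``browser``/
    ``#`` lines are skipped.
    """
    path = Path(path)
    source = source or path.stem
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.append(GenomicInterval(chrom, start, end, source))
    return IntervalSet(intervals, source=source)


def write_bed(s: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in s.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.source or s.source or '.'}\n")


def merge_intervals(s: IntervalSet) -> IntervalSet:
    """Coalesce overlapping or book-ended intervals; coverage is preserved."""
    merged: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    for iv in s.intervals:  # already sorted by (chrom, start)
        if cur is not None and iv.chrom == cur.chrom and iv.start <= cur.end:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end, s.source)
        else:
            if cur is not None:
                merged.append(cur)
            cur = GenomicInterval(iv.chrom, iv.start, iv.end, s.source)
    if cur is not None:
        merged.append(cur)
    return IntervalSet(merged, source=s.source)


def _intersect_two(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Intersect two merged sets with a per-chromosome two-pointer sweep."""
    out: list[GenomicInterval] = []
    chroms = set(iv.chrom for iv in a.intervals) & set(iv.chrom for iv in b.intervals)
    for chrom in sorted(chroms):
        xs, ys = a.by_chrom(chrom), b.by_chrom(chrom)
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return IntervalSet(out)


def intersect_all(sets: Sequence[IntervalSet]) -> IntervalSet:
    """Maximal intervals covered by at least one interval from EVERY input set.

    This is the positional reading of "regions where all studies agree":
    a base belongs to the consensus iff every study reports binding there.
    """
    if len(sets) < 2:
        raise ValueError("intersect_all needs at least 2 interval sets")
    result = merge_intervals(sets[0])
    for s in sets[1:]:
        result = _intersect_two(result, merge_intervals(s))
        if not result.intervals:
            break
    result.source = "consensus"
    return result


def union_any(sets: Sequence[IntervalSet]) -> IntervalSet:
    """Merged union: exactly the positions covered by >=1 input set."""
    if not sets:
        raise ValueError("union_any needs at least 1 interval set")
    all_ivs = [iv for s in sets for iv in s.intervals]
    out = merge_intervals(IntervalSet(all_ivs))
    out.source = "union"
    return out


def whole_region_consensus(sets: Sequence[IntervalSet]) -> IntervalSet:
    """Alternative agreement mode: whole source regions from any set that
    overlap at least one region from every other set."""
    if len(sets) < 2:
        raise ValueError("whole_region_consensus needs at least 2 interval sets")
    merged = [merge_intervals(s) for s in sets]
    kept: list[GenomicInterval] = []
    for i, s in enumerate(sets):
        others = [m for j, m in enumerate(merged) if j != i]
        for iv in s.intervals:
            probe = IntervalSet([iv])
            if all(_intersect_two(probe, o).intervals for o in others):
                kept.append(iv)
    return merge_intervals(IntervalSet(kept, source="consensus-whole"))


class _MergedIndex:
    """Binary-searchable merged view of a set, built lazily per chromosome."""

    def __init__(self, s: IntervalSet):
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for iv in merge_intervals(s).intervals:
            starts, ends = self._by_chrom.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    def covers(self, chrom: str, pos0: int) -> bool:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        k = bisect.bisect_right(starts, pos0) - 1
        return k >= 0 and pos0 < ends[k]


def contains(s: IntervalSet, chrom: str, pos_1based: int) -> bool:
    """True iff the 1-based position falls inside some interval of ``s``."""
    if pos_1based < 1:
        raise ValueError(f"position must be >= 1, got {pos_1based}")
    return _MergedIndex(s).covers(chrom, pos_1based - 1)


def make_position_index(s: IntervalSet) -> _MergedIndex:
    """Reusable index for many membership queries against one set."""
    return _MergedIndex(s)
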