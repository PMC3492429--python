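"""Genomic interval algebra on 0-based half-open coordinates.

All downstream stages (call clustering, CNVR construction, cross-study and
QTL overlap) are built on the small set of primitives in this module:
pairwise overlap, union extent, single-linkage merging with cluster
membership, total intersection length between two disjoint interval sets,
and SNP counting inside an interval.

Coordinate convention: every interval is ``[start, end)`` with
``length = end - start`` (BED-compatible).  Readers for 1-based inclusive
file dialects convert on load.  Kb and Mb are decimal (1 Kb = 1,000 bp).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Interval",
    "GenomeMap",
    "overlaps",
    "overlap_length",
    "union_extent",
    "merge_overlapping",
    "IntervalCluster",
    "intersect_length",
    "count_snps_in",
    "total_length",
    "chrom_sort_key",
    "read_bed",
    "write_bed",
]

_CHROM_NUM = re.compile(r"(\d+)")


def chrom_sort_key(chrom: str) -> tuple:
    """Natural sort key so chr2 < chr10 and named chromosomes (X) sort last."""
    parts = _CHROM_NUM.split(chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True, order=True)
class Interval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        return self.length / 1_000.0

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class GenomeMap:
    """Ordered chromosome names and lengths; the coverage denominator."""

    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {name}: {length}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def __getitem__(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]

    def validate(self, iv: Interval) -> None:
        """Raise if *iv* falls outside the mapped chromosome."""
        if iv.chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.chrom_lengths[iv.chrom]:
            raise ValueError(
                f"{iv} exceeds {iv.chrom} length {self.chrom_lengths[iv.chrom]}"
            )


def overlap_length(a: Interval, b: Interval) -> int:
    """Shared bp between two intervals (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: Interval, b: Interval, min_overlap_bp: int = 1) -> bool:
    """True iff *a* and *b* share at least ``min_overlap_bp`` bases.

    With the default of 1 bp, abutting half-open intervals ([100,200) vs
    [200,300)) do NOT overlap.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    return overlap_length(a, b) >= min_overlap_bp


def union_extent(intervals: Sequence[Interval]) -> Interval:
    """Smallest interval covering all inputs: ``[min start, max end)``.

    Inputs must be non-empty and on a single chromosome.
    """
    if not intervals:
        raise ValueError("union_extent of empty interval list")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) != 1:
        raise ValueError(f"union_extent across chromosomes: {sorted(chroms)}")
    return Interval(
        intervals[0].chrom,
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
    )


@dataclass(frozen=True)
class IntervalCluster:
    """A merged extent plus the indices of the inputs it absorbed."""

    interval: Interval
    members: tuple[int, ...]


def merge_overlapping(
    intervals: Sequence[Interval], min_overlap_bp: int = 1
) -> list[IntervalCluster]:
    """Single-linkage merge: transitive closure of pairwise overlap.

    Returns disjoint clusters sorted by (chrom, start); each carries the
    indices of its constituent input intervals.  A sorted sweep suffices
    because single-linkage clusters are contiguous in start order.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    order = sorted(
        range(len(intervals)),
        key=lambda i: (
            chrom_sort_key(intervals[i].chrom),
            intervals[i].start,
            intervals[i].end,
        ),
    )
    clusters: list[IntervalCluster] = []
    cur_members: list[int] = []
    cur_chrom = ""
    cur_start = cur_end = 0
    for idx in order:
        iv = intervals[idx]
        # join the active cluster if it shares >= min_overlap_bp with its span
        if (
            cur_members
            and iv.chrom == cur_chrom
            and min(iv.end, cur_end) - iv.start >= min_overlap_bp
        ):
            cur_members.append(idx)
            cur_end = max(cur_end, iv.end)
        else:
            if cur_members:
                clusters.append(
                    IntervalCluster(
                        Interval(cur_chrom, cur_start, cur_end),
                        tuple(cur_members),
                    )
                )
            cur_members = [idx]
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    if cur_members:
        clusters.append(
            IntervalCluster(Interval(cur_chrom, cur_start, cur_end), tuple(cur_members))
        )
    return clusters


def _by_chrom(intervals: Iterable[Interval]) -> dict[str, list[Interval]]:
    out: dict[str, list[Interval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def intersect_length(
    set_a: Sequence[Interval], set_b: Sequence[Interval]
) -> int:
    """Total bp in the intersection of two internally disjoint interval sets.

    Symmetric in its arguments.  Each set is expected pre-merged (pairwise
    disjoint); a sorted two-pointer sweep is run per chromosome.
    """
    total = 0
    a_by = _by_chrom(set_a)
    b_by = _by_chrom(set_b)
    for chrom in set(a_by) & set(b_by):
        aa = sorted(a_by[chrom], key=lambda iv: iv.start)
        bb = sorted(b_by[chrom], key=lambda iv: iv.start)
        i = j = 0
        while i < len(aa) and j < len(bb):
            total += max(0, min(aa[i].end, bb[j].end) - max(aa[i].start, bb[j].start))
            if aa[i].end <= bb[j].end:
                i += 1
            else:
                j += 1
    return total


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(iv.length for iv in intervals)


def count_snps_in(interval: Interval, snp_positions: Mapping[str, np.ndarray]) -> int:
    """Number of markers with ``start <= pos < end`` on the interval's chromosome.

    ``snp_positions`` maps chromosome -> sorted array of 0-based positions
    (a :class:`cnvrkit.io_formats.SnpMap` satisfies this).
    """
    if interval.chrom not in snp_positions:
        raise KeyError(f"unknown chromosome {interval.chrom!r} in SNP map")
    pos = np.asarray(snp_positions[interval.chrom])
    lo = int(np.searchsorted(pos, interval.start, side="left"))
    hi = int(np.searchsorted(pos, interval.end, side="left"))
    return hi - lo


# ---------------------------------------------------------------------------
# BED interchange (0-based half-open, 3+ columns)

def read_bed(path) -> list[Interval]:
    """Read a BED file (first three columns) into a list of intervals."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            out.append(Interval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(intervals: Sequence[Interval], path, names: Sequence[str] | None = None) -> None:
    """Write intervals as BED; optional fourth name column."""
    if names is not None and len(names) != len(intervals):
        raise ValueError("names must match intervals in length")
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                cols.append(str(names[i]))
            fh.write("\t".join(cols) + "\n")
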