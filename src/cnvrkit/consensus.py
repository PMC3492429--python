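"""Two-stage CNVR consensus construction.

Stage 1 (per caller): filter per-sample calls (marker support and size),
then single-linkage cluster overlapping calls across animals; clusters seen
in at least ``min_samples`` distinct animals become per-caller CNVs.

Stage 2 (across callers): single-linkage cluster the per-caller CNVs from
all callers; clusters supported by at least ``min_callers`` distinct
programs become CNV regions (CNVRs), taking the union extent of their
constituents.  CNVRs in one result set are pairwise disjoint by
construction.

The size filter applies to raw per-sample calls only; merged CNVs and
CNVRs may exceed it, which is why observed CNVR lengths can exceed the
per-call maximum.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .intervals import Interval, chrom_sort_key, merge_overlapping, union_extent
from .io_formats import GAIN, LOSS, CnvCall

__all__ = [
    "CallerCnv",
    "Cnvr",
    "filter_calls",
    "filter_chromosomes",
    "build_caller_cnvs",
    "build_cnvrs",
    "classify_status",
    "VennCounts",
    "venn_counts",
    "venn_union_total",
    "venn_multi_caller_total",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerCnv:
    """A per-caller CNV: overlapping calls from >=2 animals, one caller."""

    caller_id: str
    interval: Interval
    carriers: frozenset[str]
    states: tuple[str, ...]
    constituent_calls: tuple[CnvCall, ...] = ()

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class Cnvr:
    """A consensus CNV region supported by >=2 callers."""

    id: int
    interval: Interval
    callers: frozenset[str]
    carriers: frozenset[str]
    status: str  # loss | gain | both
    frequency: float | None = None
    constituents: tuple[CallerCnv, ...] = field(default=(), repr=False)

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def filter_calls(
    calls: Iterable[CnvCall],
    min_snps: int = 3,
    max_len_bp: int = 1_000_000,
) -> list[CnvCall]:
    """Keep calls with ``n_snps >= min_snps`` and length strictly below
    ``max_len_bp``; log how many each rule removed."""
    kept: list[CnvCall] = []
    n_snp_fail = n_len_fail = 0
    for c in calls:
        if c.n_snps < min_snps:
            n_snp_fail += 1
        elif c.interval.length >= max_len_bp:
            n_len_fail += 1
        else:
            kept.append(c)
    log.info(
        "filter_calls: kept %d, removed %d (<%d SNPs) + %d (>=%d bp)",
        len(kept), n_snp_fail, min_snps, n_len_fail, max_len_bp,
    )
    return kept


def filter_chromosomes(
    calls: Iterable[CnvCall],
    include: Sequence[str] | None = None,
    exclude: Sequence[str] | None = None,
) -> list[CnvCall]:
    """Restrict calls to a chromosome whitelist and/or drop a blacklist.

    Sex-chromosome calls are kept by default throughout the pipeline;
    excluding them (e.g. ``exclude=["chrX"]``) is an explicit choice.
    """
    include_set = set(include) if include is not None else None
    exclude_set = set(exclude or ())
    kept = [
        c
        for c in calls
        if (include_set is None or c.chrom in include_set)
        and c.chrom not in exclude_set
    ]
    log.info("filter_chromosomes: kept %d calls", len(kept))
    return kept


def _canonical_call_order(calls: Sequence[CnvCall]) -> list[CnvCall]:
    return sorted(
        calls,
        key=lambda c: (
            chrom_sort_key(c.chrom),
            c.interval.start,
            c.interval.end,
            c.sample_id,
            c.caller_id,
        ),
    )


def build_caller_cnvs(
    calls: Sequence[CnvCall],
    min_samples: int = 2,
    span_mode: str = "union",
    min_overlap_bp: int = 1,
) -> list[CallerCnv]:
    """Cluster one caller's filtered calls into per-caller CNVs.

    Single-linkage overlap clusters are formed across all samples; a
    cluster becomes a CNV only if it contains calls from at least
    ``min_samples`` *distinct* animals (the same animal called twice does
    not qualify).  ``span_mode='union'`` takes the cluster's union extent;
    ``'intersection'`` takes the core shared by every constituent (clusters
    whose chained constituents share no common core are dropped).
    """
    if span_mode not in ("union", "intersection"):
        raise ValueError(f"span_mode must be union|intersection, got {span_mode!r}")
    caller_ids = {c.caller_id for c in calls}
    if len(caller_ids) > 1:
        raise ValueError(f"calls from multiple callers: {sorted(caller_ids)}")
    if not calls:
        return []
    caller_id = next(iter(caller_ids))

    ordered = _canonical_call_order(calls)
    clusters = merge_overlapping([c.interval for c in ordered], min_overlap_bp)
    cnvs: list[CallerCnv] = []
    n_dropped = 0
    for cl in clusters:
        members = [ordered[i] for i in cl.members]
        carriers = frozenset(m.sample_id for m in members)
        if len(carriers) < min_samples:
            n_dropped += 1
            continue
        if span_mode == "union":
            extent = cl.interval
        else:
            start = max(m.interval.start for m in members)
            end = min(m.interval.end for m in members)
            if start >= end:
                log.warning(
                    "dropping chained cluster %s with empty intersection core",
                    cl.interval,
                )
                n_dropped += 1
                continue
            extent = Interval(cl.interval.chrom, start, end)
        cnvs.append(
            CallerCnv(
                caller_id=caller_id,
                interval=extent,
                carriers=carriers,
                states=tuple(m.state for m in members),
                constituent_calls=tuple(members),
            )
        )
    log.info(
        "build_caller_cnvs[%s]: %d calls -> %d CNVs (%d clusters dropped)",
        caller_id, len(calls), len(cnvs), n_dropped,
    )
    return cnvs


def classify_status(states: Sequence[str]) -> str:
    """loss if every constituent state is loss, gain if all gain, else both."""
    if not states:
        raise ValueError("empty state multiset")
    unique = set(states)
    if unique == {LOSS}:
        return LOSS
    if unique == {GAIN}:
        return GAIN
    return "both"


def build_cnvrs(
    caller_cnvs: Sequence[CallerCnv],
    min_callers: int = 2,
    min_overlap_bp: int = 1,
) -> list[Cnvr]:
    """Union overlapping per-caller CNVs across programs into CNVRs.

    Single-linkage clusters over all callers' CNVs; clusters containing at
    least ``min_callers`` distinct programs are emitted as CNVRs with the
    union extent, the union of carriers, and a loss/gain/both status.  Ids
    are ordinal in (chrom, start) order; the result is disjoint and sorted.
    """
    ordered = sorted(
        caller_cnvs,
        key=lambda v: (chrom_sort_key(v.chrom), v.interval.start, v.interval.end, v.caller_id),
    )
    clusters = merge_overlapping([v.interval for v in ordered], min_overlap_bp)
    cnvrs: list[Cnvr] = []
    for cl in clusters:
        members = [ordered[i] for i in cl.members]
        callers = frozenset(m.caller_id for m in members)
        if len(callers) < min_callers:
            continue
        states: list[str] = []
        for m in members:
            states.extend(m.states)
        carriers = frozenset().union(*(m.carriers for m in members))
        cnvrs.append(
            Cnvr(
                id=0,
                interval=union_extent([m.interval for m in members]),
                callers=callers,
                carriers=carriers,
                status=classify_status(states),
                constituents=tuple(members),
            )
        )
    cnvrs.sort(key=lambda r: (chrom_sort_key(r.chrom), r.interval.start))
    for i, r in enumerate(cnvrs, 1):
        r.id = i
    log.info("build_cnvrs: %d caller CNVs -> %d CNVRs", len(caller_cnvs), len(cnvrs))
    return cnvrs


# ---------------------------------------------------------------------------
# Venn accounting across callers

@dataclass
class VennCounts:
    """Cross-caller concordance counts over merged loci.

    A *locus* is one single-linkage cluster over all callers' CNVs.
    ``per_caller`` counts loci at which a caller has at least one CNV;
    ``subset_counts`` maps each caller subset of size >= 2 to the number
    of loci where every member has a CNV (so pairwise counts include the
    higher-order intersections, the usual Venn-diagram convention).
    ``n_cnvs`` holds the raw per-caller CNV counts, which coincide with
    ``per_caller`` whenever no locus absorbs two CNVs of one caller (the
    one-to-one regime assumed by printed Venn figures).
    """

    n_cnvs: dict[str, int]
    per_caller: dict[str, int]
    subset_counts: dict[frozenset, int]
    n_loci: int
    n_multi_caller: int

    @property
    def pairwise(self) -> dict[frozenset, int]:
        return {k: v for k, v in self.subset_counts.items() if len(k) == 2}

    @property
    def full_intersection(self) -> int:
        all_callers = frozenset(self.per_caller)
        return self.subset_counts.get(all_callers, 0) if len(all_callers) >= 2 else 0

    @property
    def union_total(self) -> int:
        """Exact inclusion-exclusion union of the per-caller locus sets.

        Always equals ``n_loci``; with three callers in the one-to-one
        regime it also equals singles - pairs + triple on the raw counts.
        """
        total = sum(self.per_caller.values())
        for subset, n in self.subset_counts.items():
            total += n if len(subset) % 2 else -n
        return total


def venn_union_total(
    per_caller: Sequence[int], pairwise: Sequence[int], triple: int
) -> int:
    """Three-set inclusion-exclusion: sum(singles) - sum(pairs) + triple."""
    if len(per_caller) != 3 or len(pairwise) != 3:
        raise ValueError("three per-caller counts and three pairwise counts required")
    return sum(per_caller) - sum(pairwise) + triple


def venn_multi_caller_total(pairwise: Sequence[int], triple: int) -> int:
    """Loci shared by >=2 of 3 callers from Venn-convention pairwise counts.

    Pairwise counts include the triple intersection, so each triply-shared
    locus is counted three times in ``sum(pairwise)``; subtracting twice
    the triple count leaves every multi-caller locus counted once.
    """
    if len(pairwise) != 3:
        raise ValueError("three pairwise counts required")
    return sum(pairwise) - 2 * triple


def venn_counts(
    caller_cnvs: Sequence[CallerCnv], min_overlap_bp: int = 1
) -> VennCounts:
    """Count per-caller CNVs and cross-caller shared loci.

    Loci are the single-linkage clusters over all callers' CNVs; a locus
    counts toward a caller subset if every caller in the subset
    contributed at least one CNV to it, so each CNV is counted once per
    subset regardless of how many partners it touches.
    """
    n_cnvs = Counter(v.caller_id for v in caller_cnvs)
    ordered = sorted(
        caller_cnvs,
        key=lambda v: (chrom_sort_key(v.chrom), v.interval.start, v.interval.end, v.caller_id),
    )
    clusters = merge_overlapping([v.interval for v in ordered], min_overlap_bp)
    per_caller: Counter = Counter()
    subset_counts: Counter = Counter()
    n_multi = 0
    for cl in clusters:
        callers = frozenset(ordered[i].caller_id for i in cl.members)
        for c in callers:
            per_caller[c] += 1
        if len(callers) >= 2:
            n_multi += 1
        for size in range(2, len(callers) + 1):
            for sub in combinations(sorted(callers), size):
                subset_counts[frozenset(sub)] += 1
    return VennCounts(
        n_cnvs=dict(n_cnvs),
        per_caller=dict(per_caller),
        subset_counts=dict(subset_counts),
        n_loci=len(clusters),
        n_multi_caller=n_multi,
    )
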