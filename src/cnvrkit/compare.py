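"""Cross-study CNVR comparison, QTL overlap and permutation enrichment.

* :func:`compare_cnvr_sets` reproduces the usual cross-study table: how
  many query CNVRs touch a reference set and what fraction of the query
  length is shared.
* :func:`dedup_qtls` collapses re-reported QTLs: records with wide
  confidence intervals (>= ``max_ci_cm`` centiMorgans) are discarded, and
  remaining QTLs whose bp confidence intervals overlap by more than half
  of the smaller interval are treated as one QTL.
* :func:`cnvr_qtl_overlap` counts CNVRs harboring or partially
  overlapping QTLs (and doubles as the gene-overlap routine when fed gene
  intervals).
* :func:`qtl_density_enrichment` formalizes "QTL density is higher inside
  CNVRs than genome-wide" as a permutation test that re-places the CNVR
  set uniformly at random, preserving each region's length and chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intervals import (
    GenomeMap,
    Interval,
    intersect_length,
    overlap_length,
    overlaps,
    total_length,
)
from .io_formats import QtlRecord
from .consensus import Cnvr

__all__ = [
    "OverlapReport",
    "compare_cnvr_sets",
    "dedup_qtls",
    "cnvr_qtl_overlap",
    "region_overlap",
    "qtl_density_enrichment",
]

log = logging.getLogger(__name__)


@dataclass
class OverlapReport:
    """Overlap of a query CNVR set with one reference region set."""

    n_query: int
    n_query_overlapped: int
    overlapped_length_bp: int
    query_length_bp: int
    mapping: list[tuple[int, int]] = field(default_factory=list, repr=False)

    @property
    def pct_count(self) -> float:
        return self.n_query_overlapped / self.n_query if self.n_query else 0.0

    @property
    def pct_length(self) -> float:
        return (
            self.overlapped_length_bp / self.query_length_bp
            if self.query_length_bp
            else 0.0
        )


def compare_cnvr_sets(
    query: Sequence[Interval],
    reference: Sequence[Interval],
    min_overlap_bp: int = 1,
) -> OverlapReport:
    """Count query regions touching the reference set and the shared bp.

    Both sets must be internally disjoint (pre-merged).  Percentages are
    relative to the query set; the shared length itself is symmetric.
    ``mapping`` lists (query index, reference index) overlap pairs.
    """
    mapping = [
        (qi, ri)
        for qi, q in enumerate(query)
        for ri, r in enumerate(reference)
        if overlaps(q, r, min_overlap_bp)
    ]
    hit_queries = {qi for qi, _ in mapping}
    return OverlapReport(
        n_query=len(query),
        n_query_overlapped=len(hit_queries),
        overlapped_length_bp=intersect_length(query, reference),
        query_length_bp=total_length(query),
        mapping=mapping,
    )


def _qtl_same(
    a: QtlRecord, b: QtlRecord, frac: float, denominator: str
) -> bool:
    ov = overlap_length(a.interval, b.interval)
    if ov == 0:
        return False
    if denominator == "smaller":
        return ov > frac * min(a.interval.length, b.interval.length)
    # reciprocal: the fraction must exceed the cutoff for BOTH intervals
    return ov > frac * a.interval.length and ov > frac * b.interval.length


def dedup_qtls(
    qtls: Sequence[QtlRecord],
    max_ci_cm: float = 30.0,
    same_qtl_overlap: float = 0.5,
    overlap_denominator: str = "smaller",
) -> list[QtlRecord]:
    """Filter wide-CI QTLs and collapse re-reports of the same QTL.

    Records with ``ci_cm >= max_ci_cm`` are dropped (strict "less than").
    Remaining QTLs are single-linkage clustered wherever the pairwise bp
    overlap exceeds ``same_qtl_overlap`` of the smaller interval (or of
    both, with ``overlap_denominator='reciprocal'``); each cluster is
    represented by its narrowest-CI record (ties broken by start, then id).
    """
    if overlap_denominator not in ("smaller", "reciprocal"):
        raise ValueError(f"unknown overlap_denominator {overlap_denominator!r}")
    narrow = [q for q in qtls if q.ci_cm < max_ci_cm]
    log.info("dedup_qtls: %d/%d QTLs pass ci_cm < %g", len(narrow), len(qtls), max_ci_cm)

    # union-find over pairwise same-QTL checks, per chromosome
    narrow = sorted(
        narrow, key=lambda q: (q.chrom, q.interval.start, q.interval.end, q.qtl_id)
    )
    parent = list(range(len(narrow)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(narrow)):
        for j in range(i + 1, len(narrow)):
            if narrow[j].chrom != narrow[i].chrom:
                break
            if narrow[j].interval.start >= narrow[i].interval.end:
                break
            if _qtl_same(narrow[i], narrow[j], same_qtl_overlap, overlap_denominator):
                parent[find(j)] = find(i)

    groups: dict[int, list[QtlRecord]] = {}
    for i, q in enumerate(narrow):
        groups.setdefault(find(i), []).append(q)
    reps = [
        min(g, key=lambda q: (q.ci_cm, q.interval.start, q.qtl_id))
        for g in groups.values()
    ]
    reps.sort(key=lambda q: (q.chrom, q.interval.start, q.qtl_id))
    log.info("dedup_qtls: %d distinct QTLs after collapsing", len(reps))
    return reps


def region_overlap(
    cnvrs: Sequence[Cnvr],
    regions: Sequence[Interval],
    region_ids: Sequence[str] | None = None,
    min_overlap_bp: int = 1,
) -> tuple[int, int, list[tuple[int, str, bool]]]:
    """CNVR-vs-region overlap with a containment flag per hit.

    Returns (number of CNVRs hitting >=1 region, number of regions hit,
    mapping of (cnvr id, region id, region fully inside the CNVR)).  Used
    for both QTL and gene annotation overlap; the containment flag
    distinguishes features harbored within a CNVR from partial overlaps.
    """
    if region_ids is None:
        region_ids = [str(i) for i in range(len(regions))]
    mapping: list[tuple[int, str, bool]] = []
    hit_regions: set[str] = set()
    hit_cnvrs: set[int] = set()
    for r in cnvrs:
        for reg, reg_id in zip(regions, region_ids):
            if overlaps(r.interval, reg, min_overlap_bp):
                contained = (
                    reg.start >= r.interval.start and reg.end <= r.interval.end
                )
                mapping.append((r.id, reg_id, contained))
                hit_cnvrs.add(r.id)
                hit_regions.add(reg_id)
    return len(hit_cnvrs), len(hit_regions), mapping


def cnvr_qtl_overlap(
    cnvrs: Sequence[Cnvr],
    qtls: Sequence[QtlRecord],
    min_overlap_bp: int = 1,
) -> tuple[int, int, list[tuple[int, str, bool]]]:
    """Count CNVRs harboring or partially overlapping (deduplicated) QTLs."""
    return region_overlap(
        cnvrs,
        [q.interval for q in qtls],
        [q.qtl_id for q in qtls],
        min_overlap_bp,
    )


def _fraction_qtls_hit(
    qtl_ivs: Sequence[Interval], cnvr_ivs: Sequence[Interval]
) -> float:
    n_hit = sum(
        1 for q in qtl_ivs if any(overlaps(q, c) for c in cnvr_ivs)
    )
    return n_hit / len(qtl_ivs)


def _random_placement(
    cnvr_ivs: Sequence[Interval],
    genome_map: GenomeMap,
    rng: np.random.Generator,
    max_retries: int = 1000,
) -> list[Interval]:
    """Re-place each region uniformly on its own chromosome, disjointly.

    Length and chromosome are preserved; rejection sampling keeps the
    placed set pairwise disjoint (regions placed longest-first so the
    hardest constraints go in early).
    """
    placed_by_chrom: dict[str, list[Interval]] = {}
    out: list[Interval] = []
    for iv in sorted(cnvr_ivs, key=lambda v: -v.length):
        span = genome_map[iv.chrom] - iv.length
        if span < 0:
            raise ValueError(f"{iv} longer than chromosome {iv.chrom}")
        existing = placed_by_chrom.setdefault(iv.chrom, [])
        for _ in range(max_retries):
            start = int(rng.integers(0, span + 1))
            cand = Interval(iv.chrom, start, start + iv.length)
            if not any(overlaps(cand, p) for p in existing):
                existing.append(cand)
                out.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place a {iv.length} bp region on {iv.chrom} "
                f"after {max_retries} retries"
            )
    return out


def qtl_density_enrichment(
    cnvrs: Sequence[Cnvr],
    qtls: Sequence[QtlRecord],
    genome_map: GenomeMap,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Permutation test for QTL enrichment within the CNVR set.

    The observed statistic is the fraction of QTLs overlapping >=1 CNVR.
    The null re-places the CNVR set uniformly at random ``n_perm`` times,
    preserving each region's length and chromosome and keeping placements
    disjoint.  Returns (observed fraction, null mean, empirical p) with

        p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if not qtls:
        raise ValueError("QTL set is empty; observed fraction undefined")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    cnvr_ivs = [r.interval for r in cnvrs]
    qtl_ivs = [q.interval for q in qtls]
    observed = _fraction_qtls_hit(qtl_ivs, cnvr_ivs)
    null = np.empty(n_perm)
    for k in range(n_perm):
        placed = _random_placement(cnvr_ivs, genome_map, rng)
        null[k] = _fraction_qtls_hit(qtl_ivs, placed)
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return observed, float(null.mean()), p
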