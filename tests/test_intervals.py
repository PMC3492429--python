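"""Interval algebra checked against per-basepair boolean-array oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvrkit.intervals import (
    GenomeMap,
    Interval,
    count_snps_in,
    intersect_length,
    merge_overlapping,
    overlaps,
    read_bed,
    total_length,
    union_extent,
    write_bed,
)

GENOME_BP = 10_000  # oracle genomes stay small enough for per-bp arrays


def bp_mask(intervals, size=GENOME_BP):
    """Per-bp boolean coverage oracle on a single chromosome."""
    mask = np.zeros(size, dtype=bool)
    for iv in intervals:
        mask[iv.start : iv.end] = True
    return mask


st_interval = st.integers(0, GENOME_BP - 1).flatmap(
    lambda s: st.integers(s + 1, GENOME_BP).map(lambda e: Interval("chr1", s, e))
)
st_interval_list = st.lists(st_interval, min_size=0, max_size=20)


class TestIntervalBasics:
    def test_length_is_end_minus_start(self):
        assert Interval("chr1", 100, 200).length == 100
        assert Interval("chr1", 0, 27_010).length_kb == pytest.approx(27.01)

    @pytest.mark.parametrize("start,end", [(5, 5), (10, 3), (-1, 5)])
    def test_invalid_intervals_rejected(self, start, end):
        with pytest.raises(ValueError):
            Interval("chr1", start, end)

    def test_genome_map_validation(self, genome_map):
        genome_map.validate(Interval("chr1", 0, 1_000_000))
        with pytest.raises(ValueError):
            genome_map.validate(Interval("chr1", 0, 1_000_001))
        with pytest.raises(KeyError):
            genome_map.validate(Interval("chrX", 0, 10))
        with pytest.raises(ValueError):
            GenomeMap({"chr1": 0})


class TestOverlaps:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (Interval("chr1", 100, 200), Interval("chr1", 150, 300), True),
            (Interval("chr1", 100, 200), Interval("chr1", 200, 300), False),  # abutting
            (Interval("chr1", 100, 200), Interval("chr2", 100, 200), False),
        ],
    )
    def test_examples(self, a, b, expected):
        assert overlaps(a, b) is expected
        assert overlaps(b, a) is expected  # symmetric

    def test_min_overlap_threshold(self):
        a, b = Interval("chr1", 0, 100), Interval("chr1", 90, 200)
        assert overlaps(a, b, min_overlap_bp=10)
        assert not overlaps(a, b, min_overlap_bp=11)


class TestUnionExtent:
    def test_two_overlapping(self):
        got = union_extent([Interval("chr1", 100, 200), Interval("chr1", 150, 300)])
        assert got == Interval("chr1", 100, 300)

    def test_identity(self):
        iv = Interval("chr1", 100, 200)
        assert union_extent([iv]) == iv

    def test_chained_matches_bp_oracle(self):
        ivs = [Interval("chr1", 0, 10), Interval("chr1", 5, 8), Interval("chr1", 9, 20)]
        got = union_extent(ivs)
        mask = bp_mask(ivs)
        covered = np.flatnonzero(mask)
        assert (got.start, got.end) == (covered[0], covered[-1] + 1)
        assert got == Interval("chr1", 0, 20)

    def test_errors(self):
        with pytest.raises(ValueError):
            union_extent([])
        with pytest.raises(ValueError):
            union_extent([Interval("chr1", 0, 10), Interval("chr2", 0, 10)])

    @given(st.lists(st_interval, min_size=1, max_size=10))
    @settings(deadline=None)
    def test_extent_bounds_constituents(self, ivs):
        ext = union_extent(ivs)
        assert ext.length >= max(iv.length for iv in ivs)
        assert all(ext.start <= iv.start and iv.end <= ext.end for iv in ivs)


def brute_force_clusters(intervals):
    """All-pairs transitive closure of pairwise overlap (independent oracle)."""
    parent = list(range(len(intervals)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            if overlaps(intervals[i], intervals[j]):
                parent[find(j)] = find(i)
    groups = {}
    for i in range(len(intervals)):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestMergeOverlapping:
    def test_two_clusters(self):
        ivs = [Interval("chr1", 0, 10), Interval("chr1", 5, 15), Interval("chr1", 20, 30)]
        got = merge_overlapping(ivs)
        assert [c.interval for c in got] == [Interval("chr1", 0, 15), Interval("chr1", 20, 30)]
        assert [set(c.members) for c in got] == [{0, 1}, {2}]

    def test_chain_joins_disjoint_ends(self):
        # A and C are disjoint but both touch B: one transitive cluster
        ivs = [Interval("chr1", 0, 10), Interval("chr1", 8, 20), Interval("chr1", 18, 30)]
        got = merge_overlapping(ivs)
        assert len(got) == 1
        assert got[0].interval == Interval("chr1", 0, 30)
        assert brute_force_clusters(ivs) == {frozenset({0, 1, 2})}

    def test_empty_input(self):
        assert merge_overlapping([]) == []

    @given(st_interval_list)
    @settings(deadline=None, max_examples=200)
    def test_matches_transitive_closure_oracle(self, ivs):
        got = merge_overlapping(ivs)
        assert {frozenset(c.members) for c in got} == brute_force_clusters(ivs)

    @given(st_interval_list)
    @settings(deadline=None, max_examples=200)
    def test_output_disjoint_and_covers_like_bp_union(self, ivs):
        got = merge_overlapping(ivs)
        merged = [c.interval for c in got]
        for a, b in zip(merged, merged[1:]):
            assert a.end <= b.start  # disjoint and sorted
        assert total_length(merged) == int(bp_mask(ivs).sum())


class TestIntersectLength:
    def test_examples(self):
        assert intersect_length([Interval("chr1", 0, 100)], [Interval("chr1", 50, 150)]) == 50
        a = [Interval("chr1", 0, 100), Interval("chr2", 0, 40)]
        assert intersect_length(a, a) == total_length(a)
        assert intersect_length([], [Interval("chr1", 0, 10)]) == 0

    @given(st_interval_list, st_interval_list)
    @settings(deadline=None, max_examples=200)
    def test_matches_bp_and_oracle_and_symmetry(self, raw_a, raw_b):
        # pre-merge both sets, as the contract requires
        a = [c.interval for c in merge_overlapping(raw_a)]
        b = [c.interval for c in merge_overlapping(raw_b)]
        expected = int((bp_mask(a) & bp_mask(b)).sum())
        assert intersect_length(a, b) == expected
        assert intersect_length(b, a) == expected


class TestCountSnps:
    def test_boundary_conventions(self):
        snps = {"chr1": np.array([10, 20, 30])}
        assert count_snps_in(Interval("chr1", 10, 31), snps) == 3
        assert count_snps_in(Interval("chr1", 11, 20), snps) == 0
        with pytest.raises(KeyError):
            count_snps_in(Interval("chr9", 0, 10), snps)

    @given(
        st.lists(st.integers(0, GENOME_BP - 1), min_size=0, max_size=50, unique=True),
        st_interval,
        st.integers(1, GENOME_BP - 1),
    )
    @settings(deadline=None)
    def test_linear_scan_oracle_and_additivity(self, positions, iv, cut):
        snps = {"chr1": np.array(sorted(positions))}
        expected = sum(1 for p in positions if iv.start <= p < iv.end)
        assert count_snps_in(iv, snps) == expected
        if iv.start < cut < iv.end:  # additive over a partition
            left = count_snps_in(Interval("chr1", iv.start, cut), snps)
            right = count_snps_in(Interval("chr1", cut, iv.end), snps)
            assert left + right == expected


class TestBedIO:
    def test_round_trip(self, tmp_path):
        ivs = [Interval("chr1", 0, 100), Interval("chr2", 50, 500)]
        path = tmp_path / "regions.bed"
        write_bed(ivs, path, names=["r1", "r2"])
        assert read_bed(path) == ivs

    def test_skips_comments_and_rejects_short_lines(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("# comment\nchr1\t0\t100\nchr1\t5\n")
        with pytest.raises(ValueError, match="3 BED columns"):
            read_bed(path)
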