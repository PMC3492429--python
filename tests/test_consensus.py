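"""Two-stage consensus: call filtering, per-caller CNVs, CNVRs, Venn counts."""

from __future__ import annotations

import random

import pytest

from cnvrkit.consensus import (
    build_caller_cnvs,
    build_cnvrs,
    classify_status,
    filter_calls,
    venn_counts,
    venn_multi_caller_total,
    venn_union_total,
)
from cnvrkit.intervals import Interval
from cnvrkit.synthetic import venn_scenario
from conftest import make_call

FIG_VENN = dict(per_caller=[219, 169, 140], pairwise=[71, 61, 51], triple=42)


class TestFilterCalls:
    def test_marker_support_rule(self):
        assert filter_calls([make_call(n_snps=2)]) == []
        kept = filter_calls([make_call(n_snps=3, start=0, end=500_000)])
        assert len(kept) == 1

    def test_size_rule_is_strict(self):
        exactly_1mb = make_call(start=0, end=1_000_000, n_snps=50)
        just_under = make_call(start=0, end=999_999, n_snps=50)
        assert filter_calls([exactly_1mb, just_under]) == [just_under]


class TestBuildCallerCnvs:
    def test_two_animals_merge(self):
        calls = [
            make_call(sample="S1", start=100, end=200),
            make_call(sample="S2", start=150, end=300),
        ]
        (cnv,) = build_caller_cnvs(calls)
        assert cnv.interval == Interval("chr1", 100, 300)
        assert cnv.carriers == {"S1", "S2"}

    def test_single_animal_cluster_dropped(self):
        assert build_caller_cnvs([make_call(sample="S1")]) == []
        # same animal twice still fails the two-animal rule
        twice = [
            make_call(sample="S1", start=0, end=100),
            make_call(sample="S1", start=50, end=200),
        ]
        assert build_caller_cnvs(twice) == []

    def test_chained_cluster_counts_distinct_samples(self):
        calls = [
            make_call(sample="S1", start=0, end=10_000),
            make_call(sample="S1", start=5_000, end=20_000),
            make_call(sample="S2", start=18_000, end=30_000),
        ]
        (cnv,) = build_caller_cnvs(calls)
        assert cnv.interval == Interval("chr1", 0, 30_000)
        assert cnv.carriers == {"S1", "S2"}
        assert len(cnv.constituent_calls) == 3

    def test_intersection_span_mode(self):
        calls = [
            make_call(sample="S1", start=100, end=300),
            make_call(sample="S2", start=200, end=400),
        ]
        (cnv,) = build_caller_cnvs(calls, span_mode="intersection")
        assert cnv.interval == Interval("chr1", 200, 300)

    def test_mixed_callers_rejected(self):
        calls = [make_call(caller="a"), make_call(caller="b")]
        with pytest.raises(ValueError, match="multiple callers"):
            build_caller_cnvs(calls)


class TestClassifyStatus:
    @pytest.mark.parametrize(
        "states,expected",
        [
            (("loss", "loss"), "loss"),
            (("gain",), "gain"),
            (("loss", "gain"), "both"),
        ],
    )
    def test_examples(self, states, expected):
        assert classify_status(states) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_status(())


def _caller_cnv_sets():
    """Two callers with one shared locus and one private CNV each."""
    a = build_caller_cnvs(
        [make_call(caller="penncnv", sample=s, start=100, end=200 + i * 100)
         for i, s in enumerate(["S1", "S2"])]
        + [make_call(caller="penncnv", sample=s, start=500_000, end=600_000)
           for s in ["S3", "S4"]]
    )
    b = build_caller_cnvs(
        [make_call(caller="gada", sample=s, start=150, end=300) for s in ["S1", "S5"]]
        + [make_call(caller="gada", sample=s, start=700_000, end=800_000)
           for s in ["S1", "S2"]]
    )
    return a, b


class TestBuildCnvrs:
    def test_cross_caller_union(self):
        a, b = _caller_cnv_sets()
        cnvrs = build_cnvrs(a + b)
        assert len(cnvrs) == 1
        (r,) = cnvrs
        assert r.interval == Interval("chr1", 100, 300)
        assert r.callers == {"penncnv", "gada"}
        assert r.carriers == {"S1", "S2", "S5"}

    def test_unsupported_cnv_emits_nothing(self):
        a, _ = _caller_cnv_sets()
        assert build_cnvrs(a) == []

    def test_ids_ordinal_and_disjoint(self):
        sets = venn_scenario()
        cnvrs = build_cnvrs([v for vs in sets.values() for v in vs])
        assert [r.id for r in cnvrs] == list(range(1, len(cnvrs) + 1))
        for r1, r2 in zip(cnvrs, cnvrs[1:]):
            assert r1.interval.end <= r2.interval.start or r1.chrom != r2.chrom

    def test_fig_venn_structure_yields_99_consensus_regions(self):
        # pairwise sharing (71,61,51) including a triple intersection of 42
        # must produce 71+61+51-2*42 = 99 multi-program regions
        sets = venn_scenario()
        all_cnvs = [v for vs in sets.values() for v in vs]
        cnvrs = build_cnvrs(all_cnvs, min_callers=2)
        assert len(cnvrs) == 99
        assert len(build_cnvrs(all_cnvs, min_callers=3)) == 42

    def test_monotone_in_min_callers_and_min_snps(self, default_truth):
        all_cnvs = {}
        for min_snps in (3, 5):
            cnvs = []
            for calls in default_truth.calls_by_caller.values():
                cnvs.extend(build_caller_cnvs(filter_calls(calls, min_snps=min_snps)))
            all_cnvs[min_snps] = cnvs
        n22 = len(build_cnvrs(all_cnvs[3], min_callers=2))
        n32 = len(build_cnvrs(all_cnvs[3], min_callers=3))
        n25 = len(build_cnvrs(all_cnvs[5], min_callers=2))
        assert n32 <= n22
        assert n25 <= n22

    def test_order_invariance(self, default_truth):
        cnvs = []
        for calls in default_truth.calls_by_caller.values():
            cnvs.extend(build_caller_cnvs(filter_calls(calls)))
        ref = build_cnvrs(cnvs)
        shuffled = cnvs[:]
        random.Random(0).shuffle(shuffled)
        again = build_cnvrs(shuffled)
        assert [(r.interval, r.callers, r.carriers, r.status) for r in ref] == [
            (r.interval, r.callers, r.carriers, r.status) for r in again
        ]


class TestVennArithmetic:
    def test_published_style_counts_reproduce_union(self):
        assert venn_union_total(**{k: FIG_VENN[k] for k in ("per_caller", "pairwise")},
                                triple=FIG_VENN["triple"]) == 387

    def test_published_style_counts_reproduce_two_program_total(self):
        assert venn_multi_caller_total(FIG_VENN["pairwise"], FIG_VENN["triple"]) == 99


class TestVennCounts:
    def test_venn_scenario_reproduces_three_program_structure(self):
        sets = venn_scenario()
        vc = venn_counts([v for vs in sets.values() for v in vs])
        assert vc.n_cnvs == {"penncnv": 219, "gada": 169, "cnvpartition": 140}
        assert vc.per_caller == vc.n_cnvs  # one-to-one regime
        pair = {tuple(sorted(k)): v for k, v in vc.pairwise.items()}
        assert pair == {
            ("gada", "penncnv"): 71,
            ("cnvpartition", "penncnv"): 61,
            ("cnvpartition", "gada"): 51,
        }
        assert vc.full_intersection == 42
        assert vc.union_total == 387 == vc.n_loci
        assert vc.n_multi_caller == 99

    def test_disjoint_and_identical_sets(self):
        a = [next(iter(venn_scenario().values()))[0]]
        disjoint = venn_counts(
            build_caller_cnvs([make_call(caller="x", sample=s, start=0, end=100) for s in "AB"])
            + build_caller_cnvs([make_call(caller="y", sample=s, start=500, end=600) for s in "AB"])
        )
        assert disjoint.subset_counts == {}
        assert disjoint.union_total == sum(disjoint.per_caller.values()) == 2
        same_iv = [
            make_call(caller=c, sample=s, start=0, end=100)
            for c in ("x", "y", "z") for s in "AB"
        ]
        cnvs = []
        for c in ("x", "y", "z"):
            cnvs.extend(build_caller_cnvs([k for k in same_iv if k.caller_id == c]))
        identical = venn_counts(cnvs)
        assert identical.union_total == 1
        assert all(v == 1 for v in identical.subset_counts.values())

    def test_inclusion_exclusion_exact_on_simulated_output(self, default_truth):
        cnvs = []
        for calls in default_truth.calls_by_caller.values():
            cnvs.extend(build_caller_cnvs(filter_calls(calls)))
        vc = venn_counts(cnvs)
        assert vc.union_total == vc.n_loci


class TestFilterChromosomes:
    def test_include_and_exclude(self):
        from cnvrkit.consensus import filter_chromosomes

        calls = [make_call(chrom=c) for c in ("chr1", "chr2", "chrX")]
        assert [c.chrom for c in filter_chromosomes(calls, exclude=["chrX"])] == [
            "chr1", "chr2",
        ]
        assert [c.chrom for c in filter_chromosomes(calls, include=["chrX"])] == ["chrX"]
        assert filter_chromosomes(calls) == calls  # keeps everything by default
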