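# cnvrkit

Multi-caller consensus calling of copy-number-variation regions (CNVRs)
from SNP-array data, with population summaries, cross-study and QTL
overlap analysis, and qPCR ΔΔCT validation arithmetic.

## The problem

Single CNV-detection programs applied to medium-density SNP-array
intensities (e.g. PennCNV, GADA, cnvPartition on Illumina 50K bovine
chips) disagree substantially: each algorithm has its own error mode, and
a large fraction of calls are program-specific. A standard defence is a
consensus pipeline: keep only per-sample calls with adequate marker
support, require each putative CNV to recur in independent animals, and
require each reported region to be supported by at least two programs.
`cnvrkit` implements that pipeline as a reusable, tested library for
anyone analysing array-based CNV calls in populations (livestock
genomics being the motivating setting), plus the downstream analyses
such studies report.

## The method

Coordinates are 0-based half-open throughout (`length = end − start`);
readers convert from the 1-based inclusive file dialects.

**Stage 0 — call filtering.** A per-sample call from one caller is kept
iff it spans ≥ 3 consecutive markers and its length is strictly below
1 Mb.

**Stage 1 — per-caller CNVs.** For each caller, filtered calls are
single-linkage clustered by ≥ 1 bp overlap (the transitive closure of
pairwise overlap). A cluster becomes a CNV only if it contains calls
from ≥ 2 *distinct* animals; its extent is the union
`[min start, max end)` of its constituents (an intersection-core mode is
available).

**Stage 2 — CNVRs.** CNVs from all callers are clustered the same way;
a cluster supported by ≥ 2 distinct programs becomes a CNVR with the
union extent, the union of carrier animals, and status

* `loss` — every constituent call is a deletion,
* `gain` — every constituent call is a duplication,
* `both` — a mixture.

CNVR frequency is `|carriers| / n_population`. Venn accounting over the
merged loci (per-caller totals, pairwise and triple sharing) satisfies
the three-set inclusion–exclusion identity exactly.

**Comparisons.** Cross-study overlap reports the count and summed bp of
query CNVRs intersecting a reference set. QTL confidence intervals are
deduplicated (drop CI ≥ 30 cM; single-linkage merge when the shared bp
exceed 50 % of the smaller interval) before CNVR–QTL overlap counting,
and a permutation test re-places the CNVR set uniformly at random
(preserving each region's chromosome and length, placements kept
disjoint) to give an empirical enrichment p-value
`(1 + #{null ≥ observed}) / (n_perm + 1)`.

**qPCR validation.** With triplicate cycle-threshold (CT) measurements,
`ΔCT = CT(target) − CT(control region)`, `ΔΔCT = ΔCT − ΔCT(calibrator)`
and the relative copy number `NR = 2 × 2^(−ΔΔCT)`: NR ≈ 2 means two
copies (normal), NR ≈ 1 one-copy loss, NR ≈ 3+ gain. Standard-curve
amplification efficiency is `E = 10^(−1/slope) − 1`.

A seeded synthetic-study generator (50K-like marker map, planted CNVRs
with realistic lengths/statuses/frequencies, three noisy callers) makes
every stage testable end to end; see `docs/methods.md`.

## Worked example

Simulate a small study (5 × 20 Mb chromosomes, 200 animals, 30 planted
CNVRs, three callers) and run the full pipeline:

```bash
cnvrkit run --seed 11 --outdir demo --n-samples 200 --n-cnvrs 30
```

prints

```
28 CNVRs from 87 caller CNVs; 28/28 match planted truth (100.0% of count, 53.9% of length)
results in demo
```

i.e. the two-stage consensus turned 87 per-caller CNVs into 28 CNVRs —
two planted regions were bridged by boundary-jittered calls — and every
reported region overlaps a planted one (the recovered extents cover the
planted set at 53.9 % of length because extents are trimmed to marker
positions and jittered). `demo/` then contains the per-caller CNV table,
the CNVR table (`cnvrs.tsv` + BED), the Venn report and the summary:

```
id  chrom  start    end      length_kb  n_callers  callers                    status  n_carriers  frequency
1   chr1   6456246  7149324  693.08     3          cnvpartition,gada,penncnv  both    40          0.2
2   chr1   7771523  8308954  537.43     3          cnvpartition,gada,penncnv  loss    41          0.205
```

The same stages are available as individual subcommands
(`simulate`, `merge-calls`, `build-cnvr`, `summarize`, `compare`,
`qtl-overlap`, `qpcr`) and as plain library calls
(`cnvrkit.consensus.build_cnvrs`, etc.).

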