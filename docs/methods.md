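# Methods

## Interval conventions

All genomic intervals are 0-based half-open `[start, end)`, so
`length = end − start` and abutting intervals share no base. File
dialects that use 1-based inclusive coordinates (PennCNV rawcnv, the
generic caller TSV, SNP maps, QTL tables, the CNVR result TSV) are
converted on read and back on write; BED files pass through unchanged.
Kb and Mb are decimal (1 Kb = 1,000 bp). "Overlap" means ≥ 1 shared bp
by default; every clustering entry point exposes `min_overlap_bp` for a
stricter criterion. The rawcnv `length=` field is ignored and recomputed
from coordinates, since published files embed locale-dependent thousands
separators.

Single-linkage clustering (the transitive closure of pairwise overlap)
is computed with a sorted sweep: records are ordered by
(chrom, start, end, sample, caller) and a cluster stays open while the
next start lies inside the running maximum end. The canonical ordering
makes the pipeline invariant to input record order. The test suite
checks the sweep against an all-pairs union-find oracle and a
per-basepair boolean-array oracle on small genomes.

## Consensus model

The pipeline encodes three nested confidence requirements standard for
array-based CNV surveys:

1. **Call filter** (`min_snps = 3`, `max_len_bp = 1,000,000`, strict):
   a per-sample call must span three or more consecutive markers and be
   shorter than 1 Mb. The size filter applies to raw calls only; merged
   extents may legitimately exceed it, which is why the filter is not
   re-applied to CNVs or CNVRs.
2. **Recurrence across animals** (`min_samples = 2`): a per-caller CNV
   is a single-linkage cluster of calls containing ≥ 2 distinct sample
   ids. The same animal called twice does not qualify. The cluster
   extent defaults to the union of its constituents; an
   `intersection` span mode returns the core shared by all constituents
   and drops chained clusters whose core is empty. Union is the default
   because it keeps stage-1 and stage-2 semantics identical and because
   observed CNVR maxima exceed the per-call size cap, which only union
   semantics produce.
3. **Concordance across programs** (`min_callers = 2`): CNVRs are
   single-linkage clusters over all callers' CNVs containing ≥ 2
   distinct caller ids, with union extent and the union of carriers.
   Output CNVRs are pairwise disjoint, sorted, and numbered ordinally.

Status is all-or-none: `loss` if every constituent call state is loss,
`gain` if all gain, otherwise `both`. Note the asymmetry this induces: a
single discordant call anywhere in a region flips it to `both`, so the
reported `both` fraction is an upper bound on truly bidirectional loci.

Venn accounting is done over merged loci (clusters). A locus counts
toward a caller subset if every member caller contributed ≥ 1 CNV, so
pairwise counts include the triple intersection and the inclusion–
exclusion identity `union = Σ singles − Σ pairs + triple` holds exactly
on locus counts. Raw per-caller CNV counts are reported alongside; the
two coincide unless one locus absorbs two CNVs of the same caller
(chaining), which the printed arithmetic of three-caller studies
implicitly assumes away. Helper functions expose the pure arithmetic
(`venn_union_total`, `venn_multi_caller_total = Σ pairs − 2 × triple`)
for checking published figures.

The frequency denominator defaults to the number of distinct animals
observed in the input call files and can be overridden with the true
number of animals screened, which is usually larger (animals with no
calls are invisible to the files but belong in the denominator).

## Summaries

Mean length is total/`n`; median over an even count is the midpoint of
the two central values. Frequency-threshold counts use strict `freq > t`
("above"), and carrier bins strict `carriers > b` ("more than").
Per-chromosome coverage is CNVR bp on the chromosome divided by
chromosome length; genome coverage divides by the summed map length.

## QTL deduplication and enrichment

QTL records carry an explicit bp confidence interval plus its width in
centiMorgans; no cM↔bp conversion is attempted because public QTL
databases mix coordinate systems. Records with `ci_cm ≥ 30` are dropped
(strict "less than 30 cM"). Remaining QTLs are single-linkage merged
when the shared bp exceed 50 % of the *smaller* interval — measured
against the smaller because the purpose is collapsing nested re-reports
of one QTL; a reciprocal mode is available. Each cluster is represented
by its narrowest-CI record (ties: smaller start, then id).

The enrichment test formalizes "QTL density is higher inside CNVRs than
genome-wide": observed statistic = fraction of deduplicated QTLs
overlapping ≥ 1 CNVR; the null re-places the CNVR set uniformly at
random `n_perm` times, preserving each region's chromosome and length
and keeping placements pairwise disjoint by rejection sampling (regions
placed longest-first, ≤ 1000 attempts each, error on exhaustion — only
reachable when regions nearly tile a chromosome). The empirical p-value
`(1 + #{null ≥ observed}) / (n_perm + 1)` is never 0 and is bit-exact
reproducible under a fixed seed. Gene-annotation overlap reuses the same
machinery with a containment flag distinguishing genes harbored within a
CNVR from partial overlaps.

## qPCR arithmetic

Replicate CTs are averaged per region before any subtraction (triplicate
in the standard assay; the per-region replicate SD is reported for error
bars, with no outlier rejection). `NR = 2 × 2^(−ΔΔCT)` against a no-CNV
calibrator assumed to carry two copies of the control region; the
calibrator may be one flagged animal or a panel (their mean ΔCT is
used). Classification bands place the midpoints between the canonical
anchors NR ≈ 0/1 (loss), ≈ 2 (normal), ≈ 3+ (gain): `loss` below 1.5,
`gain` at or above 2.5, `normal` between; both cutoffs are parameters.
Standard curves are ordinary least squares of CT on log10 template
amount over ≥ 3 dilution points, with efficiency `10^(−1/slope) − 1`;
a non-negative slope marks the curve invalid. Efficiency is reported but
not used in NR by default (the assay design checks that target and
control efficiencies are approximately equal); an optional corrected
mode replaces base 2 with `1 + mean(E)`.

## Synthetic study generator

The generator emulates a medium-density SNP-array CNV survey well enough
to exercise every pipeline stage; it does not simulate probe
intensities, GC waves, genotyping error or linkage structure, so passing
tests demonstrate the *pipeline's* correctness on realistic call
geometry, not caller performance on real intensity data.

Defaults (one place each, all overridable):

| parameter | default | rationale |
|---|---|---|
| genome | 5 chromosomes × 20 Mb | small enough for second-scale tests |
| marker spacing | exponential gaps, mean 51.5 Kb | 50K bovine chip density |
| animals | 200 | keeps binomial carrier counts informative |
| planted CNVRs | 30, pairwise disjoint, ≥ 3 markers | rejection-sampled placement |
| lengths | log-normal (median ≈ 152 Kb, σ_log 0.75) clamped to [27.01 Kb, 1.31 Mb] | observed array-CNVR length range |
| status mix | loss : gain : both = 81 : 1 : 17 | loss-dominated, as in array surveys |
| frequency | Beta(0.8, 12) restricted to [0.02, 0.28] | rare-variant-skewed, ceiling at the highest observed population frequency; floor keeps ≥ 2 expected carriers detectable at n = 200 |
| caller sensitivity | 0.90 / 0.85 / 0.80 | three partially concordant callers |
| boundary jitter | ± 2 marker indices | breakpoint uncertainty of array callers |
| false positives | Poisson, 0.001 per sample-Mb, 3–5-marker spans, 80 % loss | see below |
| state errors | rate 0.0 (knob available) | see below |

Carriers are i.i.d. Bernoulli(frequency); each carrier of a `both`
region is independently a loss or gain carrier. Emitted calls snap to
marker positions (first marker to last marker + 1), so even noiseless
recovery reproduces planted regions only up to their marker support —
the exact trimmed extent is asserted in the noiseless round-trip test.

Two noise defaults deserve justification. The false-positive rate is
0.001/sample·Mb (≈ 0.1 spurious calls per animal genome, consistent
with post-QC call counts on 50K arrays). Because a 3–5-marker span at
51.5 Kb spacing is 100–250 Kb, much larger rates make spurious calls
from different animals overlap by chance, manufacturing consensus
regions out of pure noise and inflating genome coverage far beyond
anything an array survey reports; at the default, unshared false
positives are reliably screened out by the two-animal and two-caller
rules, which is exactly the behaviour the consensus design exists to
provide. The state-error rate defaults to 0 because the all-or-none
status rule is maximally sensitive to it: with dozens of constituent
calls per region, even a 2 % flip rate converts most regions to `both`
and erases the planted 81:1:17 mix. Even with state errors off, the
recovered `both` fraction modestly exceeds the planted one, because a
single spurious gain call landing inside a loss region flips its
status — a realistic artefact worth remembering when interpreting
reported status breakdowns.

Randomness flows from one seed through independent named substreams
(map, truth, one per caller), so the truth is unchanged when caller
noise parameters change, and a fixed seed reproduces every output file
bit-exactly. A `full_scale_config()` profile (29 autosomes, 2047
animals) exists for larger experiments; the test suite uses the small
default only. `venn_scenario()` deterministically lays out caller CNV
sets realizing any requested three-way Venn structure (default:
per-caller 219/169/140, pairwise 71/61/51, triple 42) for exact
concordance-arithmetic tests.

## Numerical and degenerate-input choices

* Strict inequalities follow the stated rules: size `< 1 Mb`, CI
  `< 30 cM`, frequency "above t" `> t`, carriers "more than b" `> b`.
* Ties in clustering are broken by the canonical
  (chrom, start, end, sample, caller) sort; chromosome order is natural
  (chr2 < chr10).
* Empty inputs: `union_extent` of nothing and status of an empty state
  multiset are errors; merging, intersect length and summaries of empty
  sets return empty/zero results; an empty QTL set makes the enrichment
  observed fraction undefined and raises.
* Copy-neutral (cn = 2) rawcnv records are rejected with a warning, not
  an error; malformed lines report their line number.
* X-chromosome calls are kept; excluding them is an explicit
  `filter_chromosomes` / `--exclude-chrom` choice.

## Known limitations

* Stage order is fixed: within-caller recurrence first, cross-caller
  concordance second; pipelines that intersect programs per sample
  before recurrence would count differently.
* A CNV partially overlapping two disjoint CNVs of another caller is
  counted once in Venn accounting (locus-based), not once per partner.
* The permutation null preserves length and chromosome but not marker
  density, so enrichment p-values ignore array-design confounding.
* No LRR/BAF-level simulation or re-implementation of the callers
  themselves; caller outputs are the pipeline's inputs.
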