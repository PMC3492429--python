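"""Synthetic SNP-array CNV study generator.

Emulates a medium-density (50K-like) bovine genotyping study analysed by
three CNV callers with partial concordance: a marker map with
exponentially distributed inter-SNP gaps (mean 51.5 Kb), planted disjoint
CNVRs whose lengths, loss/gain/both status mix and population
frequencies follow the distributions observed in array-based cattle CNV
scans, per-animal carrier assignment, and noisy per-caller call lists
(imperfect sensitivity, SNP-index boundary jitter, state errors and
unshared false positives).

Caller concordance arises solely from shared truth plus independent
noise — there is no explicit inter-caller correlation parameter.

Everything is driven by one :class:`numpy.random.Generator` derived from
``SimConfig.seed``, so a fixed seed reproduces every file bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import GenomeMap, Interval
from .io_formats import GAIN, LOSS, CnvCall, SnpMap, write_generic_calls, write_genome_map, write_snp_map
from .consensus import CallerCnv

__all__ = [
    "CallerProfile",
    "SimConfig",
    "PlantedCnvr",
    "SimTruth",
    "simulate_snp_map",
    "simulate_truth",
    "simulate_caller_outputs",
    "simulate_study",
    "write_study",
    "venn_scenario",
]


@dataclass(frozen=True)
class CallerProfile:
    """Error model for one emulated CNV caller."""

    name: str
    sensitivity: float = 0.9  # P(emit a call | carrier)
    fp_rate_per_sample_mb: float = 0.001  # Poisson rate of spurious calls
    boundary_jitter_snps: int = 2  # max endpoint shift, in SNP indices
    state_error_rate: float = 0.0  # P(loss/gain flipped)

    def __post_init__(self) -> None:
        for name in ("sensitivity", "fp_rate_per_sample_mb", "state_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


DEFAULT_CALLERS = (
    CallerProfile("penncnv", sensitivity=0.90),
    CallerProfile("gada", sensitivity=0.85),
    CallerProfile("cnvpartition", sensitivity=0.80),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the generator.

    Defaults describe a small study that exercises every pipeline stage
    in seconds: 5 chromosomes of 20 Mb screened in 200 animals with 30
    planted CNVRs.  Marker spacing, the CNVR length range, the
    81:1:17 loss/gain/both status mix and the frequency ceiling follow
    the values characteristic of 50K-array cattle CNV scans.
    """

    seed: int = 0
    n_chrom: int = 5
    chrom_length_bp: int = 20_000_000
    mean_snp_spacing_bp: float = 51_500.0
    n_samples: int = 200
    n_true_cnvrs: int = 30
    # log-normal CNVR lengths, clamped to the observed range
    length_log_mean: float = np.log(151_690.0)
    length_log_sd: float = 0.75
    min_length_bp: int = 27_010
    max_length_bp: int = 1_310_000
    status_proportions: tuple[float, float, float] = (81 / 99, 1 / 99, 17 / 99)
    # carrier frequency ~ Beta(a, b), resampled into [freq_min, freq_max]
    freq_beta_a: float = 0.8
    freq_beta_b: float = 12.0
    freq_min: float = 0.02
    freq_max: float = 0.28
    callers: tuple[CallerProfile, ...] = DEFAULT_CALLERS

    def __post_init__(self) -> None:
        if abs(sum(self.status_proportions) - 1.0) > 1e-9:
            raise ValueError("status proportions must sum to 1")
        if not 0 < self.freq_min <= self.freq_max <= 1:
            raise ValueError("need 0 < freq_min <= freq_max <= 1")


def full_scale_config(seed: int = 0) -> SimConfig:
    """A 29-autosome, 2047-animal survey-scale profile (slow; not used by the tests)."""
    return SimConfig(
        seed=seed,
        n_chrom=29,
        chrom_length_bp=87_000_000,
        n_samples=2047,
        n_true_cnvrs=99,
    )


@dataclass(frozen=True)
class PlantedCnvr:
    """Ground truth for one planted region."""

    interval: Interval
    status: str  # loss | gain | both
    frequency: float
    carriers: tuple[str, ...]
    carrier_states: tuple[str, ...]  # per carrier, loss or gain
    snp_index_span: tuple[int, int]  # first/last marker index on its chrom


@dataclass
class SimTruth:
    """Everything the generator knows: maps, planted regions, emitted calls."""

    config: SimConfig
    snp_map: SnpMap
    genome_map: GenomeMap
    cnvrs: list[PlantedCnvr]
    calls_by_caller: dict[str, list[CnvCall]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(self.config.n_samples)]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent substreams per stage so adding noise later never shifts truth
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_snp_map(config: SimConfig) -> tuple[SnpMap, GenomeMap]:
    """Draw a marker map with i.i.d. exponential inter-SNP gaps.

    Gaps have the configured mean (rounded up to >= 1 bp); positions run
    until the chromosome end.
    """
    if config.chrom_length_bp < config.mean_snp_spacing_bp:
        raise ValueError("chromosome shorter than one mean SNP gap")
    rng = _rng(config, 1)
    positions: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for ci in range(config.n_chrom):
        chrom = f"chr{ci + 1}"
        n_draw = int(config.chrom_length_bp / config.mean_snp_spacing_bp * 2) + 10
        gaps = np.maximum(
            1, rng.exponential(config.mean_snp_spacing_bp, size=n_draw).astype(np.int64)
        )
        pos = np.cumsum(gaps)
        pos = pos[pos < config.chrom_length_bp]
        positions[chrom] = pos
        lengths[chrom] = config.chrom_length_bp
    return SnpMap(positions), GenomeMap(lengths)


def _draw_frequency(rng: np.random.Generator, config: SimConfig) -> float:
    if config.freq_min == config.freq_max:  # degenerate: fixed planted frequency
        return config.freq_min
    for _ in range(10_000):
        f = rng.beta(config.freq_beta_a, config.freq_beta_b)
        if config.freq_min <= f <= config.freq_max:
            return float(f)
    raise RuntimeError("frequency rejection sampling failed; check Beta parameters")


def simulate_truth(
    config: SimConfig, snp_map: SnpMap, genome_map: GenomeMap
) -> SimTruth:
    """Plant disjoint CNVRs and assign carriers.

    Regions are placed by rejection sampling (uniform chromosome choice
    weighted by length, uniform start), must span >= 3 markers and must
    not touch an already-planted region.  Status is drawn from the
    configured loss/gain/both proportions; carriers are i.i.d.
    Bernoulli(frequency) per animal, and each carrier of a "both" region
    is independently a loss or gain carrier.
    """
    rng = _rng(config, 2)
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    chroms = genome_map.chrom_names
    weights = np.array([genome_map[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    planted: list[PlantedCnvr] = []
    occupied: dict[str, list[Interval]] = {c: [] for c in chroms}
    statuses = rng.choice(
        ["loss", "gain", "both"], size=config.n_true_cnvrs, p=config.status_proportions
    )
    for k in range(config.n_true_cnvrs):
        for attempt in range(5000):
            chrom = str(rng.choice(chroms, p=weights))
            length = int(
                np.clip(
                    rng.lognormal(config.length_log_mean, config.length_log_sd),
                    config.min_length_bp,
                    config.max_length_bp,
                )
            )
            if length >= genome_map[chrom]:
                continue
            start = int(rng.integers(0, genome_map[chrom] - length))
            iv = Interval(chrom, start, start + length)
            pos = snp_map[chrom]
            lo = int(np.searchsorted(pos, iv.start, side="left"))
            hi = int(np.searchsorted(pos, iv.end, side="left"))
            if hi - lo < 3:
                continue
            if any(
                iv.start < o.end and o.start < iv.end for o in occupied[chrom]
            ):
                continue
            break
        else:
            raise RuntimeError(
                f"could not place planted CNVR {k + 1}/{config.n_true_cnvrs} disjointly"
            )
        occupied[chrom].append(iv)
        freq = _draw_frequency(rng, config)
        carrier_mask = rng.random(config.n_samples) < freq
        carriers = tuple(s for s, m in zip(samples, carrier_mask) if m)
        status = str(statuses[k])
        if status == "both":
            carrier_states = tuple(
                LOSS if rng.random() < 0.5 else GAIN for _ in carriers
            )
        else:
            carrier_states = tuple(status for _ in carriers)
        planted.append(
            PlantedCnvr(
                interval=iv,
                status=status,
                frequency=freq,
                carriers=carriers,
                carrier_states=carrier_states,
                snp_index_span=(lo, hi - 1),
            )
        )
    planted.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return SimTruth(config=config, snp_map=snp_map, genome_map=genome_map, cnvrs=planted)


def _snap_call(
    chrom: str, pos: np.ndarray, i0: int, i1: int, sample: str,
    caller: str, state: str,
) -> CnvCall:
    """Build a call spanning marker indices [i0, i1] inclusive."""
    start = int(pos[i0])
    end = int(pos[i1]) + 1
    return CnvCall(
        sample_id=sample,
        caller_id=caller,
        interval=Interval(chrom, start, end),
        state=state,
        n_snps=i1 - i0 + 1,
        copy_number=1 if state == LOSS else 3,
    )


def simulate_caller_outputs(truth: SimTruth) -> dict[str, list[CnvCall]]:
    """Emit per-caller call lists from the planted truth.

    For every carrier x planted region x caller: the call is emitted with
    the caller's sensitivity, both endpoints are jittered by up to the
    caller's jitter (in marker indices, clamped so >= 3 markers remain),
    and the state is flipped at the caller's state-error rate.  False
    positives are spurious 3-5 marker calls placed uniformly per sample
    at the configured per-Mb Poisson rate.  The result is also stored on
    ``truth.calls_by_caller``.
    """
    config = truth.config
    genome_mb = truth.genome_map.total_length / 1e6
    out: dict[str, list[CnvCall]] = {}
    for ci, caller in enumerate(config.callers):
        rng = _rng(config, 100 + ci)
        calls: list[CnvCall] = []
        for planted in truth.cnvrs:
            chrom = planted.interval.chrom
            pos = truth.snp_map[chrom]
            lo, hi = planted.snp_index_span
            for sample, state in zip(planted.carriers, planted.carrier_states):
                if rng.random() >= caller.sensitivity:
                    continue
                j = caller.boundary_jitter_snps
                if j > 0:
                    i0 = lo + int(rng.integers(-j, j + 1))
                    i1 = hi + int(rng.integers(-j, j + 1))
                else:
                    i0, i1 = lo, hi
                i0 = max(0, i0)
                i1 = min(len(pos) - 1, i1)
                if i1 - i0 + 1 < 3:  # keep the call detectable
                    i0, i1 = lo, hi
                if rng.random() < caller.state_error_rate:
                    state_out = GAIN if state == LOSS else LOSS
                else:
                    state_out = state
                calls.append(_snap_call(chrom, pos, i0, i1, sample, caller.name, state_out))
        # independent false positives, unshared between callers and samples
        n_fp_total = rng.poisson(
            caller.fp_rate_per_sample_mb * genome_mb * config.n_samples
        )
        chroms = truth.genome_map.chrom_names
        weights = np.array([truth.genome_map[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        for _ in range(n_fp_total):
            sample = f"S{int(rng.integers(0, config.n_samples)):04d}"
            chrom = str(rng.choice(chroms, p=weights))
            pos = truth.snp_map[chrom]
            span = int(rng.integers(3, 6))
            if len(pos) <= span:
                continue
            i0 = int(rng.integers(0, len(pos) - span))
            state = LOSS if rng.random() < 0.8 else GAIN
            calls.append(_snap_call(chrom, pos, i0, i0 + span - 1, sample, caller.name, state))
        out[caller.name] = calls
    truth.calls_by_caller = out
    return out


def simulate_study(config: SimConfig) -> SimTruth:
    """Run the full generator: map, truth, caller outputs."""
    snp_map, genome_map = simulate_snp_map(config)
    truth = simulate_truth(config, snp_map, genome_map)
    simulate_caller_outputs(truth)
    return truth


def write_study(truth: SimTruth, outdir) -> dict[str, Path]:
    """Write the simulated study to a directory of plain-text files.

    Produces ``snp_map.tsv``, ``genome.tsv``, ``truth_cnvrs.tsv`` and one
    ``calls_<caller>.tsv`` per caller (generic dialect).  Returns the
    written paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["snp_map"] = outdir / "snp_map.tsv"
    write_snp_map(truth.snp_map, paths["snp_map"])
    paths["genome"] = outdir / "genome.tsv"
    write_genome_map(truth.genome_map, paths["genome"])
    truth_path = outdir / "truth_cnvrs.tsv"
    with open(truth_path, "w") as fh:
        fh.write("chrom\tstart\tend\tstatus\tfrequency\tn_carriers\n")
        for p in truth.cnvrs:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start + 1}\t{p.interval.end}\t"
                f"{p.status}\t{p.frequency:.6f}\t{len(p.carriers)}\n"
            )
    paths["truth"] = truth_path
    for caller, calls in truth.calls_by_caller.items():
        p = outdir / f"calls_{caller}.tsv"
        write_generic_calls(calls, p)
        paths[f"calls_{caller}"] = p
    return paths


# ---------------------------------------------------------------------------
# Deterministic Venn-structured caller sets

def venn_scenario(
    region_counts: dict[frozenset, int] | None = None,
    caller_names: Sequence[str] = ("penncnv", "gada", "cnvpartition"),
    slot_bp: int = 10_000,
    gap_bp: int = 10_000,
    chrom: str = "chr1",
) -> dict[str, list[CallerCnv]]:
    """Build per-caller CNV sets realizing an exact three-way Venn diagram.

    ``region_counts`` maps each non-empty subset of callers to the number
    of loci detected by exactly that subset.  Loci are laid out as
    disjoint slots along one chromosome, so the pipeline's cross-caller
    clustering recovers the subsets exactly.  The default realizes the
    concordance structure of a three-caller 50K-array study: per-caller
    totals 219/169/140 with pairwise sharing 71/61/51 and 42 loci common
    to all three.
    """
    a, b, c = caller_names
    if region_counts is None:
        region_counts = {
            frozenset([a]): 129,
            frozenset([b]): 89,
            frozenset([c]): 70,
            frozenset([a, b]): 29,
            frozenset([a, c]): 19,
            frozenset([b, c]): 9,
            frozenset([a, b, c]): 42,
        }
    out: dict[str, list[CallerCnv]] = {name: [] for name in caller_names}
    slot = 0
    for subset in sorted(region_counts, key=lambda s: sorted(s)):
        for _ in range(region_counts[subset]):
            start = slot * (slot_bp + gap_bp)
            iv = Interval(chrom, start, start + slot_bp)
            for name in subset:
                out[name].append(
                    CallerCnv(
                        caller_id=name,
                        interval=iv,
                        carriers=frozenset({"S0001", "S0002"}),
                        states=("loss", "loss"),
                    )
                )
            slot += 1
    return out
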