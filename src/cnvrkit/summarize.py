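"""Population and genome summaries of a CNVR set.

Length statistics (Kb are decimal: 1 Kb = 1,000 bp), the loss/gain/both
status breakdown, counts of CNVRs above a ladder of population-frequency
thresholds ("above" is strict), carrier-count bins ("more than" is
strict), and per-chromosome counts, lengths and coverage fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomeMap, chrom_sort_key
from .consensus import Cnvr

__all__ = ["CnvrSummary", "compute_frequency", "attach_frequencies", "summarize_cnvrs"]

DEFAULT_THRESHOLDS = (0.05, 0.04, 0.03, 0.02, 0.01)
DEFAULT_CARRIER_BINS = (100, 10, 3)


def compute_frequency(cnvr: Cnvr, n_population: int) -> float:
    """Population frequency of a CNVR: carriers / animals screened.

    The denominator is the number of animals screened, which may exceed the
    number of animals with any call.
    """
    if n_population <= 0:
        raise ValueError("n_population must be positive")
    n_carriers = len(cnvr.carriers)
    if n_carriers == 0:
        raise ValueError(f"CNVR {cnvr.id} has no carriers")
    if n_carriers > n_population:
        raise ValueError(
            f"CNVR {cnvr.id}: {n_carriers} carriers exceed population {n_population}"
        )
    return n_carriers / n_population


def attach_frequencies(cnvrs: Iterable[Cnvr], n_population: int) -> None:
    """Set ``frequency`` in place on every CNVR."""
    for r in cnvrs:
        r.frequency = compute_frequency(r, n_population)


@dataclass
class CnvrSummary:
    """Aggregate description of one CNVR set."""

    n_cnvrs: int
    total_length_bp: int
    mean_length_bp: float
    median_length_bp: float
    min_length_bp: int
    max_length_bp: int
    status_counts: dict[str, int]
    threshold_counts: dict[float, int]
    carrier_bin_counts: dict[int, int]
    genome_coverage: float | None
    per_chrom: pd.DataFrame = field(repr=False, default=None)

    @property
    def mean_length_kb(self) -> float:
        return self.mean_length_bp / 1_000.0

    @property
    def median_length_kb(self) -> float:
        return self.median_length_bp / 1_000.0

    def to_frame(self) -> pd.DataFrame:
        """One-column key/value frame for TSV export."""
        rows = [
            ("n_cnvrs", self.n_cnvrs),
            ("total_length_bp", self.total_length_bp),
            ("total_length_mb", round(self.total_length_bp / 1e6, 2)),
            ("mean_length_kb", round(self.mean_length_kb, 2)),
            ("median_length_kb", round(self.median_length_kb, 2)),
            ("min_length_kb", round(self.min_length_bp / 1e3, 2)),
            ("max_length_kb", round(self.max_length_bp / 1e3, 2)),
        ]
        for status in ("loss", "gain", "both"):
            rows.append((f"n_{status}", self.status_counts.get(status, 0)))
        for t, n in sorted(self.threshold_counts.items(), reverse=True):
            rows.append((f"n_freq_above_{t:g}", n))
        for b, n in sorted(self.carrier_bin_counts.items(), reverse=True):
            rows.append((f"n_carriers_above_{b}", n))
        if self.genome_coverage is not None:
            rows.append(("genome_coverage_pct", round(100 * self.genome_coverage, 2)))
        return pd.DataFrame(rows, columns=["metric", "value"])


def summarize_cnvrs(
    cnvrs: Sequence[Cnvr],
    genome_map: GenomeMap | None = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    carrier_bins: Sequence[int] = DEFAULT_CARRIER_BINS,
) -> CnvrSummary:
    """Summarize a finalized CNVR set.

    Frequency-threshold counts require frequencies to be attached (see
    :func:`attach_frequencies`); they are reported as NaN-free strict
    "above t" counts.  Median over an even count is the mean of the two
    central lengths.
    """
    lengths = np.array([r.interval.length for r in cnvrs], dtype=np.int64)
    status_counts: dict[str, int] = {"loss": 0, "gain": 0, "both": 0}
    for r in cnvrs:
        status_counts[r.status] = status_counts.get(r.status, 0) + 1

    freqs = [r.frequency for r in cnvrs if r.frequency is not None]
    threshold_counts = {
        float(t): int(sum(f > t for f in freqs)) for t in thresholds
    }
    carrier_bin_counts = {
        int(b): int(sum(len(r.carriers) > b for r in cnvrs)) for b in carrier_bins
    }

    per_chrom = None
    coverage = None
    if cnvrs:
        df = pd.DataFrame(
            {
                "chrom": [r.chrom for r in cnvrs],
                "length": [r.interval.length for r in cnvrs],
            }
        )
        agg = df.groupby("chrom", sort=False).agg(
            n_cnvrs=("length", "size"), total_bp=("length", "sum")
        )
        agg = agg.reindex(sorted(agg.index, key=chrom_sort_key)).reset_index()
        if genome_map is not None:
            agg["chrom_length"] = [genome_map[c] for c in agg["chrom"]]
            agg["fraction"] = agg["total_bp"] / agg["chrom_length"]
            coverage = float(lengths.sum() / genome_map.total_length)
        per_chrom = agg
    elif genome_map is not None:
        coverage = 0.0

    return CnvrSummary(
        n_cnvrs=len(cnvrs),
        total_length_bp=int(lengths.sum()) if len(lengths) else 0,
        mean_length_bp=float(lengths.mean()) if len(lengths) else float("nan"),
        median_length_bp=float(np.median(lengths)) if len(lengths) else float("nan"),
        min_length_bp=int(lengths.min()) if len(lengths) else 0,
        max_length_bp=int(lengths.max()) if len(lengths) else 0,
        status_counts=status_counts,
        threshold_counts=threshold_counts,
        carrier_bin_counts=carrier_bin_counts,
        genome_coverage=coverage,
        per_chrom=per_chrom,
    )
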