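"""Readers and writers for caller outputs, marker maps and result tables.

Supported dialects:

* PennCNV ``rawcnv`` text output (read);
* a generic tab-separated caller table with a header
  (``sample  chrom  start  end  state  [n_snps]  [cn]``), covering callers
  such as GADA and cnvPartition once exported to a flat table;
* SNP map and genome (chromosome-length) TSVs;
* QTL tables with explicit bp confidence intervals plus a cM width column;
* the CNVR result table (TSV + BED companion).

All file dialects carry 1-based inclusive coordinates unless stated
otherwise; everything is converted to 0-based half-open
:class:`~cnvrkit.intervals.Interval` on load and converted back on write.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomeMap, Interval, chrom_sort_key, count_snps_in

__all__ = [
    "CnvCall",
    "SnpMap",
    "QtlRecord",
    "GenericDialect",
    "read_penncnv_rawcnv",
    "read_generic_calls",
    "write_generic_calls",
    "read_snp_map",
    "write_snp_map",
    "read_genome_map",
    "write_genome_map",
    "read_qtl_table",
    "write_caller_cnv_table",
    "read_caller_cnv_table",
    "write_cnvr_table",
    "read_cnvr_table",
]

log = logging.getLogger(__name__)

LOSS = "loss"
GAIN = "gain"


@dataclass(frozen=True)
class CnvCall:
    """One caller's CNV call on one animal."""

    sample_id: str
    caller_id: str
    interval: Interval
    state: str  # "loss" | "gain"
    n_snps: int
    copy_number: int | None = None

    def __post_init__(self) -> None:
        if self.state not in (LOSS, GAIN):
            raise ValueError(f"state must be loss|gain, got {self.state!r}")
        if self.n_snps < 1:
            raise ValueError(f"n_snps must be >= 1, got {self.n_snps}")
        if self.copy_number is not None:
            if self.copy_number < 2 and self.state != LOSS:
                raise ValueError(f"cn={self.copy_number} inconsistent with state gain")
            if self.copy_number > 2 and self.state != GAIN:
                raise ValueError(f"cn={self.copy_number} inconsistent with state loss")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class SnpMap(Mapping[str, np.ndarray]):
    """Per-chromosome sorted marker positions, stored 0-based.

    File positions are 1-based; they are shifted on load so that marker *p*
    in a file occupies internal position ``p - 1`` and an interval
    ``[start, end)`` contains it iff ``start <= p - 1 < end``.
    """

    def __init__(self, positions: Mapping[str, Sequence[int]]):
        self._pos: dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.asarray(sorted(pos), dtype=np.int64)
            if len(arr) != len(np.unique(arr)):
                raise ValueError(f"duplicate SNP positions on {chrom}")
            self._pos[chrom] = arr

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self._pos[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._pos)

    def __len__(self) -> int:
        return len(self._pos)

    @property
    def n_snps(self) -> int:
        return sum(len(v) for v in self._pos.values())

    def count_in(self, interval: Interval) -> int:
        return count_snps_in(interval, self)


@dataclass(frozen=True)
class QtlRecord:
    """A QTL confidence interval with trait label and cM width."""

    qtl_id: str
    trait: str
    interval: Interval
    ci_cm: float

    def __post_init__(self) -> None:
        if self.ci_cm <= 0:
            raise ValueError(f"ci_cm must be positive, got {self.ci_cm}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


# ---------------------------------------------------------------------------
# PennCNV rawcnv dialect

# chr3:1500-9999  numsnp=4  length=8,500  state2,cn=1  S01.txt  startsnp=rsA endsnp=rsB
_RAWCNV = re.compile(
    r"^(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>\d+)\s+"
    r"length=(?P<length>[\d,]+)\s+"
    r"state(?P<state>\d),cn=(?P<cn>\d)\s+"
    r"(?P<samplefile>\S+)"
)


def _sample_from_file_token(token: str) -> str:
    base = token.replace("\\", "/").rsplit("/", 1)[-1]
    return base.rsplit(".", 1)[0] if "." in base else base


def read_penncnv_rawcnv(path, caller_id: str = "penncnv") -> list[CnvCall]:
    """Parse a PennCNV ``rawcnv`` file into normalized calls.

    Copy numbers 0 and 1 map to loss, 3 and 4 to gain.  Records with cn=2
    (copy-neutral) are dropped with a warning.  The ``length=`` field is
    ignored and recomputed from coordinates, which are 1-based inclusive
    in the file.
    """
    calls: list[CnvCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            m = _RAWCNV.match(line.strip())
            if m is None:
                raise ValueError(f"{path}:{lineno}: malformed rawcnv record")
            cn = int(m["cn"])
            if cn == 2:
                log.warning("%s:%d: copy-neutral record (cn=2) skipped", path, lineno)
                continue
            if cn > 4:
                raise ValueError(f"{path}:{lineno}: unsupported cn={cn}")
            state = LOSS if cn < 2 else GAIN
            calls.append(
                CnvCall(
                    sample_id=_sample_from_file_token(m["samplefile"]),
                    caller_id=caller_id,
                    interval=Interval(m["chrom"], int(m["start"]) - 1, int(m["end"])),
                    state=state,
                    n_snps=int(m["numsnp"]),
                    copy_number=cn,
                )
            )
    log.info("read %d calls from %s (caller=%s)", len(calls), path, caller_id)
    return calls


# ---------------------------------------------------------------------------
# Generic caller table dialect

@dataclass
class GenericDialect:
    """How to interpret a generic tab-separated caller table.

    ``one_based``: file start/end are 1-based inclusive (the common caller
    convention); set False for BED-style half-open input.
    ``state_map``: extra state tokens mapped onto loss/gain
    (e.g. ``{"deletion": "loss", "duplication": "gain"}``).
    """

    caller_id: str = "caller"
    one_based: bool = True
    state_map: dict[str, str] = field(default_factory=dict)
    sample_rename: dict[str, str] = field(default_factory=dict)


_REQUIRED_COLS = ("sample", "chrom", "start", "end", "state")


def read_generic_calls(
    path,
    dialect: GenericDialect | None = None,
    snp_map: SnpMap | None = None,
) -> list[CnvCall]:
    """Read a header-bearing TSV of calls into normalized :class:`CnvCall`.

    If the table lacks an ``n_snps`` column a SNP map must be supplied so
    marker counts can be computed from the coordinates.
    """
    dialect = dialect or GenericDialect()
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "n_snps" not in df.columns and snp_map is None:
        raise ValueError(f"{path}: no n_snps column and no SNP map supplied")

    offset = 1 if dialect.one_based else 0
    calls: list[CnvCall] = []
    for row in df.itertuples(index=False):
        token = str(row.state).lower()
        state = dialect.state_map.get(token, token)
        if state not in (LOSS, GAIN):
            raise ValueError(f"{path}: unknown state token {row.state!r}")
        iv = Interval(str(row.chrom), int(row.start) - offset, int(row.end))
        if hasattr(row, "n_snps") and not pd.isna(row.n_snps):
            n_snps = int(row.n_snps)
        else:
            n_snps = count_snps_in(iv, snp_map)
        cn = None
        if hasattr(row, "cn") and not pd.isna(row.cn):
            cn = int(row.cn)
        sample = dialect.sample_rename.get(str(row.sample), str(row.sample))
        calls.append(
            CnvCall(
                sample_id=sample,
                caller_id=dialect.caller_id,
                interval=iv,
                state=state,
                n_snps=n_snps,
                copy_number=cn,
            )
        )
    log.info("read %d calls from %s (caller=%s)", len(calls), path, dialect.caller_id)
    return calls


def write_generic_calls(calls: Sequence[CnvCall], path, one_based: bool = True) -> None:
    """Write calls in the generic TSV dialect (round-trips with the reader)."""
    offset = 1 if one_based else 0
    rows = [
        {
            "sample": c.sample_id,
            "chrom": c.chrom,
            "start": c.interval.start + offset,
            "end": c.interval.end,
            "state": c.state,
            "n_snps": c.n_snps,
            "cn": "" if c.copy_number is None else c.copy_number,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "state", "n_snps", "cn"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Maps

def read_snp_map(path) -> SnpMap:
    """TSV with columns ``chrom`` and ``pos`` (1-based marker positions)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos"}.issubset(df.columns):
        raise ValueError(f"{path}: SNP map needs 'chrom' and 'pos' columns")
    return SnpMap(
        {chrom: (grp["pos"].to_numpy(dtype=np.int64) - 1) for chrom, grp in df.groupby("chrom", sort=False)}
    )


def write_snp_map(snp_map: SnpMap, path) -> None:
    rows = []
    for chrom in sorted(snp_map, key=chrom_sort_key):
        for pos in snp_map[chrom]:
            rows.append({"chrom": chrom, "pos": int(pos) + 1})
    pd.DataFrame(rows, columns=["chrom", "pos"]).to_csv(path, sep="\t", index=False)


def read_genome_map(path) -> GenomeMap:
    """TSV with columns ``chrom`` and ``length`` (bp)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "length"}.issubset(df.columns):
        raise ValueError(f"{path}: genome map needs 'chrom' and 'length' columns")
    if df["chrom"].duplicated().any():
        raise ValueError(f"{path}: duplicate chromosome labels")
    return GenomeMap(dict(zip(df["chrom"], df["length"].astype(int))))


def write_genome_map(genome: GenomeMap, path) -> None:
    pd.DataFrame(
        {"chrom": genome.chrom_names, "length": [genome[c] for c in genome.chrom_names]}
    ).to_csv(path, sep="\t", index=False)


def read_qtl_table(path) -> list[QtlRecord]:
    """TSV with columns ``qtl_id trait chrom start end ci_cm``.

    Coordinates are 1-based inclusive bp; cM confidence-interval widths are
    carried through verbatim (no cM-to-bp conversion is attempted).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "qtl_id": str})
    needed = {"qtl_id", "trait", "chrom", "start", "end", "ci_cm"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing QTL column(s) {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        if pd.isna(row.ci_cm):
            raise ValueError(f"{path}: missing ci_cm for QTL {row.qtl_id}")
        out.append(
            QtlRecord(
                qtl_id=str(row.qtl_id),
                trait=str(row.trait),
                interval=Interval(str(row.chrom), int(row.start) - 1, int(row.end)),
                ci_cm=float(row.ci_cm),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Per-caller CNV table (stage-1 output, stage-2 input)

def write_caller_cnv_table(caller_cnvs, path) -> None:
    """Write per-caller CNVs (stage-1 clusters) as TSV, 1-based coords."""
    rows = [
        {
            "caller": v.caller_id,
            "chrom": v.chrom,
            "start": v.interval.start + 1,
            "end": v.interval.end,
            "n_carriers": len(v.carriers),
            "carriers": ",".join(sorted(v.carriers)),
            "states": ",".join(v.states),
        }
        for v in caller_cnvs
    ]
    pd.DataFrame(
        rows,
        columns=["caller", "chrom", "start", "end", "n_carriers", "carriers", "states"],
    ).to_csv(path, sep="\t", index=False)


def read_caller_cnv_table(path) -> list:
    """Read a stage-1 per-caller CNV table back into CallerCnv objects."""
    from .consensus import CallerCnv  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "caller": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CallerCnv(
                caller_id=str(row.caller),
                interval=Interval(str(row.chrom), int(row.start) - 1, int(row.end)),
                carriers=frozenset(str(row.carriers).split(",")),
                states=tuple(str(row.states).split(",")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# CNVR result table

def write_cnvr_table(cnvrs, path, bed_path=None) -> None:
    """Write the CNVR result table (TSV, 1-based coords) plus a BED companion.

    Expects finalized :class:`cnvrkit.consensus.Cnvr` objects with
    frequencies already computed.
    """
    rows = []
    for r in cnvrs:
        rows.append(
            {
                "id": r.id,
                "chrom": r.interval.chrom,
                "start": r.interval.start + 1,
                "end": r.interval.end,
                "length_kb": round(r.interval.length_kb, 2),
                "n_callers": len(r.callers),
                "callers": ",".join(sorted(r.callers)),
                "status": r.status,
                "n_carriers": len(r.carriers),
                "frequency": "" if r.frequency is None else round(r.frequency, 6),
            }
        )
    cols = [
        "id", "chrom", "start", "end", "length_kb", "n_callers",
        "callers", "status", "n_carriers", "frequency",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    if bed_path is None:
        bed_path = re.sub(r"\.tsv$", "", str(path)) + ".bed"
    with open(bed_path, "w") as fh:
        for r in cnvrs:
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\tCNVR{r.id}\n")


def read_cnvr_table(path) -> pd.DataFrame:
    """Read back a written CNVR table; adds 0-based start0/end0 columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["start0"] = df["start"].astype(int) - 1
    df["end0"] = df["end"].astype(int)
    return df
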