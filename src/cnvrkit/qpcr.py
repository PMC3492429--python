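"""qPCR copy-number validation arithmetic (relative ddCT method).

A target region and a two-copy control region (the BTF3 gene in the
original assay design) are amplified in technical replicates.  With
replicate CT values averaged per region,

    dCT   = mean CT(target) - mean CT(control)
    ddCT  = dCT(sample) - dCT(calibrator)        # calibrator carries no CNV
    NR    = 2 * 2^(-ddCT)                        # relative copy number

so a two-copy sample yields NR ~ 2, a one-copy loss NR ~ 1 and a
three-copy gain NR ~ 3.  Standard curves from serial dilutions give each
primer pair's amplification efficiency (E = 10^(-1/slope) - 1); the
assay assumes approximately equal efficiencies between target and
control, and an optional efficiency-corrected mode is available when
they differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, stdev
from typing import Sequence

import numpy as np

__all__ = [
    "StandardCurve",
    "QpcrSample",
    "CopyNumberResult",
    "fit_standard_curve",
    "classify_copy_number",
    "delta_ct",
    "calibrator_delta_ct",
    "copy_number_ddct",
]


@dataclass
class StandardCurve:
    """OLS fit of CT against log10 relative template amount."""

    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    valid: bool

    @property
    def slope_per_log10(self) -> float:
        return self.slope


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit a dilution series: points are (log10 amount, mean CT).

    Amplification efficiency is ``10^(-1/slope) - 1``; a perfectly
    efficient reaction doubles per cycle (slope -3.3219, E = 1.0).  A
    non-negative slope marks the curve invalid (no amplification trend).
    """
    if len(points) < 3:
        raise ValueError(f"standard curve needs >= 3 dilution points, got {len(points)}")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    valid = slope < 0
    efficiency = 10.0 ** (-1.0 / slope) - 1.0 if valid else float("nan")
    return StandardCurve(
        slope=float(slope),
        intercept=float(intercept),
        efficiency=efficiency,
        r_squared=r2,
        valid=valid,
    )


@dataclass(frozen=True)
class QpcrSample:
    """Replicate CT measurements for one animal at one assayed region."""

    sample_id: str
    target_cts: tuple[float, ...]
    control_cts: tuple[float, ...]
    is_calibrator: bool = False

    def __post_init__(self) -> None:
        if not self.target_cts or not self.control_cts:
            raise ValueError(f"{self.sample_id}: empty CT replicate list")
        if any(ct <= 0 for ct in self.target_cts + self.control_cts):
            raise ValueError(f"{self.sample_id}: CT values must be positive")


@dataclass
class CopyNumberResult:
    sample_id: str
    delta_ct: float
    delta_delta_ct: float
    nr_value: float
    status: str  # loss | normal | gain
    target_sd: float
    control_sd: float


def classify_copy_number(
    nr_value: float, loss_max: float = 1.5, gain_min: float = 2.5
) -> str:
    """Band the relative copy number: loss below ``loss_max`` (NR around 0
    or 1), gain at or above ``gain_min`` (NR around 3 or above), normal in
    between (NR around 2)."""
    if nr_value <= 0:
        raise ValueError("nr_value must be positive")
    if nr_value < loss_max:
        return "loss"
    if nr_value >= gain_min:
        return "gain"
    return "normal"


def delta_ct(sample: QpcrSample) -> float:
    """Replicate-averaged CT(target) - CT(control) for one sample."""
    return mean(sample.target_cts) - mean(sample.control_cts)


def calibrator_delta_ct(samples: Sequence[QpcrSample]) -> float:
    """Mean dCT over the flagged no-CNV calibrator samples.

    Accepts one calibrator animal or a panel of non-carriers; with several
    flagged samples the calibrator dCT is their mean.
    """
    cal = [delta_ct(s) for s in samples if s.is_calibrator]
    if not cal:
        raise ValueError("no calibrator sample flagged")
    return mean(cal)


def copy_number_ddct(
    sample: QpcrSample,
    calibrator_dct: float,
    loss_max: float = 1.5,
    gain_min: float = 2.5,
    target_efficiency: float | None = None,
    control_efficiency: float | None = None,
) -> CopyNumberResult:
    """Relative copy number NR = 2 * 2^(-ddCT) for one sample.

    By default amplification is assumed to double per cycle (base 2), the
    standard assay assumption once target and control efficiencies have
    been checked to be approximately equal on their standard curves.  If
    both efficiencies are supplied, the base becomes 1 + mean(E), a
    first-order correction for jointly sub-ideal efficiency.
    """
    dct = delta_ct(sample)
    ddct = dct - calibrator_dct
    if target_efficiency is not None and control_efficiency is not None:
        base = 1.0 + (target_efficiency + control_efficiency) / 2.0
    else:
        base = 2.0
    nr = 2.0 * base ** (-ddct)
    return CopyNumberResult(
        sample_id=sample.sample_id,
        delta_ct=dct,
        delta_delta_ct=ddct,
        nr_value=nr,
        status=classify_copy_number(nr, loss_max, gain_min),
        target_sd=stdev(sample.target_cts) if len(sample.target_cts) > 1 else 0.0,
        control_sd=stdev(sample.control_cts) if len(sample.control_cts) > 1 else 0.0,
    )
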