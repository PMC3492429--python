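"""Shared fixtures: tiny maps, call sets and a simulated study."""

from __future__ import annotations

import numpy as np
import pytest

from cnvrkit.intervals import GenomeMap, Interval
from cnvrkit.io_formats import CnvCall, SnpMap
from cnvrkit import synthetic


def make_call(
    sample="S1",
    caller="penncnv",
    chrom="chr1",
    start=0,
    end=10_000,
    state="loss",
    n_snps=3,
    cn=None,
):
    return CnvCall(
        sample_id=sample,
        caller_id=caller,
        interval=Interval(chrom, start, end),
        state=state,
        n_snps=n_snps,
        copy_number=cn,
    )


@pytest.fixture
def genome_map():
    return GenomeMap({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def snp_map():
    # 0-based positions every 100 bp
    return SnpMap(
        {
            "chr1": np.arange(100, 1_000_000, 100),
            "chr2": np.arange(50, 500_000, 100),
        }
    )


@pytest.fixture(scope="session")
def default_truth():
    """One default-scenario simulated study, shared across tests."""
    return synthetic.simulate_study(synthetic.SimConfig(seed=7))
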