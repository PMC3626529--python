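"""Shared fixtures: small truth-known genomes and read sets.

Everything is generated programmatically with fixed seeds; no data files.
"""

import numpy as np
import pytest

from dbgasm.graph import Unitig
from dbgasm.io_config import Library
from dbgasm.sim import simulate_genome, simulate_pe_library


@pytest.fixture(scope="session")
def small_genome():
    return simulate_genome(10_000, seed=7)


@pytest.fixture(scope="session")
def pe_library():
    return Library(name="pe500", avg_ins=500, ins_sd=20, rank=1)


@pytest.fixture(scope="session")
def small_reads(small_genome, pe_library):
    r1, r2, truths = simulate_pe_library(small_genome, pe_library,
                                         read_len=100, coverage=30, seed=11)
    return r1, r2, truths


def make_truth_layout(seed, n_contigs=10, genome_len=40_000,
                      contig_len=(2200, 4000), gap_len=(80, 200)):
    """A genome cut into truth-known contigs separated by known gaps."""
    gt = simulate_genome(genome_len, seed=seed)
    g = gt.haplotypes[0]
    rng = np.random.default_rng(seed + 1000)
    lens = rng.integers(*contig_len, size=n_contigs)
    gaps = rng.integers(*gap_len, size=n_contigs - 1)
    contigs, true_gaps, pos = [], [], 0
    for i in range(n_contigs):
        contigs.append(Unitig(id=i, seq=g[pos : pos + int(lens[i])],
                              mean_coverage=0.0))
        pos += int(lens[i])
        if i < n_contigs - 1:
            true_gaps.append(int(gaps[i]))
            pos += int(gaps[i])
    assert pos <= genome_len
    return gt, contigs, true_gaps
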