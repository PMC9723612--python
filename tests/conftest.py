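"""Shared fixtures: synthetic datasets, BAM synthesis, HMM brute-force oracle."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pysam
import pytest
from scipy.stats import binom

from xocall import SimulationConfig, simulate_dataset
from xocall.core import AlleleCountMatrix, SNPTable
from xocall.crossover_hmm import HMMParams

_BASES = np.array(list("ACGT"))


def make_snptable(n: int, seed: int = 0, chrom: str = "chr1", span: int | None = None) -> SNPTable:
    rng = np.random.default_rng(seed)
    span = span or max(10 * n, 1000)
    pos = np.sort(rng.choice(span, n, replace=False)) + 1
    ri = rng.integers(0, 4, n)
    ai = (ri + rng.integers(1, 4, n)) % 4
    return SNPTable(chrom, pos, _BASES[ri], _BASES[ai])


@pytest.fixture(scope="session")
def small_dataset():
    """30 gametes x 300 SNPs at high coverage with one crossover each."""
    cfg = SimulationConfig(
        n_cells=30,
        n_snps=300,
        region_bp=100_000,
        crossovers_per_cell=1,
        min_breakpoint_sep=30,
        coverage_mean=1.0,
        miscall_rate=0.005,
        seed=7,
    )
    truth, counts = simulate_dataset(cfg)
    return cfg, truth, counts


def bam_from_counts(path, counts: AlleleCountMatrix, mapq: int = 60, baseq: int = 40):
    """Synthesise a sorted, indexed BAM whose pileup reproduces ``counts``.

    One single-base read per counted read, carrying the cell barcode in CB.
    """
    snps = counts.snps
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": snps.chrom, "LN": int(snps.positions[-1]) + 100}],
    }
    ref = counts.ref_counts.tocsc()
    alt = counts.alt_counts.tocsc()
    k = 0
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for j in range(len(snps)):
            for mat, base in ((ref, snps.ref_alleles[j]), (alt, snps.alt_alleles[j])):
                col = mat[:, j].tocoo()
                for c, n in zip(col.row, col.data):
                    for _ in range(int(n)):
                        a = pysam.AlignedSegment(pysam.AlignmentHeader.from_dict(header))
                        a.query_name = f"r{k}"
                        k += 1
                        a.query_sequence = str(base)
                        a.flag = 0
                        a.reference_id = 0
                        a.reference_start = int(snps.positions[j]) - 1
                        a.mapping_quality = mapq
                        a.cigartuples = [(0, 1)]
                        a.query_qualities = pysam.qualitystring_to_array(chr(baseq + 33))
                        a.set_tag("CB", counts.barcodes[int(c)])
                        bam.write(a)
    pysam.index(str(path))
    return str(path)


# ---------------------------------------------------------------------------
# independent HMM oracle: exhaustive path enumeration with its own likelihood


def path_tables(counts_cell, positions, params: HMMParams):
    counts_cell = np.asarray(counts_cell, dtype=np.int64)
    tot = counts_cell.sum(axis=1)
    e = np.stack(
        [
            binom.logpmf(counts_cell[:, 0], tot, params.theta2),
            binom.logpmf(counts_cell[:, 0], tot, params.theta1),
        ]
    )
    gaps = np.diff(np.asarray(positions, dtype=np.int64))
    if params.p_const is not None:
        p = np.full(len(gaps), params.p_const)
    else:
        p = np.clip(gaps * params.cmPmb * 1e-8, params.p_min, params.p_max)
    return e, np.log(p), np.log1p(-p)


def path_loglik(states01, e, lp, l1p, params: HMMParams) -> float:
    ll = math.log(params.pi[states01[0]]) + e[states01[0], 0]
    for t in range(1, len(states01)):
        ll += lp[t - 1] if states01[t] != states01[t - 1] else l1p[t - 1]
        ll += e[states01[t], t]
    return ll


def brute_force_best(counts_cell, positions, params: HMMParams) -> float:
    """Max log-likelihood over all 2^n state paths (n small)."""
    e, lp, l1p = path_tables(counts_cell, positions, params)
    n = e.shape[1]
    return max(
        path_loglik(s, e, lp, l1p, params) for s in itertools.product((0, 1), repeat=n)
    )
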