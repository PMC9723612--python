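"""Two-state HMM crossover calling over phased hetSNPs.

Each gamete's chromosome is modelled as a hidden sequence over states H1/H2
(which parental haplotype the local DNA segment derives from), observed
through per-SNP allele read counts.  Emissions are full binomial
probabilities of the haplotype-1-supporting read count: under state H1 a
read supports haplotype 1 with probability ``theta2`` (default 0.9), under
H2 with ``theta1`` (default 0.1) — technical noise such as mapping artefacts
makes both strictly inside (0, 1).  The per-gap transition probability
scales with physical distance, ``p = gap_bp * cmPmb * 1e-8`` (a
centiMorgan-per-megabase recombination rate turned into a per-gap
recombination fraction), clamped to ``[p_min, p_max]``; a constant per-gap
probability is available via ``p_const``.

Viterbi decoding gives the most probable state path; maximal same-state runs
become segments, and each segment's confidence is the log-likelihood ratio of
the full decoded path against the same path with that segment's states
reversed (only the segment's emissions and its boundary transitions differ,
everything else cancels).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import binom

from .core import MISSING, REF, AlleleCountMatrix, Haplotype

logger = logging.getLogger(__name__)

H1: int = 1
H2: int = 2


@dataclass(frozen=True)
class HMMParams:
    theta1: float = 0.1  # P(hap1-supporting read | state H2)
    theta2: float = 0.9  # P(hap1-supporting read | state H1)
    cmPmb: float = 0.1  # assumed recombination rate, centiMorgan per megabase
    p_min: float = 1e-10
    p_max: float = 0.25
    pi: tuple[float, float] = (0.5, 0.5)
    p_const: float | None = None  # constant per-gap transition prob (overrides cmPmb)

    def __post_init__(self) -> None:
        if not 0.0 < self.theta1 < 0.5 < self.theta2 < 1.0:
            raise ValueError("require 0 < theta1 < 0.5 < theta2 < 1")
        if not 0.0 < self.p_min <= self.p_max <= 0.5:
            raise ValueError("require 0 < p_min <= p_max <= 0.5")
        if abs(self.pi[0] + self.pi[1] - 1.0) > 1e-12 or min(self.pi) <= 0:
            raise ValueError("pi must be positive and sum to 1")
        if self.p_const is not None and not self.p_min <= self.p_const <= self.p_max:
            raise ValueError("p_const must lie in [p_min, p_max]")


@dataclass(frozen=True)
class Segment:
    cell: str
    chrom: str
    state: int  # H1 or H2
    first_snp_pos: int
    last_snp_pos: int
    n_snps: int
    n_reads: int
    log_lik_ratio: float


@dataclass(frozen=True)
class CellResult:
    snp_indices: np.ndarray  # covered SNP indices into the phased SNP table
    states: np.ndarray  # {1, 2}, same length
    segments: tuple[Segment, ...]

    @property
    def n_crossovers(self) -> int:
        return max(len(self.segments) - 1, 0)


@dataclass
class ViterbiResult:
    chrom: str
    cells: dict[str, CellResult] = field(default_factory=dict)

    def to_segments_frame(self) -> pd.DataFrame:
        rows = [
            {
                "barcode": seg.cell,
                "chrom": seg.chrom,
                "first_snp_pos": seg.first_snp_pos,
                "last_snp_pos": seg.last_snp_pos,
                "state": f"H{seg.state}",
                "n_snps": seg.n_snps,
                "n_reads": seg.n_reads,
                "log_lik_ratio": seg.log_lik_ratio,
            }
            for res in self.cells.values()
            for seg in res.segments
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "barcode",
                "chrom",
                "first_snp_pos",
                "last_snp_pos",
                "state",
                "n_snps",
                "n_reads",
                "log_lik_ratio",
            ],
        )


def emission_logprob(h1_reads: int, h2_reads: int, state: int, params: HMMParams) -> float:
    """Binomial log-pmf of the hap1-supporting read count under a state."""
    if h1_reads < 0 or h2_reads < 0:
        raise ValueError("read counts must be non-negative")
    n = h1_reads + h2_reads
    p = params.theta2 if state == H1 else params.theta1
    return float(binom.logpmf(h1_reads, n, p))


def transition_prob(gap_bp: int, params: HMMParams) -> float:
    """Per-gap probability of switching haplotype state."""
    if params.p_const is not None:
        return params.p_const
    p = gap_bp * params.cmPmb * 1e-8
    return float(min(max(p, params.p_min), params.p_max))


def _emissions(h1: np.ndarray, total: np.ndarray, params: HMMParams) -> np.ndarray:
    """(2, n) log emission matrix: row 0 = H1, row 1 = H2."""
    return np.stack(
        [binom.logpmf(h1, total, params.theta2), binom.logpmf(h1, total, params.theta1)]
    )


def _gap_logprobs(positions: np.ndarray, params: HMMParams) -> tuple[np.ndarray, np.ndarray]:
    gaps = np.diff(positions.astype(np.int64))
    if params.p_const is not None:
        p = np.full(len(gaps), params.p_const, dtype=float)
    else:
        p = np.clip(gaps * params.cmPmb * 1e-8, params.p_min, params.p_max)
    return np.log(p), np.log1p(-p)


def viterbi_cell(
    counts_cell: np.ndarray, positions: np.ndarray, params: HMMParams
) -> np.ndarray:
    """Most probable state path for one gamete; ties stay in the previous state.

    ``counts_cell`` is an (n, 2) array of (h1_reads, h2_reads) over the
    gamete's covered SNPs; ``positions`` their strictly increasing bp
    coordinates.  Returns states coded H1=1 / H2=2 (empty input -> empty).
    """
    counts_cell = np.asarray(counts_cell, dtype=np.int64).reshape(-1, 2)
    positions = np.asarray(positions, dtype=np.int64)
    n = len(positions)
    if counts_cell.shape[0] != n:
        raise ValueError("counts and positions lengths differ")
    if n == 0:
        return np.empty(0, dtype=np.int8)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    total = counts_cell.sum(axis=1)
    if np.any(total < 1):
        raise ValueError("zero-coverage SNPs must be excluded from the sequence")
    e = _emissions(counts_cell[:, 0], total, params)
    lp, l1p = _gap_logprobs(positions, params)
    v0 = math.log(params.pi[0]) + e[0, 0]
    v1 = math.log(params.pi[1]) + e[1, 0]
    back = np.empty((n, 2), dtype=np.int8)
    for t in range(1, n):
        stay0, move0 = v0 + l1p[t - 1], v1 + lp[t - 1]
        stay1, move1 = v1 + l1p[t - 1], v0 + lp[t - 1]
        if stay0 >= move0:
            nv0, back[t, 0] = stay0, 0
        else:
            nv0, back[t, 0] = move0, 1
        if stay1 >= move1:
            nv1, back[t, 1] = stay1, 1
        else:
            nv1, back[t, 1] = move1, 0
        v0, v1 = nv0 + e[0, t], nv1 + e[1, t]
    states = np.empty(n, dtype=np.int8)
    states[-1] = 0 if v0 >= v1 else 1
    for t in range(n - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states + 1


def segment_and_score(
    states: np.ndarray,
    counts_cell: np.ndarray,
    positions: np.ndarray,
    params: HMMParams,
    cell: str = "",
    chrom: str = "",
) -> list[Segment]:
    """Cut the state path into segments and attach log-likelihood ratios.

    A segment's LLR is the full-path log-likelihood of the decoded path minus
    that of the path with every SNP in the segment flipped to the other
    state: the segment's emission terms plus the transition terms at its
    boundaries (and the initial-state term for a leading segment); all other
    terms cancel.
    """
    states = np.asarray(states, dtype=np.int64)
    counts_cell = np.asarray(counts_cell, dtype=np.int64).reshape(-1, 2)
    positions = np.asarray(positions, dtype=np.int64)
    n = len(states)
    if n == 0:
        return []
    total = counts_cell.sum(axis=1)
    e = _emissions(counts_cell[:, 0], total, params)
    lp, l1p = _gap_logprobs(positions, params)
    s0 = states - 1  # 0/1 coding
    run_starts = np.concatenate(([0], np.flatnonzero(np.diff(s0) != 0) + 1))
    run_ends = np.concatenate((run_starts[1:], [n]))
    segments = []
    for i, j in zip(run_starts, run_ends):
        s = int(s0[i])
        llr = float(np.sum(e[s, i:j] - e[1 - s, i:j]))
        if i > 0:
            llr += float(lp[i - 1] - l1p[i - 1])
        else:
            llr += math.log(params.pi[s]) - math.log(params.pi[1 - s])
        if j < n:
            llr += float(lp[j - 1] - l1p[j - 1])
        segments.append(
            Segment(
                cell=cell,
                chrom=chrom,
                state=s + 1,
                first_snp_pos=int(positions[i]),
                last_snp_pos=int(positions[j - 1]),
                n_snps=int(j - i),
                n_reads=int(total[i:j].sum()),
                log_lik_ratio=llr,
            )
        )
    return segments


def hap_read_counts(
    counts: AlleleCountMatrix, hap: Haplotype
) -> tuple[sparse.csr_matrix, sparse.csr_matrix, np.ndarray]:
    """Re-express ref/alt counts as (hap1-, hap2-supporting) read counts.

    SNPs with a missing haplotype assignment are dropped; returns the kept
    SNP indices alongside the two cells x kept-SNPs matrices.
    """
    kept = np.flatnonzero(hap.hap1 != MISSING)
    ref = counts.ref_counts[:, kept]
    alt = counts.alt_counts[:, kept]
    hap_ref = (hap.hap1[kept] == REF).astype(np.int64)
    h1 = ref.multiply(hap_ref) + alt.multiply(1 - hap_ref)
    h2 = ref.multiply(1 - hap_ref) + alt.multiply(hap_ref)
    return sparse.csr_matrix(h1), sparse.csr_matrix(h2), kept


def call_crossovers_dataset(
    counts: AlleleCountMatrix,
    hap: Haplotype,
    params: HMMParams | None = None,
    out_prefix: str | None = None,
) -> ViterbiResult:
    """Viterbi-decode and score every gamete; optionally write outputs.

    Writes ``<prefix>_vi.mtx`` (sparse state matrix: 1=H1, 2=H2, absent =
    uncovered) and ``<prefix>_segments.txt`` when ``out_prefix`` is given.
    """
    if params is None:
        params = HMMParams()
    if hap.n_phased < 1:
        raise ValueError("haplotype must be phased for at least one SNP")
    h1, h2, kept = hap_read_counts(counts, hap)
    positions = counts.snps.positions[kept]
    chrom = counts.snps.chrom
    result = ViterbiResult(chrom=chrom)
    rows, cols, vals = [], [], []
    h1 = h1.tocsr()
    tot = (h1 + h2).tocsr()
    for c, barcode in enumerate(counts.barcodes):
        row_tot = tot.getrow(c).toarray().ravel()
        covered = np.flatnonzero(row_tot > 0)
        if len(covered) == 0:
            logger.info("cell %s has no covered phased SNPs", barcode)
            result.cells[barcode] = CellResult(
                np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int8), ()
            )
            continue
        row_h1 = h1.getrow(c).toarray().ravel()[covered]
        cc = np.column_stack([row_h1, row_tot[covered] - row_h1])
        pos = positions[covered]
        states = viterbi_cell(cc, pos, params)
        segs = segment_and_score(states, cc, pos, params, cell=barcode, chrom=chrom)
        result.cells[barcode] = CellResult(kept[covered], states, tuple(segs))
        rows.extend([c] * len(covered))
        cols.extend(kept[covered].tolist())
        vals.extend(states.tolist())
    if out_prefix is not None:
        from .gamete_io import write_int_mtx, write_segments

        vi = sparse.coo_matrix(
            (vals, (rows, cols)), shape=(len(counts.barcodes), len(counts.snps)), dtype=np.int64
        )
        write_int_mtx(f"{out_prefix}_vi.mtx", vi)
        write_segments(f"{out_prefix}_segments.txt", result.to_segments_frame())
    return result
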