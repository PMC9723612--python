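"""Switch-error detection and repair on an inferred haplotype.

A switch error complements the haplotype's allele assignments from one SNP
onward, typically because the template gamete carried a crossover there.
Each candidate SNP gets a switch score: a per-gamete two-orientation
likelihood contrast between "the haplotype flips orientation here" and "it
does not", summed over gametes, assuming a per-SNP genotype error rate
``epsilon``.  Positive scores favour a switch.  Peaks above a detection
threshold are accepted greedily and the haplotype is complemented from each
accepted position onward.

The score formulation is a block-splitting likelihood test adapted to
haploid gametes; it is isolated in :func:`switch_score` /
:func:`score_candidates` so the statistic can be swapped without touching
callers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import GenotypeMatrix, Haplotype, complement_code

#: default detection threshold: decisive evidence, ln(10^4)
DEFAULT_MIN_SCORE: float = math.log(1e4)


@dataclass(frozen=True)
class SwitchScoreTrack:
    candidate_indices: np.ndarray  # SNP indices, strictly increasing
    scores: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "candidate_indices", np.asarray(self.candidate_indices, dtype=np.int64))
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        if len(self.candidate_indices) != len(self.scores):
            raise ValueError("candidate/score lengths differ")
        if len(self.candidate_indices) > 1 and np.any(np.diff(self.candidate_indices) <= 0):
            raise ValueError("candidate indices must be strictly increasing")
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")


@dataclass(frozen=True)
class SwitchCall:
    positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    scores_at_switch: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=np.int64))
        object.__setattr__(self, "scores_at_switch", np.asarray(self.scores_at_switch, dtype=float))

    def __len__(self) -> int:
        return len(self.positions)


def candidate_sites(
    G: GenotypeMatrix, hap: Haplotype, link_ratio_threshold: float = 0.7
) -> np.ndarray:
    """SNP indices at elevated risk of carrying a switch error.

    For each adjacent pair of phased SNPs, the linkage support is the
    fraction of gametes covering both whose genotype pair is consistent with
    the haplotype (both match it, or both match its complement).  The right
    member of a pair is a candidate when support falls below the threshold or
    fewer than 2 gametes cover the pair.
    """
    if len(hap) == 0:
        raise ValueError("haplotype is empty")
    phased = np.flatnonzero(hap.hap1 != 0)
    if len(phased) < 2:
        return np.empty(0, dtype=np.int64)
    m = G.signed().astype(np.int32)[:, phased] * hap.signed().astype(np.int32)[phased][None, :]
    pair = m[:, :-1] * m[:, 1:]  # +1 consistent, -1 inconsistent, 0 uncovered
    n_cov = (pair != 0).sum(axis=0)
    n_ok = (pair == 1).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        support = np.where(n_cov > 0, n_ok / np.maximum(n_cov, 1), 0.0)
    is_cand = (n_cov < 2) | (support < link_ratio_threshold)
    return phased[1:][is_cand]


def score_candidates(
    G: GenotypeMatrix,
    hap: Haplotype,
    candidates: np.ndarray,
    window: int = 10,
    epsilon: float = 0.1,
) -> SwitchScoreTrack:
    """Switch scores at the given (phased, increasing) candidate SNP indices.

    Per gamete, the left flank is its nearest <= ``window`` informative SNPs
    before the candidate and the right flank the candidate plus the following
    <= ``window`` - 1; gametes with fewer than 2 informative SNPs in either
    flank contribute 0.  With ``a``/``b`` the (matches - mismatches) sums of
    the two flanks, the per-gamete contribution reduces to
    ``(|a - b| - |a + b|) / 2 * (ln(1 - eps) - ln(eps))``.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    candidates = np.asarray(candidates, dtype=np.int64)
    scores = np.zeros(len(candidates))
    if len(candidates) == 0:
        return SwitchScoreTrack(candidates, scores, epsilon)
    if np.any(hap.hap1[candidates] == 0):
        raise ValueError("candidates must be phased SNP indices")
    c0 = math.log(1.0 - epsilon) - math.log(epsilon)
    sg = G.signed().astype(np.int64)
    hs = hap.signed().astype(np.int64)
    for c in range(G.n_cells):
        m = sg[c] * hs
        inf = np.flatnonzero(m)
        if len(inf) < 4:
            continue
        cum = np.concatenate(([0], np.cumsum(m[inf])))
        pos = np.searchsorted(inf, candidates)  # left flank < k, right flank >= k
        n_left = np.minimum(window, pos)
        n_right = np.minimum(window, len(inf) - pos)
        ok = (n_left >= 2) & (n_right >= 2)
        a = cum[pos] - cum[pos - n_left]
        b = cum[pos + n_right] - cum[pos]
        contrib = (np.abs(a - b) - np.abs(a + b)) * (c0 / 2.0)
        scores += np.where(ok, contrib, 0.0)
    return SwitchScoreTrack(candidates, scores, epsilon)


def switch_score(
    G: GenotypeMatrix, hap: Haplotype, k: int, window: int = 10, epsilon: float = 0.1
) -> float:
    """Switch score at one SNP index (see :func:`score_candidates`)."""
    track = score_candidates(G, hap, np.asarray([k]), window=window, epsilon=epsilon)
    return float(track.scores[0])


def find_switches(
    track: SwitchScoreTrack, min_score: float = DEFAULT_MIN_SCORE, min_gap: int = 20
) -> SwitchCall:
    """Accept score peaks greedily, suppressing neighbours within min_gap SNPs."""
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    idx = track.candidate_indices
    sc = track.scores
    n = len(idx)
    if n == 0:
        return SwitchCall()
    # local maximum among track neighbours closer than min_gap SNP indices;
    # candidates further apart are unrelated sites, not the same peak
    is_peak = np.ones(n, dtype=bool)
    if n > 1:
        near = np.diff(idx) < min_gap
        is_peak[1:] &= ~near | (sc[1:] >= sc[:-1])
        is_peak[:-1] &= ~near | (sc[:-1] >= sc[1:])
    eligible = np.flatnonzero(is_peak & (sc >= min_score))
    order = sorted(eligible, key=lambda i: (-sc[i], idx[i]))
    accepted: list[int] = []
    for i in order:
        if all(abs(int(idx[i]) - int(idx[j])) >= min_gap for j in accepted):
            accepted.append(i)
    accepted.sort(key=lambda i: idx[i])
    return SwitchCall(idx[accepted], sc[accepted])


def apply_switches(hap: Haplotype, call: SwitchCall) -> Haplotype:
    """Complement the haplotype from each switch position onward (parity)."""
    n = len(hap)
    if len(call) and (call.positions.min() < 0 or call.positions.max() >= n):
        raise ValueError("switch position out of range")
    flip = np.zeros(n + 1, dtype=np.int64)
    for p in call.positions:
        flip[p] += 1
    odd = (np.cumsum(flip[:-1]) % 2).astype(bool)
    hap1 = hap.hap1.copy()
    hap1[odd] = complement_code(hap1[odd])
    return Haplotype(hap.snps, hap1)


def correct_switches(
    G: GenotypeMatrix,
    hap: Haplotype,
    link_ratio_threshold: float = 0.7,
    window: int = 10,
    epsilon: float = 0.1,
    min_score: float = DEFAULT_MIN_SCORE,
    min_gap: int = 20,
    max_switches: int = 50,
) -> tuple[Haplotype, SwitchCall, SwitchScoreTrack]:
    """Full swphase run: iterative peak correction.

    Each iteration recomputes candidates and scores against the current
    haplotype, applies the single strongest accepted peak, and repeats until
    no peak reaches ``min_score`` (or ``max_switches`` corrections were
    made).  Re-scoring after every correction keeps secondary peaks produced
    by the same underlying switch (e.g. at the edges of a sparsely phased
    stretch) from being accepted as additional, spurious switches.  The
    returned track is the one computed on the input haplotype.
    """
    cands = candidate_sites(G, hap, link_ratio_threshold=link_ratio_threshold)
    first_track = score_candidates(G, hap, cands, window=window, epsilon=epsilon)
    track = first_track
    corrected = hap
    accepted_pos: list[int] = []
    accepted_scores: list[float] = []
    for _ in range(max_switches):
        call = find_switches(track, min_score=min_score, min_gap=min_gap)
        if len(call) == 0:
            break
        best = int(np.argmax(call.scores_at_switch))
        p = int(call.positions[best])
        if p in accepted_pos:  # refuse to toggle the same site twice
            break
        accepted_pos.append(p)
        accepted_scores.append(float(call.scores_at_switch[best]))
        corrected = apply_switches(corrected, SwitchCall([p], [call.scores_at_switch[best]]))
        cands = candidate_sites(G, corrected, link_ratio_threshold=link_ratio_threshold)
        track = score_candidates(G, corrected, cands, window=window, epsilon=epsilon)
    order = np.argsort(accepted_pos)
    final_call = SwitchCall(
        np.asarray(accepted_pos, dtype=np.int64)[order],
        np.asarray(accepted_scores)[order],
    )
    return corrected, final_call, first_track
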