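"""Crossover-landscape construction and comparison.

Downstream of Viterbi segmentation: filter implausible cells and segments,
turn state changes into crossover intervals, count crossovers over genomic
bins (mass split proportionally because a crossover's position is only known
to an interval), convert per-bin rates to genetic distances with the Kosambi
or Haldane mapping function, and compare groups of gametes with bootstrap
confidence intervals or permutation p-values.  Phasing diagnostics
(per-bin accuracy against a truth haplotype; contradictory-allele read
frequencies) live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, AlleleCountMatrix, BarcodeList, Haplotype, complement_code


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for removing implausible cells and crossover calls."""

    min_cell_snps: int = 200  # covered SNPs per cell per chromosome
    max_raw_co: int = 10  # unfiltered crossovers per cell per chromosome
    min_seg_snps: int = 3  # SNPs per segment flanking a crossover
    min_seg_llr: float = 10.0  # log-likelihood ratio per flanking segment
    min_seg_bp: float = 1e5  # bp span per flanking segment

    def __post_init__(self) -> None:
        if min(self.min_cell_snps, self.max_raw_co, self.min_seg_snps) < 0:
            raise ValueError("filter thresholds must be >= 0")
        if self.min_seg_llr < 0 or self.min_seg_bp < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class CrossoverMatrix:
    """Intervals x cells crossover mass, plus optional per-cell group labels."""

    intervals: pd.DataFrame  # columns chrom, start, end
    cells: BarcodeList
    counts: np.ndarray  # (n_intervals, n_cells), non-negative reals
    group_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.intervals), len(self.cells)):
            raise ValueError("counts shape must be (n_intervals, n_cells)")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("crossover mass must be non-negative")
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels)
            if len(self.group_labels) != len(self.cells):
                raise ValueError("one group label per cell required")


@dataclass(frozen=True)
class GroupComparison:
    observed_diff: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")
    n_resamples: int = 0
    seed: int = 0


def _segment_fails(seg: dict, f: FilterParams) -> bool:
    span = seg["last_snp_pos"] - seg["first_snp_pos"]
    return (
        seg["n_snps"] < f.min_seg_snps
        or seg["log_lik_ratio"] < f.min_seg_llr
        or span < f.min_seg_bp
    )


def _merge_same_state(segs: list[dict]) -> list[dict]:
    out: list[dict] = []
    for s in segs:
        if out and out[-1]["state"] == s["state"]:
            prev = out[-1]
            prev["last_snp_pos"] = max(prev["last_snp_pos"], s["last_snp_pos"])
            prev["first_snp_pos"] = min(prev["first_snp_pos"], s["first_snp_pos"])
            prev["n_snps"] += s["n_snps"]
            prev["n_reads"] += s["n_reads"]
            prev["log_lik_ratio"] += s["log_lik_ratio"]
        else:
            out.append(s)
    return out


def crossovers_from_segments(
    segments: pd.DataFrame, filters: FilterParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter segments and emit crossovers plus a per-cell QC table.

    Whole cells failing ``min_cell_snps`` or exceeding ``max_raw_co`` on a
    chromosome are dropped.  Segments failing any per-segment threshold are
    removed in one pass (so tightening a threshold can only shrink the kept
    set); each removed segment's SNPs and reads are absorbed into its left
    surviving neighbour (the right one at the chromosome start) and adjacent
    same-state survivors are re-merged with spans, SNPs, reads and LLRs
    combined.  Every remaining state change is a crossover whose confidence
    is the smaller flanking-segment LLR.
    """
    if filters is None:
        filters = FilterParams()
    co_rows, qc_rows = [], []
    for (barcode, chrom), grp in segments.groupby(["barcode", "chrom"], sort=False):
        firsts = grp["first_snp_pos"].to_numpy()
        if np.any(np.diff(firsts) < 0):
            raise ValueError(f"segments of cell {barcode!r} are not ordered by position")
        segs = grp.to_dict("records")
        total_snps = int(sum(s["n_snps"] for s in segs))
        raw_co = len(segs) - 1
        reason = ""
        if total_snps < filters.min_cell_snps:
            reason = "low_snp_coverage"
        elif raw_co > filters.max_raw_co:
            reason = "excess_crossovers"
        retained = 0
        if not reason:
            keep = [s for s in segs if not _segment_fails(s, filters)]
            if not keep:  # nothing survives: no crossover is callable
                keep = []
            else:
                for s in segs:
                    if _segment_fails(s, filters):
                        # absorb into the nearest surviving neighbour
                        left_surv = [k for k in keep if k["first_snp_pos"] <= s["first_snp_pos"]]
                        target = left_surv[-1] if left_surv else keep[0]
                        target["n_snps"] += s["n_snps"]
                        target["n_reads"] += s["n_reads"]
                        target["first_snp_pos"] = min(target["first_snp_pos"], s["first_snp_pos"])
                        target["last_snp_pos"] = max(target["last_snp_pos"], s["last_snp_pos"])
            segs = _merge_same_state(keep)
            for left, right in zip(segs[:-1], segs[1:]):
                co_rows.append(
                    {
                        "barcode": barcode,
                        "chrom": chrom,
                        "left_pos": int(left["last_snp_pos"]),
                        "right_pos": int(right["first_snp_pos"]),
                        "confidence": float(
                            min(left["log_lik_ratio"], right["log_lik_ratio"])
                        ),
                    }
                )
            retained = len(segs) - 1
        qc_rows.append(
            {
                "barcode": barcode,
                "chrom": chrom,
                "n_snps": total_snps,
                "raw_co": raw_co,
                "retained_co": retained,
                "kept": not reason,
                "reason": reason,
            }
        )
    crossovers = pd.DataFrame(
        co_rows, columns=["barcode", "chrom", "left_pos", "right_pos", "confidence"]
    )
    qc = pd.DataFrame(
        qc_rows,
        columns=["barcode", "chrom", "n_snps", "raw_co", "retained_co", "kept", "reason"],
    )
    return crossovers, qc


def make_bins(chrom: str, start: int, end: int, bin_bp: int) -> pd.DataFrame:
    """Half-open tiling bins [start, end) of width ``bin_bp``."""
    edges = np.arange(start, end, bin_bp, dtype=np.int64)
    return pd.DataFrame(
        {"chrom": chrom, "start": edges, "end": np.minimum(edges + bin_bp, end)}
    )


def count_cos(
    crossovers: pd.DataFrame,
    intervals: pd.DataFrame,
    cells: BarcodeList,
    mode: str = "proportional",
) -> CrossoverMatrix:
    """Distribute each crossover's unit mass over genomic intervals.

    In ``proportional`` mode mass is split by overlap of the crossover
    interval ``[left_pos, right_pos)`` with each bin; in ``midpoint`` mode the
    bin containing the interval midpoint receives the full unit.  Mass
    falling outside every bin is dropped with a warning.
    """
    if mode not in {"proportional", "midpoint"}:
        raise ValueError("mode must be 'proportional' or 'midpoint'")
    intervals = intervals.reset_index(drop=True)
    for chrom, grp in intervals.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if np.any(np.diff(starts) < 0):
            raise ValueError("intervals must be sorted by start within chromosome")
        if np.any(ends[:-1] > starts[1:]) or np.any(ends <= starts):
            raise ValueError("intervals must be non-overlapping with end > start")
    counts = np.zeros((len(intervals), len(cells)))
    dropped = 0.0
    for row in crossovers.itertuples(index=False):
        if row.barcode not in cells:
            raise ValueError(f"crossover cell {row.barcode!r} not in cell list")
        c = cells.index(row.barcode)
        sel = intervals["chrom"] == row.chrom
        idx = np.flatnonzero(sel.to_numpy())
        if len(idx) == 0:
            dropped += 1.0
            continue
        starts = intervals.loc[sel, "start"].to_numpy()
        ends = intervals.loc[sel, "end"].to_numpy()
        left, right = row.left_pos, row.right_pos
        if not left < right:
            raise ValueError("crossover interval must satisfy left_pos < right_pos")
        if mode == "midpoint":
            mid = 0.5 * (left + right)
            j = np.flatnonzero((starts <= mid) & (mid < ends))
            if len(j):
                counts[idx[j[0]], c] += 1.0
            else:
                dropped += 1.0
            continue
        overlap = np.minimum(ends, right) - np.maximum(starts, left)
        overlap = np.clip(overlap, 0, None).astype(float)
        mass = overlap / (right - left)
        counts[idx, c] += mass
        dropped += 1.0 - mass.sum()
    if dropped > 1e-9:
        warnings.warn(
            f"{dropped:.3g} units of crossover mass fell outside all intervals",
            stacklevel=2,
        )
    return CrossoverMatrix(intervals, cells, counts)


def map_distance(r, method: str = "kosambi", clamp: bool = False):
    """Convert a recombination fraction to genetic distance in centiMorgans."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("recombination fraction must be >= 0")
    if clamp:
        r = np.minimum(r, 0.5 - 1e-9)
    elif np.any(r >= 0.5):
        raise ValueError("mapping functions are undefined for r >= 0.5")
    if method == "kosambi":
        d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    elif method == "haldane":
        d = -50.0 * np.log(1.0 - 2.0 * r)
    else:
        raise ValueError(f"unknown mapping function: {method!r}")
    return float(d) if d.ndim == 0 else d


def _group_indices(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    g1 = np.flatnonzero(labels == groups[0])
    g2 = np.flatnonzero(labels == groups[1])
    return groups, g1, g2


def cal_genetic_dist(
    m: CrossoverMatrix,
    method: str = "kosambi",
    group_by: np.ndarray | None = None,
    clamp: bool = False,
) -> pd.DataFrame:
    """Per-bin and cumulative genetic distances, optionally per cell group.

    The per-bin recombination fraction is the group's mean crossover mass per
    gamete; distances accumulate along each chromosome.
    """
    labels = group_by if group_by is not None else m.group_labels
    if labels is None:
        labels = np.repeat("all", len(m.cells))
    labels = np.asarray(labels)
    frames = []
    for grp in pd.unique(labels):
        cols = np.flatnonzero(labels == grp)
        if len(cols) == 0:
            raise ValueError(f"group {grp!r} has no cells")
        r = m.counts[:, cols].sum(axis=1) / len(cols)
        cm = map_distance(r, method=method, clamp=clamp)
        df = m.intervals.copy()
        df["group"] = grp
        df["r"] = r
        df["cM"] = cm
        df["cum_cM"] = df.groupby("chrom", sort=False)["cM"].cumsum()
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _total_dist_per_resample(
    mass: np.ndarray, n_cells: int, method: str
) -> np.ndarray:
    """mass: (n_bins, B) total group mass -> (B,) total genetic distance.

    Resampled per-bin rates are clamped just below 0.5 so an extreme
    resample keeps the statistic finite.
    """
    r = mass / n_cells
    return map_distance(r, method=method, clamp=True).sum(axis=0)


def bootstrap_dist(
    m: CrossoverMatrix,
    labels: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    method: str = "kosambi",
    ci: float = 0.95,
) -> GroupComparison:
    """Percentile bootstrap CI for the difference in total genetic distance.

    Gametes are resampled with replacement within each group; the statistic
    is total cM of group 1 minus total cM of group 2.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    groups, g1, g2 = _group_indices(labels)
    for g, name in ((g1, groups[0]), (g2, groups[1])):
        if len(g) == 1:
            warnings.warn(f"group {name!r} has a single cell; CI is degenerate", stacklevel=2)
    rng = np.random.default_rng(seed)
    obs = float(
        _total_dist_per_resample(m.counts[:, g1].sum(axis=1)[:, None], len(g1), method)[0]
        - _total_dist_per_resample(m.counts[:, g2].sum(axis=1)[:, None], len(g2), method)[0]
    )
    diffs = np.empty(B)
    c1, c2 = m.counts[:, g1], m.counts[:, g2]
    for b in range(B):
        s1 = c1[:, rng.integers(0, len(g1), len(g1))].sum(axis=1)
        s2 = c2[:, rng.integers(0, len(g2), len(g2))].sum(axis=1)
        diffs[b] = (
            _total_dist_per_resample(s1[:, None], len(g1), method)[0]
            - _total_dist_per_resample(s2[:, None], len(g2), method)[0]
        )
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(diffs, [100 * alpha, 100 * (1 - alpha)])
    return GroupComparison(
        observed_diff=obs, ci_low=float(lo), ci_high=float(hi), n_resamples=B, seed=seed
    )


def permute_dist(
    m: CrossoverMatrix,
    labels: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    method: str = "kosambi",
) -> GroupComparison:
    """Two-sided permutation p-value for the total genetic-distance difference.

    Empirical p = (1 + #{|diff_perm| >= |diff_obs|}) / (B + 1).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    groups, g1, g2 = _group_indices(labels)
    rng = np.random.default_rng(seed)
    n = len(m.cells)
    n1 = len(g1)
    obs = float(
        _total_dist_per_resample(m.counts[:, g1].sum(axis=1)[:, None], n1, method)[0]
        - _total_dist_per_resample(m.counts[:, g2].sum(axis=1)[:, None], len(g2), method)[0]
    )
    # vectorised permutations: each row of `order` is a random permutation
    keys = rng.random((B, n))
    order = np.argsort(keys, axis=1)
    in_g1 = (order < n1).astype(float)  # first n1 slots of each permutation
    mass1 = m.counts @ in_g1.T  # (n_bins, B)
    total = m.counts.sum(axis=1, keepdims=True)
    mass2 = np.maximum(total - mass1, 0.0)  # guard float round-off
    d1 = _total_dist_per_resample(mass1, n1, method)
    d2 = _total_dist_per_resample(mass2, len(g2), method)
    diffs = d1 - d2
    p = (1.0 + np.count_nonzero(np.abs(diffs) >= abs(obs) - 1e-12)) / (B + 1.0)
    return GroupComparison(observed_diff=obs, p_value=float(p), n_resamples=B, seed=seed)


@dataclass(frozen=True)
class PhasingAccuracy:
    accuracy: float
    n_phased: int
    n_compared: int
    flipped: bool
    bins: pd.DataFrame  # bin_index, n_snps, concordance


def phasing_accuracy(
    inferred: Haplotype, truth: Haplotype, bin_snps: int = 100
) -> PhasingAccuracy:
    """Concordance of an inferred haplotype with a truth haplotype.

    The inferred haplotype is first oriented to the truth by whole-chromosome
    majority vote (the two labelings are equivalent), then concordant
    fractions are reported per bin of ``bin_snps`` consecutive co-phased SNPs
    and overall.
    """
    if inferred.snps != truth.snps:
        raise ValueError("haplotypes must share one SNP table")
    both = np.flatnonzero((inferred.hap1 != MISSING) & (truth.hap1 != MISSING))
    if len(both) == 0:
        raise ValueError("no SNP is phased in both haplotypes")
    inf = inferred.hap1[both]
    tru = truth.hap1[both]
    agree = int(np.count_nonzero(inf == tru))
    flipped = agree * 2 < len(both)
    if flipped:
        inf = complement_code(inf)
        agree = len(both) - agree
    match = (inf == tru).astype(float)
    bin_index = np.arange(len(both)) // bin_snps
    bins = (
        pd.DataFrame({"bin_index": bin_index, "match": match})
        .groupby("bin_index")
        .agg(n_snps=("match", "size"), concordance=("match", "mean"))
        .reset_index()
    )
    return PhasingAccuracy(
        accuracy=agree / len(both),
        n_phased=inferred.n_phased,
        n_compared=len(both),
        flipped=flipped,
        bins=bins,
    )


def caf_bins(
    counts: AlleleCountMatrix, hap: Haplotype, bin_snps: int = 1000
) -> pd.DataFrame:
    """Contradictory-allele read frequency per gamete per SNP bin.

    Reads are classified as supporting haplotype 1 or 2 through ``hap``; in
    each bin of ``bin_snps`` consecutive phased SNPs the contradictory class
    is whichever has fewer reads for that gamete, so CAF <= 0.5 by
    construction.  Bins with no reads for a gamete are omitted.
    """
    if bin_snps < 1:
        raise ValueError("bin_snps must be >= 1")
    from .crossover_hmm import hap_read_counts

    h1, h2, kept = hap_read_counts(counts, hap)
    n_bins = int(np.ceil(len(kept) / bin_snps)) if len(kept) else 0
    rows = []
    h1 = np.asarray(h1.todense())
    h2 = np.asarray(h2.todense())
    for b in range(n_bins):
        sl = slice(b * bin_snps, (b + 1) * bin_snps)
        s1 = h1[:, sl].sum(axis=1)
        s2 = h2[:, sl].sum(axis=1)
        tot = s1 + s2
        for c in np.flatnonzero(tot > 0):
            rows.append(
                {
                    "barcode": counts.barcodes[int(c)],
                    "bin_index": b,
                    "first_pos": int(counts.snps.positions[kept[sl][0]]),
                    "last_pos": int(counts.snps.positions[kept[sl][-1]]),
                    "n_reads": int(tot[c]),
                    "caf": float(min(s1[c], s2[c]) / tot[c]),
                }
            )
    return pd.DataFrame(
        rows, columns=["barcode", "bin_index", "first_pos", "last_pos", "n_reads", "caf"]
    )


# ---------------------------------------------------------------------------
# CrossoverMatrix TSV round trip (CLI surface)


def write_crossover_matrix(path, m: CrossoverMatrix) -> None:
    df = m.intervals.copy()
    for i, b in enumerate(m.cells):
        df[b] = m.counts[:, i]
    df.to_csv(path, sep="\t", index=False)


def read_crossover_matrix(path) -> CrossoverMatrix:
    df = pd.read_csv(path, sep="\t")
    meta = ["chrom", "start", "end"]
    cells = BarcodeList([c for c in df.columns if c not in meta])
    return CrossoverMatrix(
        df[meta], cells, df[[c for c in df.columns if c not in meta]].to_numpy(float)
    )
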